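"""Probe model: Debye references, Stuchly forward/inverse, one-port calibration."""

import numpy as np
import pytest

from mwibone.probe_model import (
    GLYCOL_22C,
    SHORT,
    WATER_22C,
    DebyeLiquid,
    ErrorTerms,
    PermittivitySpectrum,
    ProbeParams,
    S11Sweep,
    de_embed,
    debye_permittivity,
    embed,
    extract_at_frequency,
    fit_probe_params,
    forward_gamma,
    invert_permittivity,
    solve_error_terms,
)
from mwibone.touchstone import read_s1p, write_s1p


class TestDebye:
    def test_static_limit(self):
        liquid = DebyeLiquid(80.0, 5.0, 9e-12)
        eps = debye_permittivity(liquid, np.array([1e8, 2e8])).eps_complex
        assert eps[0].real == pytest.approx(80.0, abs=0.01)

    def test_optical_limit(self):
        liquid = DebyeLiquid(80.0, 5.0, 9e-12)
        eps = debye_permittivity(liquid, np.array([1e14])).eps_complex
        assert eps[0].real == pytest.approx(5.0, rel=1e-3)

    def test_hand_value_at_omega_tau_one(self):
        # at ωτ = 1: ε = ε∞ + (εs − ε∞)(1 − j)/2
        tau = 1.0 / (2 * np.pi * 1e9)
        eps = debye_permittivity(DebyeLiquid(80.0, 5.0, tau), np.array([1e9])).eps_complex[0]
        assert eps.real == pytest.approx(42.5, abs=1e-9)
        assert -eps.imag == pytest.approx(37.5, abs=1e-9)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            debye_permittivity(WATER_22C, np.array([0.0, 1e9]))


class TestForwardInverse:
    def test_lossless_load_is_unimodular(self, probe_params):
        g = forward_gamma(4.0 + 0j, 2.5e9, probe_params)
        assert abs(g) == pytest.approx(1.0, abs=1e-12)

    def test_lossy_load_reflects_less(self, probe_params):
        g = forward_gamma(4.0 - 0.5j, 2.5e9, probe_params)
        assert abs(g) < 1.0

    def test_round_trip_specific(self, probe_params):
        eps = 4.0 - 0.5j
        g = forward_gamma(eps, 2.5e9, probe_params)
        assert invert_permittivity(g, 2.5e9, probe_params) == pytest.approx(eps, rel=1e-12)

    def test_air_inverts_to_one(self, probe_params):
        g = forward_gamma(1.0 + 0j, 2.7e9, probe_params)
        assert invert_permittivity(g, 2.7e9, probe_params) == pytest.approx(1.0 + 0j, abs=1e-10)

    def test_short_is_singular(self, probe_params):
        with pytest.raises(ValueError):
            invert_permittivity(-1.0 + 0j, 2.5e9, probe_params)

    def test_round_trip_property(self, probe_params, rng):
        """Forward/inverse agree to 1e-9 relative over the physical ε range."""
        eps = rng.uniform(1, 80, 1000) - 1j * rng.uniform(0, 40, 1000)
        f = rng.uniform(2.25e9, 3.0e9, 1000)
        rec = invert_permittivity(forward_gamma(eps, f, probe_params), f, probe_params)
        assert np.max(np.abs(rec - eps) / np.abs(eps)) < 1e-9


def _standards(freqs, params, terms=None, noise=0.0, rng=None):
    """Four embedded standards (open/short/water/glycol) on one grid."""
    out = []
    air = debye_permittivity(DebyeLiquid(1.0, 1.0, 1e-12, name="air"), freqs)
    for actual in (air, SHORT, WATER_22C, GLYCOL_22C):
        if actual is SHORT:
            g = np.full(freqs.shape, -1.0 + 0j)
        else:
            spec = actual if isinstance(actual, PermittivitySpectrum) else debye_permittivity(actual, freqs)
            g = forward_gamma(spec.eps_complex, freqs, params)
        sweep = S11Sweep(freqs, g)
        if terms is not None:
            sweep = embed(sweep, terms)
        if noise:
            sweep = S11Sweep(freqs, sweep.gamma + noise * (rng.standard_normal(freqs.shape)
                                                           + 1j * rng.standard_normal(freqs.shape)))
        out.append((sweep, actual))
    return out


class TestCalibration:
    def test_identity_fixture(self, sweep_freqs, probe_params):
        terms = solve_error_terms(_standards(sweep_freqs, probe_params)[:3], probe_params)
        assert np.allclose(terms.e_d, 0, atol=1e-10)
        assert np.allclose(terms.e_s, 0, atol=1e-10)
        assert np.allclose(terms.e_r, 1, atol=1e-10)

    def test_synthetic_terms_recovered_exactly(self, sweep_freqs, probe_params):
        ones = np.ones_like(sweep_freqs, dtype=complex)
        truth = ErrorTerms(sweep_freqs, (0.1 + 0.05j) * ones, 0.9 * ones, -0.02 * ones)
        standards = _standards(sweep_freqs, probe_params, terms=truth)[:3]
        rec = solve_error_terms(standards, probe_params)
        assert np.allclose(rec.e_d, truth.e_d, atol=1e-10)
        assert np.allclose(rec.e_r, truth.e_r, atol=1e-10)
        assert np.allclose(rec.e_s, truth.e_s, atol=1e-10)

    def test_four_noisy_standards(self, sweep_freqs, probe_params, rng):
        ones = np.ones_like(sweep_freqs, dtype=complex)
        truth = ErrorTerms(sweep_freqs, (0.1 + 0.05j) * ones, 0.9 * ones, -0.02 * ones)
        standards = _standards(sweep_freqs, probe_params, terms=truth, noise=1e-3, rng=rng)
        rec = solve_error_terms(standards, probe_params)
        for got, want in ((rec.e_d, truth.e_d), (rec.e_r, truth.e_r), (rec.e_s, truth.e_s)):
            assert np.max(np.abs(got - want)) < 1e-2

    def test_too_few_standards(self, sweep_freqs, probe_params):
        with pytest.raises(ValueError):
            solve_error_terms(_standards(sweep_freqs, probe_params)[:2], probe_params)

    def test_degenerate_standards(self, sweep_freqs, probe_params):
        stds = _standards(sweep_freqs, probe_params)[:3]
        with pytest.raises(ValueError):
            solve_error_terms(stds + [stds[-1]], probe_params)


class TestDeEmbed:
    def test_identity_terms(self, sweep_freqs, rng):
        terms = ErrorTerms(sweep_freqs, np.zeros_like(sweep_freqs, dtype=complex),
                           np.ones_like(sweep_freqs, dtype=complex),
                           np.zeros_like(sweep_freqs, dtype=complex))
        g = 0.3 * np.exp(1j * rng.uniform(0, 2 * np.pi, sweep_freqs.shape))
        sweep = S11Sweep(sweep_freqs, g)
        assert np.allclose(de_embed(sweep, terms).gamma, g, atol=1e-15)

    def test_embed_round_trip(self, sweep_freqs, rng):
        ones = np.ones_like(sweep_freqs, dtype=complex)
        terms = ErrorTerms(sweep_freqs, (0.1 + 0.05j) * ones, (0.9 - 0.1j) * ones, -0.02 * ones)
        g = 0.5 * np.exp(1j * rng.uniform(0, 2 * np.pi, sweep_freqs.shape))
        sweep = S11Sweep(sweep_freqs, g)
        assert np.allclose(de_embed(embed(sweep, terms), terms).gamma, g, atol=1e-10)

    def test_misaligned_grids_interpolated(self, sweep_freqs):
        ones = np.ones_like(sweep_freqs, dtype=complex)
        terms = ErrorTerms(sweep_freqs, 0.05 * ones, 0.95 * ones, -0.01 * ones)
        f2 = np.linspace(2.3e9, 2.9e9, 37)
        sweep = S11Sweep(f2, np.full(f2.shape, 0.2 + 0.1j))
        out = de_embed(sweep, terms)
        assert out.gamma.shape == f2.shape


class TestFitProbeParams:
    def test_noise_free_recovery(self, sweep_freqs):
        truth = ProbeParams(c0=25e-15, cf=20e-15)
        sweeps = []
        for liquid in (WATER_22C, GLYCOL_22C):
            eps = debye_permittivity(liquid, sweep_freqs).eps_complex
            sweeps.append((S11Sweep(sweep_freqs, forward_gamma(eps, sweep_freqs, truth)), liquid))
        fit = fit_probe_params(sweeps)
        assert fit.c0 == pytest.approx(truth.c0, rel=1e-3)
        assert fit.cf == pytest.approx(truth.cf, rel=1e-3)

    def test_single_liquid_underdetermined(self, sweep_freqs):
        truth = ProbeParams()
        eps = debye_permittivity(WATER_22C, sweep_freqs).eps_complex
        sweep = S11Sweep(sweep_freqs, forward_gamma(eps, sweep_freqs, truth))
        with pytest.raises(ValueError):
            fit_probe_params([(sweep, WATER_22C)])

    def test_noisy_recovery(self, sweep_freqs, rng):
        truth = ProbeParams(c0=25e-15, cf=20e-15)
        sweeps = []
        for liquid in (WATER_22C, GLYCOL_22C):
            eps = debye_permittivity(liquid, sweep_freqs).eps_complex
            g = forward_gamma(eps, sweep_freqs, truth)
            g = g + 1e-3 * (rng.standard_normal(g.shape) + 1j * rng.standard_normal(g.shape))
            sweeps.append((S11Sweep(sweep_freqs, g), liquid))
        fit = fit_probe_params(sweeps)
        assert fit.c0 == pytest.approx(truth.c0, rel=0.05)
        assert fit.cf == pytest.approx(truth.cf, rel=0.05)


class TestExtract:
    def test_on_grid_exact(self, sweep_freqs):
        spec = PermittivitySpectrum(sweep_freqs, np.arange(len(sweep_freqs), dtype=complex))
        assert extract_at_frequency(spec, sweep_freqs[40]) == pytest.approx(40.0)

    def test_constant_spectrum(self, sweep_freqs):
        spec = PermittivitySpectrum(sweep_freqs, np.full(sweep_freqs.shape, 7 - 2j))
        assert extract_at_frequency(spec, 2.6e9) == pytest.approx(7 - 2j)

    def test_linear_midpoint(self):
        f = np.array([2.4e9, 2.6e9])
        spec = PermittivitySpectrum(f, np.array([10 + 0j, 20 + 0j]))
        assert extract_at_frequency(spec, 2.5e9) == pytest.approx(15.0 + 0j)

    def test_out_of_span(self, sweep_freqs):
        spec = PermittivitySpectrum(sweep_freqs, np.ones_like(sweep_freqs, dtype=complex))
        with pytest.raises(ValueError):
            extract_at_frequency(spec, 5e9)


class TestEndToEnd:
    def test_calibrated_pipeline_recovers_eps(self, sweep_freqs, probe_params):
        """Simulated standards + specimen sweep: ε at 2.5 GHz within 1% noise-free."""
        ones = np.ones_like(sweep_freqs, dtype=complex)
        truth_terms = ErrorTerms(sweep_freqs, (0.05 + 0.02j) * ones, (0.93 - 0.05j) * ones,
                                 (-0.04 + 0.01j) * ones)
        eps_true = 12.0 - 1.5j
        raw = embed(S11Sweep(sweep_freqs,
                             forward_gamma(np.full(sweep_freqs.shape, eps_true),
                                           sweep_freqs, probe_params)), truth_terms)
        standards = _standards(sweep_freqs, probe_params, terms=truth_terms)
        terms = solve_error_terms(standards, probe_params)
        clean = de_embed(raw, terms)
        eps = invert_permittivity(clean.gamma, clean.frequencies_hz, probe_params)
        got = extract_at_frequency(PermittivitySpectrum(sweep_freqs, eps), 2.5e9)
        assert abs(got - eps_true) / abs(eps_true) < 0.01

    def test_passivity_after_de_embedding(self, sweep_freqs, probe_params):
        ones = np.ones_like(sweep_freqs, dtype=complex)
        truth_terms = ErrorTerms(sweep_freqs, (0.05 + 0.02j) * ones, (0.93 - 0.05j) * ones,
                                 (-0.04 + 0.01j) * ones)
        standards = _standards(sweep_freqs, probe_params, terms=truth_terms)
        terms = solve_error_terms(standards, probe_params)
        for sweep, _ in standards:
            clean = de_embed(sweep, terms)
            assert np.all(np.abs(clean.gamma) <= 1 + 1e-6)


class TestTouchstone:
    @pytest.mark.parametrize("fmt", ["RI", "MA"])
    def test_round_trip(self, tmp_path, sweep_freqs, rng, fmt):
        g = 0.4 * np.exp(1j * rng.uniform(-np.pi, np.pi, sweep_freqs.shape))
        path = tmp_path / "sweep.s1p"
        write_s1p(path, sweep_freqs, g, fmt=fmt, comment="synthetic sweep")
        f2, g2 = read_s1p(path)
        assert np.allclose(f2, sweep_freqs)
        assert np.allclose(g2, g, atol=1e-9)

    def test_ghz_units(self, tmp_path):
        path = tmp_path / "g.s1p"
        path.write_text("# GHZ S RI R 50\n2.5 0.1 -0.2\n2.6 0.2 -0.1\n")
        f, g = read_s1p(path)
        assert np.allclose(f, [2.5e9, 2.6e9])
        assert g[0] == pytest.approx(0.1 - 0.2j)
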
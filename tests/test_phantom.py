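"""Synthetic phantom generator and forward measurement simulation."""

import numpy as np
import pytest

from mwibone.phantom import (
    AntennaGainProfile,
    Hole,
    StudyConfig,
    default_error_terms,
    generate_study,
    inter_antenna_cv,
    make_phantom,
    simulate_coarse_grids,
    simulate_s11_layer,
)
from mwibone.probe_model import (
    PermittivitySpectrum,
    ProbeParams,
    de_embed,
    extract_at_frequency,
    invert_permittivity,
    solve_error_terms,
)


class TestMakePhantom:
    def test_realized_field_stats(self):
        phantom = make_phantom(16, baseline_mean=1.771, baseline_sd=0.185, seed=1)
        assert phantom.baseline_eps.mean() == pytest.approx(1.771, rel=0.10)
        assert phantom.baseline_eps.std() == pytest.approx(0.185, rel=0.10)

    def test_zero_holes(self):
        phantom = make_phantom(0, seed=2)
        assert phantom.holes == []

    def test_determinism(self):
        a = make_phantom(20, seed=3)
        b = make_phantom(20, seed=3)
        assert np.array_equal(a.baseline_eps, b.baseline_eps)
        assert [h.center_mm for h in a.holes] == [h.center_mm for h in b.holes]

    def test_hole_layouts(self):
        for n, shape in ((16, 16), (20, 20), (25, 25)):
            phantom = make_phantom(n, seed=0)
            assert len(phantom.holes) == n

    def test_hole_spacing_enforced(self):
        phantom = make_phantom(16, seed=0)
        centers = np.array([h.center_mm for h in phantom.holes])
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4.0 - 1e-9


class TestGains:
    def test_realized_cv_matches_target(self, rng):
        gains = AntennaGainProfile.draw(0.082, rng)
        realized = gains.gains.std(ddof=1) / gains.gains.mean()
        assert realized == pytest.approx(0.082, rel=1e-9)

    def test_out_of_band_cv_rejected(self):
        with pytest.raises(ValueError):
            AntennaGainProfile(np.ones(16), target_cv=0.082)


class TestSimulateGrids:
    def test_constant_baseline_no_holes_gives_constant(self, geometry, kernel, depth_profile):
        phantom = make_phantom(0, baseline_mean=1.5, baseline_sd=0.0, seed=0)
        rng = np.random.default_rng(0)
        gains = AntennaGainProfile.draw(0.082, rng)
        gains.gains[:] = 1.0
        grids = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                      0.0, "pre", rng)
        assert len(grids) == 4
        assert np.allclose(grids[0].values, 1.5, atol=1e-6)

    def test_pre_post_differ_only_near_holes(self, geometry, kernel, depth_profile):
        phantom = make_phantom(1, baseline_mean=1.5, baseline_sd=0.05, seed=4)
        phantom.holes[:] = [Hole((28.0, 28.0))]
        rng = np.random.default_rng(4)
        gains = AntennaGainProfile.draw(0.082, rng)
        gains.gains[:] = 1.0
        pre = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                    0.0, "pre", rng)[0]
        post = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                     0.0, "post", rng)[0]
        diff = np.abs(post.values - pre.values)
        yy, xx = geometry.cell_centers_mm()
        far = np.hypot(yy - 28.0, xx - 28.0) > 1.0 + kernel.radii_mm[-1]
        assert np.all(diff[far] < 1e-9)
        assert diff[7, 7] > 0.01

    def test_single_hole_quadrature_oracle(self, geometry, kernel, depth_profile):
        """The cell reading equals brute-force quadrature of kernel × √ε field."""
        phantom = make_phantom(1, baseline_mean=1.5, baseline_sd=0.0, seed=5)
        phantom.holes[:] = [Hole((28.0, 28.0))]
        rng = np.random.default_rng(5)
        gains = AntennaGainProfile.draw(0.082, rng)
        gains.gains[:] = 1.0
        post = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                     0.0, "post", rng)[0]
        # quadrature on the same fine lattice the phantom is defined on
        coords = phantom.fine_coords()
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        fld = np.sqrt(phantom.field("post", depth_profile))
        w = kernel.density_at(np.hypot(yy - 28.0, xx - 28.0))
        expected = (np.sum(w * fld) / np.sum(w)) ** 2
        assert post.values[7, 7] == pytest.approx(expected, abs=1e-6)

    def test_rotated_grids_share_common_frame(self, geometry, kernel, depth_profile):
        from mwibone.mapping import rotate_to_common

        phantom = make_phantom(1, baseline_mean=1.5, baseline_sd=0.1, seed=6)
        phantom.holes[:] = [Hole((16.0, 36.0))]  # off-center marker
        rng = np.random.default_rng(6)
        gains = AntennaGainProfile.draw(0.082, rng)
        gains.gains[:] = 1.0
        grids = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                      0.0, "post", rng)
        peaks = set()
        for g in grids:
            common = rotate_to_common(g)
            peaks.add(np.unravel_index(np.argmax(common.values), (16, 16)))
        assert len(peaks) == 1


class TestS11Layer:
    def test_full_loop_reproduces_grid(self, geometry, kernel, depth_profile, probe_params):
        """Simulate → calibrate → de-embed → invert → extract: < 0.5% noise-free."""
        phantom = make_phantom(4, baseline_mean=1.6, baseline_sd=0.1, seed=7)
        rng = np.random.default_rng(7)
        gains = AntennaGainProfile.draw(0.082, rng)
        grid = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                     0.0, "post", rng)[0]
        freqs = np.linspace(2.25e9, 3.0e9, 21)
        terms_true = default_error_terms(freqs)
        cells, standards = simulate_s11_layer(grid, probe_params, terms_true,
                                              frequencies_hz=freqs)
        terms = solve_error_terms(list(standards.values()), probe_params)
        for (i, j) in [(0, 0), (7, 7), (15, 15), (3, 12)]:
            clean = de_embed(cells[(i, j)], terms)
            eps = invert_permittivity(clean.gamma, clean.frequencies_hz, probe_params)
            val = extract_at_frequency(PermittivitySpectrum(freqs, eps), 2.5e9)
            assert val.real == pytest.approx(grid.values[i, j], rel=0.005)

    def test_identity_terms_give_raw_gamma(self, geometry, kernel, depth_profile, probe_params):
        from mwibone.probe_model import ErrorTerms, forward_gamma

        phantom = make_phantom(0, baseline_mean=1.5, baseline_sd=0.0, seed=8)
        rng = np.random.default_rng(8)
        gains = AntennaGainProfile.draw(0.082, rng)
        gains.gains[:] = 1.0
        grid = simulate_coarse_grids(phantom, geometry, kernel, depth_profile, gains,
                                     0.0, "pre", rng)[0]
        freqs = np.linspace(2.25e9, 3.0e9, 5)
        identity = ErrorTerms(freqs, np.zeros(5, dtype=complex), np.ones(5, dtype=complex),
                              np.zeros(5, dtype=complex))
        cells, _ = simulate_s11_layer(grid, probe_params, identity, frequencies_hz=freqs)
        raw = forward_gamma(np.full(5, grid.values[0, 0], dtype=complex), freqs, probe_params)
        assert np.allclose(cells[(0, 0)].gamma, raw, atol=1e-12)


class TestStudy:
    def test_default_study_matches_design(self):
        study = generate_study(StudyConfig(seed=0))
        names = [sd.spec.name for sd in study.specimens]
        counts = [sd.spec.n_holes for sd in study.specimens]
        assert names == list("ABCDEFG")
        assert counts == [16, 16, 25, 25, 20, 20, 16]

    def test_ground_truth_bookkeeping(self):
        study = generate_study(StudyConfig(seed=0))
        for sd in study.specimens:
            assert sd.truth["injected_ul"] == pytest.approx(sd.spec.n_holes * 25.133, rel=1e-3)
            assert sd.truth["depth_visible_ul"] == pytest.approx(
                sd.truth["injected_ul"] * 0.16875, rel=1e-6
            )

    def test_determinism(self):
        a = generate_study(StudyConfig(seed=42))
        b = generate_study(StudyConfig(seed=42))
        for sa, sb in zip(a.specimens, b.specimens):
            assert np.array_equal(sa.grids["post"][2].values, sb.grids["post"][2].values)
            assert np.array_equal(sa.ct["post"].hu, sb.ct["post"].hu)

    def test_inter_antenna_cv_in_reported_band(self):
        """Per-antenna baseline means vary by 5–11% CV at the default gain spread."""
        study = generate_study(StudyConfig(seed=1))
        cvs = [inter_antenna_cv(sd.grids["pre"]) for sd in study.specimens]
        assert all(5.0 <= cv <= 11.0 for cv in cvs)
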
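"""Open-ended coaxial probe (OECP) reflection model and one-port calibration.

Raw one-port reflection sweeps are de-embedded through the standard
three-term error model (directivity ``e_d``, reflection tracking ``e_r``,
source match ``e_s``) solved from measurements of known standards — open
(air), short, and reference liquids described by single-pole Debye
relaxations — and then inverted to complex relative permittivity with the
Stuchly capacitive aperture model

    Y(ω) = jω (C0 ε_r + Cf),   Γ = (1 − Y Z0) / (1 + Y Z0).

Sign convention (used everywhere in this package): time dependence
``e^{+jωt}``; a lossy material has ε = ε′ − jε″ with ε″ ≥ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

__all__ = [
    "S11Sweep",
    "ErrorTerms",
    "ProbeParams",
    "DebyeLiquid",
    "PermittivitySpectrum",
    "WATER_22C",
    "GLYCOL_22C",
    "SHORT",
    "debye_permittivity",
    "forward_gamma",
    "invert_permittivity",
    "solve_error_terms",
    "de_embed",
    "fit_probe_params",
    "extract_at_frequency",
]


@dataclass
class S11Sweep:
    """One-port reflection coefficient versus frequency."""

    frequencies_hz: np.ndarray
    gamma: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=complex)
        if self.frequencies_hz.ndim != 1 or self.frequencies_hz.size < 2:
            raise ValueError("need a 1-D frequency array with at least 2 points")
        if self.frequencies_hz.shape != self.gamma.shape:
            raise ValueError("frequency and gamma arrays must align")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any((self.frequencies_hz < 1e8) | (self.frequencies_hz > 1e11)):
            raise ValueError("frequencies outside the supported 0.1–100 GHz range")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma must be finite")


@dataclass
class ErrorTerms:
    """Per-frequency one-port error model (directivity, tracking, source match)."""

    frequencies_hz: np.ndarray
    e_d: np.ndarray
    e_r: np.ndarray
    e_s: np.ndarray

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.e_d = np.asarray(self.e_d, dtype=complex)
        self.e_r = np.asarray(self.e_r, dtype=complex)
        self.e_s = np.asarray(self.e_s, dtype=complex)
        for arr in (self.e_d, self.e_r, self.e_s):
            if arr.shape != self.frequencies_hz.shape:
                raise ValueError("error-term arrays must align with frequencies")
        if np.any(np.abs(self.e_r) == 0):
            raise ValueError("reflection tracking must be nonzero at every frequency")

    def interpolated(self, frequencies_hz: np.ndarray) -> "ErrorTerms":
        """Linearly interpolate the terms onto a new grid within the span."""
        f = np.asarray(frequencies_hz, dtype=float)
        if f.min() < self.frequencies_hz[0] - 1e-6 or f.max() > self.frequencies_hz[-1] + 1e-6:
            raise ValueError("requested grid extends beyond the calibrated span")

        def interp_c(arr):
            return np.interp(f, self.frequencies_hz, arr.real) + 1j * np.interp(
                f, self.frequencies_hz, arr.imag
            )

        return ErrorTerms(f, interp_c(self.e_d), interp_c(self.e_r), interp_c(self.e_s))


@dataclass
class ProbeParams:
    """Stuchly aperture parameters: C0 scales with ε, Cf is the fringe term."""

    c0: float = 25e-15
    cf: float = 20e-15
    z0: float = 50.0

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.cf < 0:
            raise ValueError("cf must be non-negative")
        if self.z0 <= 0:
            raise ValueError("z0 must be positive")


@dataclass
class DebyeLiquid:
    """Single-relaxation Debye dispersion for a polar reference liquid."""

    eps_static: float
    eps_inf: float
    tau_s: float
    sigma_dc: float = 0.0
    temperature_c: float | None = None
    name: str = ""

    def __post_init__(self):
        if not (self.eps_static >= self.eps_inf >= 1.0):
            raise ValueError("require eps_static >= eps_inf >= 1")
        if self.tau_s <= 0:
            raise ValueError("relaxation time must be positive")
        if self.sigma_dc < 0:
            raise ValueError("dc conductivity must be non-negative")


#: Literature-informed defaults for the simulator's reference liquids.
WATER_22C = DebyeLiquid(79.2, 5.2, 9.36e-12, temperature_c=22.0, name="water")
GLYCOL_22C = DebyeLiquid(19.0, 3.0, 320e-12, temperature_c=22.0, name="propylene_glycol")

#: Sentinel marking the short standard (actual Γ = −1 at all frequencies).
SHORT = "short"


@dataclass
class PermittivitySpectrum:
    """Complex relative permittivity vs frequency (ε = ε′ − jε″, ε″ ≥ 0 passive)."""

    frequencies_hz: np.ndarray
    eps_complex: np.ndarray
    label: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.eps_complex = np.asarray(self.eps_complex, dtype=complex)
        if self.frequencies_hz.shape != self.eps_complex.shape:
            raise ValueError("frequency and permittivity arrays must align")
        # physical data should have non-negative real part; flag, don't clip
        if np.any(self.eps_complex.real < 0):
            self.flags.append("negative_real_permittivity")


def debye_permittivity(liquid: DebyeLiquid, frequencies_hz) -> PermittivitySpectrum:
    """Evaluate ε(f) = ε∞ + (εs − ε∞)/(1 + jωτ) − j σ_dc/(ω ε0)."""
    f = np.asarray(frequencies_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    w = 2 * np.pi * f
    eps = liquid.eps_inf + (liquid.eps_static - liquid.eps_inf) / (1 + 1j * w * liquid.tau_s)
    if liquid.sigma_dc:
        eps = eps - 1j * liquid.sigma_dc / (w * EPS0)
    return PermittivitySpectrum(f, eps, label=liquid.name)


def forward_gamma(eps, f_hz, params: ProbeParams):
    """Reflection coefficient of the capacitive aperture loaded with ε."""
    f_hz = np.asarray(f_hz, dtype=float)
    if np.any(f_hz <= 0):
        raise ValueError("frequency must be positive")
    y = 1j * 2 * np.pi * f_hz * (params.c0 * np.asarray(eps, dtype=complex) + params.cf)
    return (1 - y * params.z0) / (1 + y * params.z0)


def invert_permittivity(gamma, f_hz, params: ProbeParams):
    """Exact algebraic inverse of :func:`forward_gamma`.

    Raises for Γ = −1 (a short), which is outside the capacitive model's
    domain (infinite admittance).
    """
    gamma = np.asarray(gamma, dtype=complex)
    f_hz = np.asarray(f_hz, dtype=float)
    if np.any(np.abs(1 + gamma) < 1e-12):
        raise ValueError("gamma = -1 (short) is singular in the Stuchly model")
    w = 2 * np.pi * f_hz
    y = (1 - gamma) / (1 + gamma) / params.z0
    return y / (1j * w * params.c0) - params.cf / params.c0


def _actual_gamma(actual, frequencies_hz, params: ProbeParams) -> np.ndarray:
    if isinstance(actual, str):
        if actual != SHORT:
            raise ValueError(f"unknown standard flag {actual!r}")
        return np.full(len(frequencies_hz), -1.0 + 0j)
    if isinstance(actual, DebyeLiquid):
        actual = debye_permittivity(actual, frequencies_hz)
    if isinstance(actual, PermittivitySpectrum):
        if actual.frequencies_hz.shape != np.shape(frequencies_hz) or not np.allclose(
            actual.frequencies_hz, frequencies_hz
        ):
            raise ValueError("standard spectrum must share the sweep's frequency grid")
        return forward_gamma(actual.eps_complex, actual.frequencies_hz, params)
    raise TypeError("actual must be a PermittivitySpectrum, DebyeLiquid, or the SHORT flag")


def solve_error_terms(standards, params: ProbeParams) -> ErrorTerms:
    """Solve the one-port error model from ≥ 3 measured standards.

    ``standards`` is a list of ``(S11Sweep measured, actual)`` pairs where
    ``actual`` is a :class:`PermittivitySpectrum`, a :class:`DebyeLiquid`,
    or the :data:`SHORT` flag. The bilinear model

        Γ_m = e_d + e_r Γ / (1 − e_s Γ)

    is rearranged to the per-frequency linear system
    ``Γ_m = e_d + k Γ + e_s (Γ Γ_m)`` with ``k = e_r − e_d e_s``, solved
    exactly for 3 standards and by least squares for more.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    f = standards[0][0].frequencies_hz
    for sweep, _ in standards[1:]:
        if sweep.frequencies_hz.shape != f.shape or not np.allclose(sweep.frequencies_hz, f):
            raise ValueError("all standards must share one frequency grid")
    gam_act = np.stack([_actual_gamma(act, f, params) for _, act in standards])
    gam_meas = np.stack([sweep.gamma for sweep, _ in standards])

    # degenerate check: distinct actual Γ at every frequency
    for i in range(len(standards)):
        for j in range(i + 1, len(standards)):
            if np.any(np.abs(gam_act[i] - gam_act[j]) < 1e-9):
                raise ValueError(
                    f"standards {i} and {j} have (nearly) equal actual reflection "
                    "at some frequency; calibration is degenerate"
                )

    n_std, n_f = gam_meas.shape
    e_d = np.empty(n_f, dtype=complex)
    e_r = np.empty(n_f, dtype=complex)
    e_s = np.empty(n_f, dtype=complex)
    for m in range(n_f):
        a = np.column_stack(
            [np.ones(n_std, dtype=complex), gam_act[:, m], gam_act[:, m] * gam_meas[:, m]]
        )
        sol, *_ = np.linalg.lstsq(a, gam_meas[:, m], rcond=None)
        ed, k, es = sol
        e_d[m], e_s[m] = ed, es
        e_r[m] = k + ed * es
    return ErrorTerms(f, e_d, e_r, e_s)


def de_embed(sweep: S11Sweep, terms: ErrorTerms) -> S11Sweep:
    """Remove the error model: Γ = (Γ_m − e_d) / (e_s (Γ_m − e_d) + e_r)."""
    if terms.frequencies_hz.shape != sweep.frequencies_hz.shape or not np.allclose(
        terms.frequencies_hz, sweep.frequencies_hz
    ):
        terms = terms.interpolated(sweep.frequencies_hz)
    num = sweep.gamma - terms.e_d
    den = terms.e_s * num + terms.e_r
    bad = np.abs(den) < 1e-12
    if np.any(bad):
        f_bad = sweep.frequencies_hz[bad][0]
        raise ValueError(f"de-embedding denominator vanishes at {f_bad:.6g} Hz")
    return S11Sweep(sweep.frequencies_hz, num / den, label=sweep.label)


def embed(sweep: S11Sweep, terms: ErrorTerms) -> S11Sweep:
    """Apply the error model (forward direction); inverse of :func:`de_embed`."""
    if terms.frequencies_hz.shape != sweep.frequencies_hz.shape or not np.allclose(
        terms.frequencies_hz, sweep.frequencies_hz
    ):
        terms = terms.interpolated(sweep.frequencies_hz)
    g = sweep.gamma
    return S11Sweep(
        sweep.frequencies_hz, terms.e_d + terms.e_r * g / (1 - terms.e_s * g), label=sweep.label
    )


def fit_probe_params(liquid_sweeps, z0: float = 50.0) -> ProbeParams:
    """Estimate (C0, Cf) from de-embedded sweeps of known reference liquids.

    ``liquid_sweeps`` is a list of ``(S11Sweep, DebyeLiquid)`` pairs. The
    aperture admittance Y/(jω) = C0 ε + Cf is linear in the unknowns, so
    the least-squares solution is obtained in closed form by stacking real
    and imaginary parts across all liquids and frequencies.
    """
    if len(liquid_sweeps) < 2:
        raise ValueError("need at least 2 distinct liquids to separate C0 from Cf")
    rows = []
    rhs = []
    for sweep, liquid in liquid_sweeps:
        eps = debye_permittivity(liquid, sweep.frequencies_hz).eps_complex
        w = 2 * np.pi * sweep.frequencies_hz
        y_over_jw = (1 - sweep.gamma) / (1 + sweep.gamma) / (z0 * 1j * w)
        rows.append(np.column_stack([eps.real, np.ones_like(w)]))
        rhs.append(y_over_jw.real)
        rows.append(np.column_stack([eps.imag, np.zeros_like(w)]))
        rhs.append(y_over_jw.imag)
    a = np.vstack(rows)
    b = np.concatenate(rhs)
    (c0, cf), *_ = np.linalg.lstsq(a, b, rcond=None)
    if c0 <= 0 or cf < 0:
        raise RuntimeError(
            f"probe-parameter fit failed: recovered C0={c0:.3e} F, Cf={cf:.3e} F "
            "(expected positive); check that the liquids have distinct permittivities"
        )
    return ProbeParams(c0=float(c0), cf=float(cf), z0=z0)


def extract_at_frequency(spec: PermittivitySpectrum, f_target_hz: float) -> complex:
    """Linear interpolation of the spectrum at the working frequency."""
    f = spec.frequencies_hz
    if not (f[0] <= f_target_hz <= f[-1]):
        raise ValueError(f"target {f_target_hz:.6g} Hz outside sweep span [{f[0]:.6g}, {f[-1]:.6g}]")
    re = np.interp(f_target_hz, f, spec.eps_complex.real)
    im = np.interp(f_target_hz, f, spec.eps_complex.imag)
    return complex(re, im)
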
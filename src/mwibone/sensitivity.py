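"""Probe sensitivity characterization: radial kernel, lateral profile, depth decay.

Three bench experiments characterize each antenna's sensing footprint:

* **center-to-edge** — response to centered known-permittivity cylinders of
  increasing diameter; the cumulative curve is inverted annulus-by-annulus
  to the intrinsic per-area radial sensitivity density;
* **side-to-side** — response while a large flat sample slides laterally
  across the probe; an edge-response S-curve fitted with a logistic whose
  derivative is the lateral sensitivity profile;
* **penetration** — visibility versus target thickness, fitted with a
  saturating exponential 1 − exp(−t/δ) to give the depth-decay constant δ
  and the effective penetration depth d_eff(H) = δ(1 − e^{−H/δ}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit, isotonic_regression

__all__ = [
    "CumulativeResponseCurve",
    "RadialKernel",
    "SigmoidFit",
    "DepthProfile",
    "invert_radial_kernel",
    "fit_sigmoid",
    "fit_depth_profile",
    "effective_depth",
]


@dataclass
class CumulativeResponseCurve:
    """Normalized response vs size (cylinder diameter or lateral offset), in mm."""

    sizes_mm: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        self.sizes_mm = np.asarray(self.sizes_mm, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.sizes_mm.shape != self.response.shape:
            raise ValueError("sizes and response must align")
        if np.any(np.diff(self.sizes_mm) <= 0):
            raise ValueError("sizes must be strictly ascending")


@dataclass
class RadialKernel:
    """Piecewise-constant per-area sensitivity density over annuli.

    ``radii_mm`` are the annulus outer edges (ascending, starting after 0);
    ``density`` holds one value per annulus. Total mass over the disc of the
    largest radius is normalized to 1.
    """

    radii_mm: np.ndarray
    density: np.ndarray
    r_eq_mm: float

    def __post_init__(self):
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.radii_mm.shape != self.density.shape:
            raise ValueError("radii and density must align")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        mass = self.mass()
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"kernel mass {mass} not normalized to 1")
        if not (0 < self.r_eq_mm <= self.radii_mm[-1]):
            raise ValueError("equivalent radius must lie within the kernel support")

    def _edges(self) -> np.ndarray:
        return np.concatenate([[0.0], self.radii_mm])

    def mass(self) -> float:
        edges = self._edges()
        areas = np.pi * np.diff(edges**2)
        return float(np.sum(self.density * areas))

    def cumulative(self, r) -> np.ndarray:
        """Mass inside radius r (vectorized)."""
        edges = self._edges()
        cum_edges = np.concatenate([[0.0], np.cumsum(self.density * np.pi * np.diff(edges**2))])
        rc = np.clip(np.asarray(r, dtype=float), 0.0, edges[-1])
        k = np.clip(np.searchsorted(edges, rc, side="right") - 1, 0, len(self.density) - 1)
        return cum_edges[k] + self.density[k] * np.pi * (rc**2 - edges[k] ** 2)

    def density_at(self, r) -> np.ndarray:
        """Per-area density at radius r; 0 beyond the support."""
        r = np.asarray(r, dtype=float)
        edges = self._edges()
        idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(self.density) - 1)
        out = self.density[idx]
        return np.where(r > self.radii_mm[-1], 0.0, out)

    @classmethod
    def gaussian(cls, sigma_mm: float, r_max_mm: float | None = None, n_annuli: int = 64,
                 r_eq_quantile: float = 0.9) -> "RadialKernel":
        """Discretized Gaussian radial density exp(−r²/2σ²), mass-normalized."""
        if r_max_mm is None:
            r_max_mm = 4.0 * sigma_mm
        edges = np.linspace(0.0, r_max_mm, n_annuli + 1)
        # exact Gaussian mass per annulus / annulus area
        mass = np.exp(-edges[:-1] ** 2 / (2 * sigma_mm**2)) - np.exp(
            -edges[1:] ** 2 / (2 * sigma_mm**2)
        )
        mass = mass / mass.sum()
        density = mass / (np.pi * np.diff(edges**2))
        cum = np.cumsum(mass)
        r_eq = float(np.interp(r_eq_quantile, np.concatenate([[0], cum]), edges))
        return cls(edges[1:], density, r_eq)


@dataclass
class SigmoidFit:
    """Logistic fit lo + (hi − lo)/(1 + exp(−(x − x0)/s))."""

    midpoint_mm: float
    scale_mm: float
    lo: float
    hi: float
    rmse: float

    def __post_init__(self):
        if self.scale_mm <= 0:
            raise ValueError("scale must be positive")
        if not self.hi > self.lo:
            raise ValueError("hi asymptote must exceed lo")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.lo + (self.hi - self.lo) / (1 + np.exp(-(x - self.midpoint_mm) / self.scale_mm))

    def profile(self, distance_mm):
        """Lateral sensitivity profile: peak-normalized derivative of the logistic.

        The side-to-side experiment records an edge response; its spatial
        derivative is the probe's lateral weight, 1 at the center and
        decaying over the logistic scale.
        """
        d = np.abs(np.asarray(distance_mm, dtype=float))
        e = np.exp(-d / self.scale_mm)
        return 4.0 * e / (1 + e) ** 2


@dataclass
class DepthProfile:
    """Exponential depth sensitivity w(z) = exp(−z/δ)."""

    delta_mm: float

    def __post_init__(self):
        if self.delta_mm <= 0:
            raise ValueError("decay constant must be positive")

    def weight(self, z_mm):
        return np.exp(-np.asarray(z_mm, dtype=float) / self.delta_mm)

    def effective_depth(self, thickness_mm):
        """d_eff(H) = δ (1 − e^{−H/δ}): integral of w over the slab."""
        h = np.asarray(thickness_mm, dtype=float)
        return self.delta_mm * (1 - np.exp(-h / self.delta_mm))

    def depth_factor(self, thickness_mm):
        """ρ = d_eff/H ∈ (0, 1), decreasing in H."""
        h = np.asarray(thickness_mm, dtype=float)
        return self.effective_depth(h) / h

    @classmethod
    def from_depth_factor(cls, rho: float, thickness_mm: float) -> "DepthProfile":
        """Solve δ(1 − e^{−H/δ}) = ρ·H for δ given a measured depth factor."""
        if not 0 < rho < 1:
            raise ValueError("depth factor must be in (0, 1)")
        target = rho * thickness_mm

        def f(delta):
            return delta * (1 - np.exp(-thickness_mm / delta)) - target

        # d_eff is increasing in δ with range (0, H)
        lo, hi = 1e-6, thickness_mm * 1e6
        return cls(float(brentq(f, lo, hi, xtol=1e-12)))


def invert_radial_kernel(
    curve: CumulativeResponseCurve,
    r_eq_quantile: float = 0.9,
    monotone_tol: float = 0.05,
) -> RadialKernel:
    """Invert a center-to-edge cumulative curve to the radial density.

    The response to a centered cylinder of diameter D is the kernel mass
    within radius D/2, so successive differences divided by annulus areas
    recover the density. Measurement noise is cleaned up with isotonic
    regression first; annuli driven negative by residual noise are floored
    at zero and the total mass renormalized.
    """
    if len(curve.sizes_mm) < 3:
        raise ValueError("need at least 3 diameters")
    if curve.sizes_mm[0] <= 0:
        raise ValueError("first diameter must be positive")
    iso = isotonic_regression(curve.response).x
    if np.max(np.abs(iso - curve.response)) > monotone_tol:
        raise ValueError(
            "cumulative curve is non-monotone beyond tolerance "
            f"{monotone_tol}; not a valid center-to-edge response"
        )
    radii = curve.sizes_mm / 2.0
    edges = np.concatenate([[0.0], radii])
    increments = np.diff(np.concatenate([[0.0], iso]))
    areas = np.pi * np.diff(edges**2)
    density = np.maximum(increments, 0.0) / areas
    mass = np.sum(density * areas)
    if mass <= 0:
        raise ValueError("curve carries no mass")
    density = density / mass
    cum = np.cumsum(density * areas)
    r_eq = float(np.interp(r_eq_quantile, np.concatenate([[0.0], cum]), edges))
    return RadialKernel(radii, density, r_eq)


def fit_sigmoid(curve: CumulativeResponseCurve) -> SigmoidFit:
    """Least-squares logistic fit of a sensitivity curve."""
    x, y = curve.sizes_mm, curve.response
    if len(x) < 4:
        raise ValueError("need at least 4 points for a 4-parameter logistic")
    span = y.max() - y.min()
    if span < 1e-9:
        raise ValueError("constant curve: logistic scale is unidentifiable")

    def logistic(x, x0, s, lo, hi):
        z = np.clip((x - x0) / s, -500, 500)
        return lo + (hi - lo) / (1 + np.exp(-z))

    # midpoint guess: crossing of the half-range level
    half = y.min() + span / 2
    x0_guess = float(np.interp(half, y, x)) if y[-1] > y[0] else float(x[len(x) // 2])
    p0 = [x0_guess, (x[-1] - x[0]) / 6, float(y.min()), float(y.max())]
    try:
        popt, _ = curve_fit(logistic, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"sigmoid fit did not converge (initial guess {p0}): {err}") from err
    x0, s, lo, hi = popt
    if s < 0:  # same curve with swapped asymptotes; store the canonical increasing form
        s, lo, hi = -s, hi, lo
    rmse = float(np.sqrt(np.mean((logistic(x, x0, s, lo, hi) - y) ** 2)))
    return SigmoidFit(float(x0), float(s), float(lo), float(hi), rmse)


def fit_depth_profile(thickness_mm, visibility) -> DepthProfile:
    """Fit V(t) = 1 − exp(−t/δ) to a visibility–thickness curve."""
    t = np.asarray(thickness_mm, dtype=float)
    v = np.asarray(visibility, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValueError("need aligned arrays with at least 3 points")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("visibility must lie in [0, 1]")
    if np.ptp(v) < 1e-12:
        raise ValueError("all-equal visibility: decay constant is unidentifiable")

    def model(t, delta):
        return 1 - np.exp(-t / delta)

    # guess from the first sub-saturation point
    mask = (v > 0.05) & (v < 0.95)
    d0 = float(t[mask][0] / -np.log(1 - v[mask][0])) if np.any(mask) else float(np.median(t))
    popt, _ = curve_fit(model, t, v, p0=[d0], maxfev=10000)
    return DepthProfile(float(popt[0]))


def effective_depth(profile: DepthProfile, hole_depth_mm: float) -> float:
    """Effective penetration depth for a slab of the given thickness."""
    if hole_depth_mm <= 0:
        raise ValueError("thickness must be positive")
    return float(profile.effective_depth(hole_depth_mm))
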
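"""Synthetic specimen phantoms and forward simulation of the measurement chain.

Emulates the study's ex vivo design at desk scale: flat-faced bone halves
with a low, spatially correlated baseline permittivity (means ≈ 1.13–1.79),
regular matrices of Ø 2 mm × 8 mm holes at 4-mm centers (16/20/25 holes per
specimen) filled with a high-permittivity gel, a 16×16 effective measurement
grid acquired at four 90° rotations with per-antenna gain variation
(inter-antenna CV ≈ 8%), optional raw S11 sweeps with embedded error terms,
and synthetic CT volumes whose empty/filled hole HU distributions match the
reported group statistics (empty mean 25 HU SD 73, max 132; filled mean
482 HU SD 132, min 388).

Every random draw flows from a single seeded generator per dataset, with
sub-generators derived deterministically per specimen, so identical
configurations yield identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal, stats
from scipy.ndimage import gaussian_filter

from .mapping import AcquisitionGeometry, CoarseGrid
from .probe_model import (
    GLYCOL_22C,
    SHORT,
    WATER_22C,
    DebyeLiquid,
    ErrorTerms,
    ProbeParams,
    S11Sweep,
    debye_permittivity,
    embed,
    forward_gamma,
)
from .sensitivity import DepthProfile, RadialKernel

__all__ = [
    "Hole",
    "SpecimenPhantom",
    "AntennaGainProfile",
    "SpecimenSpec",
    "StudyConfig",
    "SpecimenDataset",
    "StudyDataset",
    "DEFAULT_SPECIMENS",
    "make_phantom",
    "simulate_coarse_grids",
    "simulate_s11_layer",
    "default_error_terms",
    "simulate_ct",
    "generate_study",
    "inter_antenna_cv",
]

FINE_STEP_MM = 0.5


@dataclass
class Hole:
    center_mm: tuple  # (y, x) in the measurement-grid frame
    diameter_mm: float = 2.0
    depth_mm: float = 8.0
    fill_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError("fill fraction must be in [0, 1]")


@dataclass
class SpecimenPhantom:
    """Ground-truth 2-D baseline field plus the drilled-hole list.

    Coordinates are the measurement-grid frame: effective cell centers at
    (0, 4, …, 60) mm on both axes; the phantom extends ``margin_mm`` beyond
    on every side.
    """

    baseline_eps: np.ndarray  # fine field at FINE_STEP_MM resolution
    margin_mm: float
    holes: list
    eps_fluid: float
    specimen_id: str = ""

    def __post_init__(self):
        centers = [h.center_mm for h in self.holes]
        for i, a in enumerate(centers):
            for b in centers[i + 1:]:
                if np.hypot(a[0] - b[0], a[1] - b[1]) < 4.0 - 1e-9:
                    raise ValueError("hole centers must be at least 4 mm apart")

    def fine_coords(self):
        n = self.baseline_eps.shape[0]
        return -self.margin_mm + np.arange(n) * FINE_STEP_MM

    def field(self, condition: str, depth_profile: DepthProfile) -> np.ndarray:
        """Fine-grid permittivity field for 'pre' or 'post'.

        Post-injection, each hole's footprint carries the CRIM mixture of
        the fluid column visible to the probe: the depth-weighted visible
        fluid fraction is (1 − e^{−fH/δ})/(1 − e^{−H/δ}) of the sensed slab.
        """
        if condition == "pre":
            return self.baseline_eps.copy()
        if condition != "post":
            raise ValueError("condition must be 'pre' or 'post'")
        c = self.fine_coords()
        yy, xx = np.meshgrid(c, c, indexing="ij")
        sqrt_eps = np.sqrt(self.baseline_eps)
        for h in self.holes:
            if h.fill_fraction == 0:
                continue
            delta = depth_profile.delta_mm
            vis = (1 - np.exp(-h.fill_fraction * h.depth_mm / delta)) / (
                1 - np.exp(-h.depth_mm / delta)
            )
            mask = (yy - h.center_mm[0]) ** 2 + (xx - h.center_mm[1]) ** 2 <= (
                h.diameter_mm / 2
            ) ** 2
            sqrt_eps[mask] = sqrt_eps[mask] + vis * (
                np.sqrt(self.eps_fluid) - sqrt_eps[mask]
            )
        return sqrt_eps**2

    def true_depth_visible_ul(self, depth_profile: DepthProfile) -> float:
        """Depth-scaled ground-truth volume the probe can see, in μL."""
        total = 0.0
        for h in self.holes:
            area = np.pi * (h.diameter_mm / 2) ** 2
            total += area * depth_profile.delta_mm * (
                1 - np.exp(-h.fill_fraction * h.depth_mm / depth_profile.delta_mm)
            )
        return total

    def true_injected_ul(self) -> float:
        return sum(
            np.pi * (h.diameter_mm / 2) ** 2 * h.depth_mm * h.fill_fraction for h in self.holes
        )


@dataclass
class AntennaGainProfile:
    """Multiplicative per-antenna gains for the 16-element array."""

    gains: np.ndarray
    target_cv: float

    def __post_init__(self):
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (16,):
            raise ValueError("need exactly 16 gains")
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")
        realized = self.gains.std(ddof=1) / self.gains.mean()
        if abs(realized - self.target_cv) > 0.2 * self.target_cv:
            raise ValueError(
                f"realized gain CV {realized:.3f} departs from target {self.target_cv:.3f}"
            )

    @classmethod
    def draw(cls, target_cv: float, rng: np.random.Generator) -> "AntennaGainProfile":
        z = rng.standard_normal(16)
        z = (z - z.mean()) / z.std(ddof=1)
        gains = 1.0 + target_cv * z
        gains = np.clip(gains, 0.05, None)
        return cls(gains, target_cv)


def _hole_layout(n_holes: int, start_mm: float = 24.0, pitch_mm: float = 4.0):
    """Regular drill layout on the 4-mm lattice: 16→4×4, 20→5×4, 25→5×5."""
    shapes = {16: (4, 4), 20: (5, 4), 25: (5, 5)}
    if n_holes == 0:
        return []
    if n_holes in shapes:
        rows, cols = shapes[n_holes]
    else:
        rows = int(np.ceil(np.sqrt(n_holes)))
        cols = int(np.ceil(n_holes / rows))
    centers = []
    for i in range(rows):
        for j in range(cols):
            if len(centers) < n_holes:
                centers.append((start_mm + i * pitch_mm, start_mm + j * pitch_mm))
    return centers


def make_phantom(
    n_holes: int,
    baseline_mean: float = 1.5,
    baseline_sd: float = 0.12,
    eps_fluid: float = 62.0,
    seed: int | np.random.Generator = 0,
    margin_mm: float = 8.0,
    correlation_mm: float = 8.0,
    specimen_id: str = "",
    fill_fraction: float = 1.0,
) -> SpecimenPhantom:
    """Build a phantom with a smooth Gaussian-random baseline field.

    The baseline is white noise smoothed to the requested correlation
    length, then rescaled to the requested mean/SD and floored just above
    the vacuum permittivity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extent = 60.0 + 2 * margin_mm
    n = int(round(extent / FINE_STEP_MM)) + 1
    white = rng.standard_normal((n, n))
    smooth = gaussian_filter(white, sigma=correlation_mm / FINE_STEP_MM, mode="reflect")
    smooth = (smooth - smooth.mean()) / smooth.std()
    fld = baseline_mean + baseline_sd * smooth
    fld = np.maximum(fld, 1.01)
    holes = [Hole(c, fill_fraction=fill_fraction) for c in _hole_layout(n_holes)]
    for h in holes:
        if not (-margin_mm < h.center_mm[0] < 60 + margin_mm
                and -margin_mm < h.center_mm[1] < 60 + margin_mm):
            raise ValueError("hole layout does not fit the specimen extent")
    return SpecimenPhantom(fld, margin_mm, holes, eps_fluid, specimen_id)


def _kernel_fine(kernel: RadialKernel):
    """Kernel sampled on the fine grid, renormalized to unit discrete mass."""
    r_max = kernel.radii_mm[-1]
    n = int(np.ceil(r_max / FINE_STEP_MM))
    c = np.arange(-n, n + 1) * FINE_STEP_MM
    yy, xx = np.meshgrid(c, c, indexing="ij")
    k = kernel.density_at(np.hypot(yy, xx))
    return k / k.sum()


def simulate_coarse_grids(
    phantom: SpecimenPhantom,
    geometry: AcquisitionGeometry,
    kernel: RadialKernel,
    depth_profile: DepthProfile,
    gains: AntennaGainProfile,
    noise_sd: float,
    condition: str,
    rng: np.random.Generator,
) -> list:
    """Forward-simulate the four per-rotation 16×16 measurement matrices.

    Each effective antenna reads the kernel-weighted mean of the (CRIM-mixed,
    depth-weighted) permittivity field over its footprint, multiplied by its
    physical antenna's gain, plus Gaussian noise. Rotating the array keeps
    the antenna layout fixed in the measurement frame while the specimen
    field appears rotated.
    """
    fld = phantom.field(condition, depth_profile)
    # footprint mixing follows the CRIM rule: the probe reads the square of
    # the kernel-weighted refractive index, not the kernel-weighted ε
    smoothed = signal.fftconvolve(np.sqrt(fld), _kernel_fine(kernel), mode="same") ** 2
    coords = phantom.fine_coords()
    yy, xx = geometry.cell_centers_mm()
    iy = np.searchsorted(coords, yy[:, 0] - 1e-9)
    ix = np.searchsorted(coords, xx[0, :] - 1e-9)
    if iy.max() >= len(coords) or ix.max() >= len(coords):
        raise ValueError("measurement footprint exceeds the phantom extent")
    readings_spec = smoothed[np.ix_(iy, ix)]  # specimen frame, noise/gain-free
    base_ids = geometry.antenna_id_map()
    grids = []
    for rot in geometry.rotations_deg:
        k = (rot // 90) % 4
        field_meas = np.rot90(readings_spec, -k)
        vals = field_meas * gains.gains[base_ids] + rng.normal(0.0, noise_sd, (16, 16))
        grids.append(
            CoarseGrid(vals, rotation_deg=rot, condition=condition,
                       specimen=phantom.specimen_id, antenna_ids=base_ids.copy())
        )
    return grids


def default_error_terms(frequencies_hz) -> ErrorTerms:
    """Plausible flat one-port error terms for simulation."""
    f = np.asarray(frequencies_hz, dtype=float)
    ones = np.ones_like(f, dtype=complex)
    return ErrorTerms(f, (0.05 + 0.02j) * ones, (0.93 - 0.05j) * ones, (-0.04 + 0.01j) * ones)


def simulate_s11_layer(
    grid: CoarseGrid,
    params: ProbeParams,
    terms: ErrorTerms,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    frequencies_hz: np.ndarray | None = None,
):
    """Expand a coarse grid into raw embedded S11 sweeps plus standards.

    Each cell's scalar permittivity becomes a flat spectrum; the forward
    Stuchly reflection is embedded with the given error terms. The returned
    standards (open/short/water/glycol) are embedded the same way so the
    full calibration path can be exercised.
    """
    if frequencies_hz is None:
        frequencies_hz = np.linspace(2.25e9, 3.0e9, 101)
    f = np.asarray(frequencies_hz, dtype=float)

    def embedded(gamma_flat, label):
        sweep = S11Sweep(f, gamma_flat, label=label)
        out = embed(sweep, terms)
        if noise_sd > 0:
            if rng is None:
                raise ValueError("need an rng when noise_sd > 0")
            noise = rng.normal(0, noise_sd, f.shape) + 1j * rng.normal(0, noise_sd, f.shape)
            out = S11Sweep(f, out.gamma + noise, label=label)
        return out

    cells = {}
    for i in range(16):
        for j in range(16):
            g = forward_gamma(np.full(f.shape, grid.values[i, j], dtype=complex), f, params)
            cells[(i, j)] = embedded(g, f"cell_{i}_{j}")
    standards = {
        "open": (embedded(forward_gamma(np.ones(f.shape, dtype=complex), f, params), "open"),
                 debye_permittivity(DebyeLiquid(1.0, 1.0, 1e-12, name="air"), f)),
        "short": (embedded(np.full(f.shape, -1.0 + 0j), "short"), SHORT),
        "water": (embedded(forward_gamma(debye_permittivity(WATER_22C, f).eps_complex, f, params),
                           "water"), debye_permittivity(WATER_22C, f)),
        "glycol": (embedded(forward_gamma(debye_permittivity(GLYCOL_22C, f).eps_complex, f,
                                          params), "glycol"), debye_permittivity(GLYCOL_22C, f)),
    }
    return cells, standards


def simulate_ct(
    phantom: SpecimenPhantom,
    condition: str,
    rng: np.random.Generator,
    spacing_mm: tuple = (0.94, 0.94, 3.0),
    background_hu: float = 150.0,
    empty_mean_sd: tuple = (25.0, 73.0),
    filled_mean_sd: tuple = (482.0, 132.0),
    empty_max_hu: float = 132.0,
    filled_min_hu: float = 388.0,
    truncate: bool = True,
):
    """Synthetic CT of the flat face: drill-axis along z.

    Voxels inside a hole draw from the empty or filled HU distribution
    (truncated by default so the two populations keep the non-overlapping
    extremes observed in the bench data); everything else is trabecular
    background. Returns the volume together with the hole layout so the
    CT reference chain can run without shared state.
    """
    from .ct_reference import CTVolume

    extent = 60.0 + 2 * phantom.margin_mm
    sx, sy, sz = spacing_mm
    nx = int(np.floor(extent / sx))
    ny = int(np.floor(extent / sy))
    nz = max(int(np.ceil(8.0 / sz)) + 1, 4)
    hu = np.full((nx, ny, nz), background_hu)
    origin = (-phantom.margin_mm, -phantom.margin_mm, 0.0)
    xc = origin[0] + (np.arange(nx) + 0.5) * sx
    yc = origin[1] + (np.arange(ny) + 0.5) * sy
    zc = (np.arange(nz) + 0.5) * sz

    def draw(mean, sd, lo, hi, size):
        if truncate:
            a = (lo - mean) / sd
            b = (hi - mean) / sd
            return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
        return rng.normal(mean, sd, size=size)

    for h in phantom.holes:
        cy, cx = h.center_mm  # phantom stores (y, x); CT x-axis is first index
        in_circle = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2 <= (h.diameter_mm / 2) ** 2
        in_depth = zc <= h.depth_mm
        filled_depth = h.fill_fraction * h.depth_mm if condition == "post" else 0.0
        for kz in np.flatnonzero(in_depth):
            n_vox = int(in_circle.sum())
            if zc[kz] <= filled_depth:
                vals = draw(filled_mean_sd[0], filled_mean_sd[1], filled_min_hu, np.inf, n_vox)
            else:
                vals = draw(empty_mean_sd[0], empty_mean_sd[1], -1000.0, empty_max_hu, n_vox)
            sub = hu[:, :, kz]
            sub[in_circle] = vals
    return CTVolume(hu, spacing_mm=spacing_mm, origin_mm=origin)


#: Specimen specifications mirroring the seven study samples: hole counts
#: A,B,G = 16; E,F = 20; C,D = 25, with the per-specimen baseline
#: permittivity statistics reported for the array.
DEFAULT_SPECIMENS = (
    ("A", 16, 1.771, 0.185),
    ("B", 16, 1.789, 0.162),
    ("C", 25, 1.646, 0.112),
    ("D", 25, 1.357, 0.114),
    ("E", 20, 1.386, 0.127),
    ("F", 20, 1.378, 0.114),
    ("G", 16, 1.134, 0.062),
)


@dataclass
class SpecimenSpec:
    name: str
    n_holes: int
    baseline_mean: float
    baseline_sd: float
    fill_fraction: float = 1.0


@dataclass
class StudyConfig:
    """Conditions of a simulated study; defaults mirror the bench study."""

    specimens: list = field(default_factory=lambda: [SpecimenSpec(*s) for s in DEFAULT_SPECIMENS])
    seed: int = 0
    noise_sd: float = 0.02
    gain_cv: float = 0.082
    eps_fluid: float = 62.0
    kernel_sigma_mm: float = 2.0
    depth_factor: float = 0.16875
    hole_depth_mm: float = 8.0
    pixel_size_mm: float = 0.5
    correlation_mm: float = 8.0

    @classmethod
    def synthetic(cls, n_specimens: int, seed: int = 0, **kwargs) -> "StudyConfig":
        """A study of ``n_specimens`` cycling through the seven reference specs."""
        base = [SpecimenSpec(*s) for s in DEFAULT_SPECIMENS]
        specs = [
            SpecimenSpec(f"S{i:02d}", base[i % 7].n_holes, base[i % 7].baseline_mean,
                         base[i % 7].baseline_sd)
            for i in range(n_specimens)
        ]
        return cls(specimens=specs, seed=seed, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["specimens"] = [SpecimenSpec(**s) for s in d.get("specimens", [])]
        return cls(**d)


@dataclass
class SpecimenDataset:
    spec: SpecimenSpec
    phantom: SpecimenPhantom
    grids: dict  # condition -> list of 4 CoarseGrid
    ct: dict  # condition -> CTVolume
    gains: AntennaGainProfile
    truth: dict


@dataclass
class StudyDataset:
    config: StudyConfig
    geometry: AcquisitionGeometry
    kernel: RadialKernel
    depth_profile: DepthProfile
    specimens: list


def generate_study(config: StudyConfig) -> StudyDataset:
    """Simulate the full study: phantoms, pre/post grids, CT, ground truth."""
    master = np.random.default_rng(config.seed)
    geometry = AcquisitionGeometry()
    kernel = RadialKernel.gaussian(config.kernel_sigma_mm)
    depth = DepthProfile.from_depth_factor(config.depth_factor, config.hole_depth_mm)
    specimens = []
    for spec in config.specimens:
        sub = np.random.default_rng(master.integers(0, 2**31 - 1))
        phantom = make_phantom(
            spec.n_holes, spec.baseline_mean, spec.baseline_sd, config.eps_fluid,
            seed=sub, correlation_mm=config.correlation_mm, specimen_id=spec.name,
            fill_fraction=spec.fill_fraction,
        )
        gains = AntennaGainProfile.draw(config.gain_cv, sub)
        grids = {
            cond: simulate_coarse_grids(phantom, geometry, kernel, depth, gains,
                                        config.noise_sd, cond, sub)
            for cond in ("pre", "post")
        }
        ct = {cond: simulate_ct(phantom, cond, sub) for cond in ("pre", "post")}
        truth = {
            "injected_ul": phantom.true_injected_ul(),
            "depth_visible_ul": phantom.true_depth_visible_ul(depth),
            "n_holes": spec.n_holes,
        }
        specimens.append(SpecimenDataset(spec, phantom, grids, ct, gains, truth))
    return StudyDataset(config, geometry, kernel, depth, specimens)


def inter_antenna_cv(pre_grids) -> float:
    """CV across the 16 physical antennas of their mean baseline readings.

    Mirrors the bench inter-antenna uniformity analysis: every physical
    antenna's readings are averaged over all cells and rotations of the
    pre-injection acquisitions, then the CV of the 16 means is taken.
    """
    sums = np.zeros(16)
    counts = np.zeros(16)
    for g in pre_grids:
        if g.antenna_ids is None:
            raise ValueError("grids need antenna-id maps")
        np.add.at(sums, g.antenna_ids.ravel(), g.values.ravel())
        np.add.at(counts, g.antenna_ids.ravel(), 1)
    means = sums / counts
    return float(100.0 * means.std(ddof=1) / means.mean())
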
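"""CT-side reference volumes: cylindrical VOIs, HU thresholding, depth rescaling.

Drilled holes (Ø 2 mm, 8 mm deep, 25.13 μL nominal) are segmented with
cylindrical volumes of interest at the known drill layout, classified
filled/empty by a Hounsfield-unit rule (positive if ≥ 50% of voxels reach
250 HU), assigned the full nominal cylinder volume when positive, and the
resulting totals depth-rescaled to the probe's effective penetration depth
so that CT, injected, and microwave volumes refer to the same sensed slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivity import DepthProfile

__all__ = [
    "CTVolume",
    "HoleVOI",
    "ThresholdDerivation",
    "NOMINAL_HOLE_UL",
    "extract_voi",
    "classify_hole",
    "derive_threshold",
    "ct_volume_from_positives",
    "depth_rescale",
]

#: Nominal drilled-hole volume: π (1 mm)² × 8 mm.
NOMINAL_HOLE_UL = float(np.pi * 1.0**2 * 8.0)


@dataclass
class CTVolume:
    """HU voxel grid. Axes (x, y, z); z is the drill axis into the flat face."""

    hu: np.ndarray
    spacing_mm: tuple = (0.94, 0.94, 3.0)
    origin_mm: tuple = (0.0, 0.0, 0.0)
    orientation: str = "drill-axis-z"

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("CT volume must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms))

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), affine), str(path))


@dataclass
class HoleVOI:
    """Cylindrical volume of interest at a known drill-layout position."""

    center_mm: tuple
    diameter_mm: float = 2.0
    depth_mm: float = 8.0

    @property
    def nominal_volume_ul(self) -> float:
        return float(np.pi * (self.diameter_mm / 2) ** 2 * self.depth_mm)


@dataclass
class ThresholdDerivation:
    """HU-threshold bookkeeping from the empty/filled group extremes."""

    max_empty_hu: float
    min_filled_hu: float
    gap_hu: float
    midpoint_hu: float
    chosen_threshold_hu: float


def extract_voi(vol: CTVolume, hole: HoleVOI) -> np.ndarray:
    """HU values of voxels whose centers fall inside the hole cylinder.

    The cylinder axis runs along z from the flat face (z = 0) to the drill
    depth. Membership is by voxel center — the simplest defensible rule;
    partial-volume effects are a known limitation, not corrected here.
    """
    sx, sy, sz = vol.spacing_mm
    ox, oy, oz = vol.origin_mm
    nx, ny, nz = vol.hu.shape
    cx, cy = hole.center_mm
    r = hole.diameter_mm / 2
    # cylinder must fit inside the grid extent
    if (cx - r < ox or cy - r < oy or cx + r > ox + nx * sx or cy + r > oy + ny * sy
            or hole.depth_mm > nz * sz):
        raise ValueError("cylindrical VOI protrudes past the CT volume bounds")
    xc = ox + (np.arange(nx) + 0.5) * sx
    yc = oy + (np.arange(ny) + 0.5) * sy
    zc = oz + (np.arange(nz) + 0.5) * sz
    in_circle = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2 <= r**2
    in_depth = (zc >= 0) & (zc <= hole.depth_mm)
    vals = vol.hu[in_circle][:, in_depth].ravel()
    if vals.size == 0:
        raise ValueError("VOI contains no voxel centers; check layout vs spacing")
    return vals


def classify_hole(values, threshold_hu: float = 250.0, fraction: float = 0.5) -> bool:
    """Positive iff at least ``fraction`` of voxels reach ``threshold_hu`` (both inclusive)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty voxel list")
    return bool(np.mean(values >= threshold_hu) >= fraction)


def derive_threshold(empty_max_hu: float, filled_min_hu: float,
                     chosen_threshold_hu: float = 250.0) -> ThresholdDerivation:
    """Separation gap and midpoint between the empty and filled HU populations."""
    if filled_min_hu <= empty_max_hu:
        raise ValueError("groups overlap: no clean threshold exists")
    gap = filled_min_hu - empty_max_hu
    midpoint = (empty_max_hu + filled_min_hu) / 2.0
    return ThresholdDerivation(empty_max_hu, filled_min_hu, gap, midpoint, chosen_threshold_hu)


def ct_volume_from_positives(n_positive: int) -> float:
    """Each positive hole contributes the full nominal cylinder volume (μL)."""
    if n_positive < 0:
        raise ValueError("count must be non-negative")
    return n_positive * NOMINAL_HOLE_UL


def depth_rescale(volume_ul: float, profile: DepthProfile, hole_depth_mm: float = 8.0) -> float:
    """Rescale a full-depth volume to the probe's sensed slab: V × d_eff(H)/H."""
    if volume_ul < 0:
        raise ValueError("volume must be non-negative")
    return float(volume_ul * profile.effective_depth(hole_depth_mm) / hole_depth_mm)
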
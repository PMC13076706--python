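"""Assembly of array readings into effective grids and kernel-weighted upscaling.

A 4×4 probe array (16-mm pitch) is stepped through a 4×4 pattern of 4-mm
offsets, interleaving to a 16×16 effective measurement grid with 4-mm
spacing — 256 effective antennas. The whole acquisition is repeated at
four 90° array rotations; per-rotation grids are de-rotated to the common
specimen frame before upscaling and averaging.

Upscaling is a normalized (partition-of-unity) interpolation: each output
pixel is the weighted mean of the coarse readings, with weights given by
the probe's composite sensitivity — radial kernel density times the
lateral profile derived from the side-to-side sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sensitivity import RadialKernel, SigmoidFit

__all__ = [
    "AcquisitionGeometry",
    "CoarseGrid",
    "PermittivityMap",
    "assemble_grid",
    "rotate_to_common",
    "upscale",
    "average_rotations",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Array layout and stepping pattern producing the effective grid."""

    array_shape: tuple = (4, 4)
    antenna_pitch_mm: float = 16.0
    rotations_deg: tuple = (0, 90, 180, 270)

    def __post_init__(self):
        if self.array_shape != (4, 4):
            raise ValueError("only a 4x4 array is supported")
        if self.antenna_pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        if any(r % 90 for r in self.rotations_deg):
            raise ValueError("rotations must be multiples of 90 degrees")

    @property
    def step_mm(self) -> float:
        return self.antenna_pitch_mm / 4.0

    @property
    def effective_shape(self) -> tuple:
        return (16, 16)

    def cell_centers_mm(self):
        """(row, col) -> (y, x) coordinates of each effective cell, mm."""
        coords = np.arange(16) * self.step_mm
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        return yy, xx

    def antenna_id_map(self) -> np.ndarray:
        """Physical antenna (0–15) producing each effective cell at rotation 0."""
        idx = np.arange(16) // 4
        return (idx[:, None] * 4 + idx[None, :]).astype(int)


@dataclass
class CoarseGrid:
    """16×16 effective measurement matrix of real permittivity at 2.5 GHz."""

    values: np.ndarray
    rotation_deg: int = 0
    condition: str = "pre"
    specimen: str = ""
    antenna_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16, 16):
            raise ValueError(f"grid must be 16x16, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if self.rotation_deg % 90:
            raise ValueError("rotation must be a multiple of 90 degrees")
        if self.antenna_ids is not None:
            self.antenna_ids = np.asarray(self.antenna_ids, dtype=int)
            if self.antenna_ids.shape != (16, 16):
                raise ValueError("antenna-id map must be 16x16")


@dataclass
class PermittivityMap:
    """Upscaled 2-D real permittivity image in the specimen frame."""

    pixels: np.ndarray
    pixel_size_mm: float
    origin_mm: tuple = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")


def assemble_grid(readings, geometry: AcquisitionGeometry, rotation_deg: int = 0,
                  condition: str = "pre", specimen: str = "") -> CoarseGrid:
    """Interleave 16 per-position 4×4 blocks into the 16×16 effective grid.

    ``readings`` maps position offsets ``(pi, pj)`` with pi, pj in 0..3 to
    4×4 arrays of antenna readings. Effective cell (4a + pi, 4b + pj) holds
    the reading of antenna (a, b) at position (pi, pj).
    """
    expected = {(i, j) for i in range(4) for j in range(4)}
    missing = expected - set(readings)
    if missing:
        raise ValueError(f"missing positions: {sorted(missing)}")
    grid = np.empty((16, 16))
    for (pi, pj), block in readings.items():
        block = np.asarray(block, dtype=float)
        if block.shape != (4, 4):
            raise ValueError(f"block at position {(pi, pj)} is not 4x4")
        rows = 4 * np.arange(4) + pi
        cols = 4 * np.arange(4) + pj
        grid[np.ix_(rows, cols)] = block
    return CoarseGrid(grid, rotation_deg=rotation_deg, condition=condition,
                      specimen=specimen, antenna_ids=geometry.antenna_id_map())


def rotate_to_common(grid: CoarseGrid) -> CoarseGrid:
    """De-rotate a measured grid into the specimen frame (exact for 90° steps)."""
    if grid.rotation_deg % 90:
        raise ValueError("only multiples of 90 degrees are supported")
    k = (grid.rotation_deg // 90) % 4
    vals = np.rot90(grid.values, k)
    ids = np.rot90(grid.antenna_ids, k) if grid.antenna_ids is not None else None
    return CoarseGrid(vals, rotation_deg=0, condition=grid.condition,
                      specimen=grid.specimen, antenna_ids=ids)


_WEIGHT_CACHE: dict = {}


def _composite_weights(geometry: AcquisitionGeometry, kernel: RadialKernel,
                       lateral: SigmoidFit | None, pixel_size_mm: float):
    """Weight matrix (n_pixels, 256) and the output pixel-grid description."""
    key = (
        geometry,
        kernel.radii_mm.tobytes(),
        kernel.density.tobytes(),
        None if lateral is None else (lateral.midpoint_mm, lateral.scale_mm,
                                      lateral.lo, lateral.hi),
        pixel_size_mm,
    )
    hit = _WEIGHT_CACHE.get(key)
    if hit is not None:
        return hit
    yy, xx = geometry.cell_centers_mm()
    centers = np.column_stack([yy.ravel(), xx.ravel()])  # (256, 2)
    margin = kernel.r_eq_mm
    lo = -margin
    hi = 15 * geometry.step_mm + margin
    n_pix = int(np.floor((hi - lo) / pixel_size_mm)) + 1
    px = lo + np.arange(n_pix) * pixel_size_mm
    pyy, pxx = np.meshgrid(px, px, indexing="ij")
    pix = np.column_stack([pyy.ravel(), pxx.ravel()])  # (n_pix², 2)
    d = np.sqrt(((pix[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    w = kernel.density_at(d)
    if lateral is not None:
        w = w * lateral.profile(d)
    result = (w, (lo, lo), (n_pix, n_pix))
    _WEIGHT_CACHE[key] = result
    return result


def upscale(grid: CoarseGrid, kernel: RadialKernel, lateral: SigmoidFit | None = None,
            pixel_size_mm: float = 0.5,
            geometry: AcquisitionGeometry = AcquisitionGeometry()) -> PermittivityMap:
    """Normalized sensitivity-weighted interpolation onto a fine pixel grid.

    ε(x) = Σ_ij W(‖x − p_ij‖) ε_ij / Σ_ij W — a convex combination, so every
    pixel lies within [min, max] of the coarse readings.
    """
    if grid.rotation_deg != 0:
        raise ValueError("upscale expects a grid already in the common frame")
    if pixel_size_mm >= geometry.step_mm:
        raise ValueError("pixel size must be finer than the effective grid spacing")
    w, origin, shape = _composite_weights(geometry, kernel, lateral, pixel_size_mm)
    wsum = w.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("some pixels receive zero weight; kernel support too small")
    vals = (w @ grid.values.ravel()) / wsum
    return PermittivityMap(
        vals.reshape(shape), pixel_size_mm, origin_mm=origin,
        metadata={"specimen": grid.specimen, "condition": grid.condition},
    )


def average_rotations(maps) -> PermittivityMap:
    """Pixel-wise mean of de-rotated, co-registered maps."""
    maps = list(maps)
    first = maps[0]
    for m in maps[1:]:
        if m.pixels.shape != first.pixels.shape or m.origin_mm != first.origin_mm:
            raise ValueError("maps must share shape and origin")
    mean = np.mean([m.pixels for m in maps], axis=0)
    meta = dict(first.metadata)
    meta["n_averaged"] = len(maps)
    return PermittivityMap(mean, first.pixel_size_mm, first.origin_mm, meta)
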
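"""Signed-distance-field bone drilling.

Material is carried on a regular voxel grid of signed distances (negative
inside bone).  Drilling is constructive-solid-geometry subtraction applied
voxelwise, locally around the tool:

    surface <- max(surface, -tool)

so voxel values only ever increase (material is only removed), the update is
idempotent for a fixed tool pose, and disjoint carves commute exactly.
Surfaces are recovered from the grid with marching cubes; removed volume is
integrated with a sub-voxel smoothed occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .geometry import ConstructionError, RigidPose, ToolShape, TriShell

MM3 = 1e9  # mm^3 per m^3

__all__ = ["SDFGrid", "CarveResult", "carve", "extract_surface",
           "carved_volume", "occupied_volume"]


@dataclass
class SDFGrid:
    """Regular voxel grid of signed distances (metres, negative inside)."""

    origin: np.ndarray        # (3,) m, position of voxel (0,0,0)
    spacing: float            # m, isotropic
    values: np.ndarray        # (nx, ny, nz)
    carved_total_mm3: float = 0.0   # cumulative removed volume

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ConstructionError("voxel spacing must be > 0")
        if not np.isfinite(self.values).all():
            raise ConstructionError("SDF values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "SDFGrid":
        return SDFGrid(self.origin.copy(), self.spacing, self.values.copy(),
                       self.carved_total_mm3)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])

    def voxel_points(self, sl: tuple[slice, slice, slice] | None = None
                     ) -> np.ndarray:
        """World coordinates of the voxel centres in the given index box."""
        sl = sl or (slice(None),) * 3
        axes = [self.axis_coords(i)[sl[i]] for i in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; points outside the grid return +inf
        (treated as far outside material)."""
        pts = np.atleast_2d(pts)
        g = (pts - self.origin) / self.spacing
        out = np.full(len(pts), np.inf)
        dims = np.asarray(self.dims)
        ok = np.all((g >= 0) & (g <= dims - 1), axis=1)
        if not ok.any():
            return out
        gi = g[ok]
        i0 = np.minimum(gi.astype(int), dims - 2)
        f = gi - i0
        v = np.zeros(len(gi))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    v += w * self.values[i0[:, 0] + dx, i0[:, 1] + dy,
                                         i0[:, 2] + dz]
        out[ok] = v
        return out

    def gradient(self, pts: np.ndarray, h: float | None = None) -> np.ndarray:
        """Central-difference gradient of the interpolated field."""
        h = h or 0.5 * self.spacing
        pts = np.atleast_2d(pts)
        grad = np.zeros_like(pts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (self.sample(pts + e) - self.sample(pts - e)) / (2 * h)
        return grad


@dataclass
class CarveResult:
    """Outcome of one carve update."""

    region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    removed_mm3: float
    cumulative_mm3: float

    def __post_init__(self) -> None:
        if self.removed_mm3 < -1e-12:
            raise ValueError("removed volume must be nonnegative")


def _occupancy(values: np.ndarray, spacing: float) -> np.ndarray:
    """Per-voxel material fraction: clamped linear smoothing of the level set
    over one voxel width."""
    return np.clip(0.5 - values / spacing, 0.0, 1.0)


def occupied_volume(sdf: SDFGrid, binary: bool = False) -> float:
    """Total material volume on the grid, in mm^3.

    `binary=True` switches to plain voxel counting (the brute-force oracle
    mode); the default integrates the smoothed occupancy.
    """
    vox = sdf.spacing ** 3
    if binary:
        return float(np.count_nonzero(sdf.values <= 0) * vox * MM3)
    return float(np.sum(_occupancy(sdf.values, sdf.spacing)) * vox * MM3)


def carve(surface: SDFGrid, tool: ToolShape, pose: RigidPose,
          active: bool = True) -> CarveResult:
    """Apply one drilling update: surface <- max(surface, -tool).

    The update is restricted to the voxel box covering the tool (padded by
    one voxel); voxels outside are untouched.  When `active` is False (the
    drill pedal released) nothing changes.
    """
    if not np.isfinite(pose.position).all():
        raise ValueError("tool pose must be finite")
    empty = ((0, 0), (0, 0), (0, 0))
    if not active:
        return CarveResult(empty, 0.0, surface.carved_total_mm3)

    r = tool.bounding_radius() + surface.spacing
    lo = np.floor((pose.position - r - surface.origin) / surface.spacing)
    hi = np.ceil((pose.position + r - surface.origin) / surface.spacing) + 1
    lo = np.clip(lo, 0, np.asarray(surface.dims)).astype(int)
    hi = np.clip(hi, 0, np.asarray(surface.dims)).astype(int)
    if np.any(hi <= lo):
        return CarveResult(empty, 0.0, surface.carved_total_mm3)

    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    pts = surface.voxel_points(sl)
    tool_vals = tool.sdf(pts, pose).reshape(tuple(hi - lo))
    old = surface.values[sl]
    new = np.maximum(old, -tool_vals)

    vox = surface.spacing ** 3
    removed = float(np.sum(_occupancy(old, surface.spacing)
                           - _occupancy(new, surface.spacing)) * vox * MM3)
    surface.values[sl] = new
    surface.carved_total_mm3 += removed
    return CarveResult(tuple((int(lo[i]), int(hi[i])) for i in range(3)),
                       removed, surface.carved_total_mm3)


def extract_surface(sdf: SDFGrid) -> TriShell:
    """Triangle mesh of the zero level set via marching cubes.

    An all-positive grid (no material) yields an empty shell.
    """
    if np.all(sdf.values > 0) or np.all(sdf.values < 0):
        return TriShell(np.zeros((0, 3)), np.zeros((0, 3), int),
                        thickness=sdf.spacing)
    verts, faces, _, _ = measure.marching_cubes(
        sdf.values, level=0.0, spacing=(sdf.spacing,) * 3)
    # weld coincident vertices and drop the degenerate slivers marching
    # cubes emits where the level set grazes a voxel corner
    uniq, inverse = np.unique(verts.round(decimals=12), axis=0,
                              return_inverse=True)
    faces = inverse[faces]
    ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
          & (faces[:, 0] != faces[:, 2]))
    return TriShell(uniq + sdf.origin, faces[ok], thickness=sdf.spacing)


def carved_volume(before: SDFGrid, after: SDFGrid,
                  binary: bool = False) -> float:
    """Volume removed between two states of the same grid, in mm^3.

    Integrates the occupancy decrease voxel by voxel (sub-voxel smoothed, or
    binary counting of {before <= 0 and after > 0} in oracle mode).
    """
    if (before.dims != after.dims or before.spacing != after.spacing
            or not np.allclose(before.origin, after.origin)):
        raise ValueError("grids do not match (origin/spacing/dims)")
    vox = before.spacing ** 3
    if binary:
        mask = (before.values <= 0) & (after.values > 0)
        return float(np.count_nonzero(mask) * vox * MM3)
    diff = (_occupancy(before.values, before.spacing)
            - _occupancy(after.values, after.spacing))
    return float(np.sum(np.maximum(diff, 0.0)) * vox * MM3)
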
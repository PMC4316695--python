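"""Structure handling: contour rasterization, mask warping, DICE, sampling.

Masks are propagated through a displacement field with pull-back
semantics: each output voxel center x looks up the source mask at
x + u(x) by nearest-neighbor interpolation (lookups outside the grid
read as background 0).  Scalar maps are projected onto structures by
trilinear sampling at mask-voxel centers with full-voxel weights; the
resulting (value, weight) samples are the substrate of every volume
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grid_io import (
    DisplacementField,
    GridGeometry,
    ScalarVolume,
    StructureMask,
    assert_same_grid,
)

__all__ = [
    "PlanarContour",
    "StructureSamples",
    "rasterize_contours",
    "warp_mask",
    "dice",
    "sample_structure",
]


@dataclass(frozen=True)
class PlanarContour:
    """A closed in-plane polygon on one axial slice.

    ``vertices`` are (x, y) world coordinates in mm; closure is implicit
    (the last vertex connects back to the first).  At least 3 distinct
    vertices are required.
    """

    slice_index: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        # drop an explicit closing vertex
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(set(verts)) < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", verts)


@dataclass
class StructureSamples:
    """Volume-weighted scalar samples over one structure.

    One (value, weight mm^3) pair per contributing voxel; the weights are
    the v_i of every volume-histogram statistic and sum to the structure's
    total volume.
    """

    values: np.ndarray
    weights: np.ndarray
    label: str = "structure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("sample values must be finite")
        if np.any(self.weights <= 0):
            raise ValueError("sample weights must be positive")

    @property
    def total_volume(self) -> float:
        return float(self.weights.sum())

    def __len__(self) -> int:
        return int(self.values.size)


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray-crossing test, vectorized over query points.

    The half-open comparison (y1 <= p) != (y2 <= p) with a strict
    x-intersection test makes shared edges of adjacent polygons claim each
    on-edge point exactly once (left/bottom inclusive), so tilings rasterize
    without gaps or double counting.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 <= py) != (y2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_contours(
    contours: list[PlanarContour], geom: GridGeometry, label: str = "structure"
) -> StructureMask:
    """Convert per-slice closed polygons into a volume bitmap.

    A voxel is set iff its center lies inside its slice's polygon under the
    even-odd rule (orientation-free); slices without a contour stay empty.
    """
    if not contours:
        raise ValueError("empty contour list")
    occ = np.zeros(geom.dims, dtype=bool)
    xs = geom.origin[0] + geom.spacing[0] * np.arange(geom.dims[0])
    ys = geom.origin[1] + geom.spacing[1] * np.arange(geom.dims[1])
    PX, PY = np.meshgrid(xs, ys, indexing="ij")
    for c in contours:
        if not (0 <= c.slice_index < geom.dims[2]):
            raise ValueError(f"contour slice {c.slice_index} outside grid {geom.dims}")
        verts = np.asarray(c.vertices, dtype=np.float64)
        occ[:, :, c.slice_index] |= _points_in_polygon(PX, PY, verts)
    if not occ.any():
        raise ValueError(f"contours for {label!r} cover no voxel centers")
    return StructureMask(geometry=geom, occupancy=occ, label=label)


def warp_mask(mask: StructureMask, dvf: DisplacementField) -> StructureMask:
    """Propagate a structure bitmap through a displacement field.

    Pull-back resampling with nearest-neighbor interpolation: output voxel
    at world point x holds the source mask value at x + u(x); mapped points
    outside the grid yield background 0 (structures leaving the field of
    view vanish rather than clamp).
    """
    assert_same_grid(mask.geometry, dvf.geometry)
    geom = mask.geometry
    spacing = np.array(geom.spacing)
    idx = np.indices(geom.dims, dtype=np.float64)  # (3, nx, ny, nz)
    # mapped point in index coordinates: i + u_i(x) / s_i (origin cancels)
    mapped = idx + np.moveaxis(dvf.vectors, -1, 0) / spacing[:, None, None, None]
    nearest = np.rint(mapped).astype(np.int64)
    valid = np.ones(geom.dims, dtype=bool)
    for ax, d in enumerate(geom.dims):
        valid &= (nearest[ax] >= 0) & (nearest[ax] < d)
    out = np.zeros(geom.dims, dtype=bool)
    v = valid
    out[v] = mask.occupancy[nearest[0][v], nearest[1][v], nearest[2][v]]
    return StructureMask(geometry=geom, occupancy=out, label=mask.label)


def dice(a: StructureMask, b: StructureMask) -> float:
    """DICE overlap 2 |A and B| / (|A| + |B|) by voxel counting.

    1 when the volumes match perfectly, 0 when they do not overlap at all.
    """
    assert_same_grid(a.geometry, b.geometry)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise ValueError("DICE of two empty masks is undefined (0/0)")
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * inter / (na + nb)


def sample_structure(scalar: ScalarVolume, mask: StructureMask) -> StructureSamples:
    """Project a scalar map onto a structure as volume-weighted samples.

    Trilinear interpolation of the scalar at each set mask-voxel center
    (an exact lookup when, as here, map and mask share one grid), weighted
    by the full voxel volume.
    """
    assert_same_grid(scalar.geometry, mask.geometry)
    if mask.voxel_count == 0:
        raise ValueError(f"structure {mask.label!r} is empty")
    idx = np.argwhere(mask.occupancy).T.astype(np.float64)
    vals = map_coordinates(scalar.values, idx, order=1, mode="nearest")
    weights = np.full(vals.shape, mask.geometry.voxel_volume)
    return StructureSamples(values=vals, weights=weights, label=mask.label)
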
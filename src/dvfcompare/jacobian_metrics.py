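"""Per-voxel Jacobian-determinant and spatial-discrepancy maps.

The Jacobian of the transformation x -> x + u(x) is det(I + nabla u),
the local volume-change factor: J > 1 expansion, J < 1 contraction,
J < 0 physically impossible folding.  The determinant is kept signed —
negative values are the diagnostic of folding, so no absolute value is
taken anywhere.

Derivatives use the immediate one-voxel neighborhood: second-order
central differences normalized by the (possibly anisotropic) voxel
spacing per axis.  The one-voxel boundary shell, where a central
difference is impossible, is set to exactly 1 (identity).
"""

from __future__ import annotations

import numpy as np

from .grid_io import (
    DisplacementField,
    ScalarVolume,
    StructureMask,
    assert_same_grid,
)

__all__ = ["jacobian_map", "sd_map", "fraction_below"]

MM_PER_CM = 10.0


def jacobian_map(field: DisplacementField) -> ScalarVolume:
    """Signed Jacobian determinant det(I + nabla u) at every voxel center.

    Interior voxels use the central-difference displacement gradient
    G[c, d] = (u_c(i + e_d) - u_c(i - e_d)) / (2 s_d), dimensionless.
    Boundary-shell voxels (any index at 0 or dim-1) are set to 1 exactly.

    Requires at least 3 voxels per axis so an interior exists.
    """
    geom = field.geometry
    if any(d < 3 for d in geom.dims):
        raise ValueError(f"grid {geom.dims} has no interior voxels (need >= 3 per axis)")
    u = field.vectors
    nx, ny, nz = geom.dims
    sx, sy, sz = geom.spacing
    core = np.s_[1:-1, 1:-1, 1:-1]

    # G[..., c, d] = d u_c / d x_d on the interior
    G = np.empty((nx - 2, ny - 2, nz - 2, 3, 3), dtype=np.float64)
    G[..., 0] = (u[2:, 1:-1, 1:-1, :] - u[:-2, 1:-1, 1:-1, :]) / (2 * sx)
    G[..., 1] = (u[1:-1, 2:, 1:-1, :] - u[1:-1, :-2, 1:-1, :]) / (2 * sy)
    G[..., 2] = (u[1:-1, 1:-1, 2:, :] - u[1:-1, 1:-1, :-2, :]) / (2 * sz)
    G[..., 0, 0] += 1.0
    G[..., 1, 1] += 1.0
    G[..., 2, 2] += 1.0

    # explicit 3x3 determinant (cheaper than np.linalg.det on the stack)
    a, b, c = G[..., 0, 0], G[..., 0, 1], G[..., 0, 2]
    d, e, f = G[..., 1, 0], G[..., 1, 1], G[..., 1, 2]
    g, h, i = G[..., 2, 0], G[..., 2, 1], G[..., 2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)

    values = np.ones(geom.dims, dtype=np.float64)
    values[core] = det
    return ScalarVolume(geometry=geom, values=values)


def sd_map(field_a: DisplacementField, field_b: DisplacementField) -> ScalarVolume:
    """Spatial discrepancy |u_A - u_B| at every voxel, in cm.

    The Euclidean length of the voxel-wise vector difference between two
    DVFs of the same anatomy — the distance between the two algorithms'
    mapped points, hence between their dose lookup points.  Symmetric in
    its arguments and zero exactly where the vectors agree.
    """
    assert_same_grid(field_a.geometry, field_b.geometry)
    diff = field_a.vectors - field_b.vectors
    values = np.sqrt((diff * diff).sum(axis=-1)) / MM_PER_CM
    return ScalarVolume(geometry=field_a.geometry, values=values)


def fraction_below(
    j: ScalarVolume, mask: StructureMask, threshold: float
) -> float:
    """Fraction of the structure's volume with map value < ``threshold``.

    With threshold 0 this is the folded fraction; thresholds 0.5 and 2
    implement the factor-of-two physicality screen (local volume change
    beyond a factor of two is not credible tissue behavior):
    ``fraction_below(j, m, 0.5)`` below, ``1 - fraction_below(j, m, 2.0)``
    above.
    """
    assert_same_grid(j.geometry, mask.geometry)
    if mask.voxel_count == 0:
        raise ValueError(f"structure {mask.label!r} is empty")
    vals = j.values[mask.occupancy]
    return float(np.count_nonzero(vals < threshold) / vals.size)
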
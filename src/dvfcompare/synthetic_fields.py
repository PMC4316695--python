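"""Analytic deformation fields with closed-form Jacobians.

Every downstream statistic in this package (Jacobian maps, volume
histograms, spatial-discrepancy boundaries) is validated against fields
generated here, because each generated field carries its exact pointwise
displacement gradient and hence an exact Jacobian determinant ground truth.

The generator emulates exhale-to-inhale lung-like motion at desk scale:
a mild affine volume change (overall inflation/deflation) superposed with
axial sinusoids (nonuniform, diaphragm-like compression), plus optional
compactly supported "folding" defects whose Jacobian goes negative — the
kind of physically impossible feature a registration QA tool must flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .grid_io import DisplacementField, GridGeometry, ScalarVolume, StructureMask

__all__ = [
    "AnalyticDeformation",
    "SyntheticCase",
    "SyntheticTruth",
    "DEFAULT_GRID",
    "make_affine_field",
    "make_axial_sinusoid_field",
    "make_sphere_mask",
    "inject_fold",
    "make_synthetic_cohort",
]

#: Desk-scale test grid: deliberately anisotropic spacing so spacing bugs in
#: derivative code cannot hide (clinical grids are 512x512 in-plane with
#: 2.5 mm slices; this is the same aspect scaled for fast tests).
DEFAULT_GRID = GridGeometry(dims=(64, 64, 48), spacing=(1.5, 1.5, 2.5))

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AnalyticDeformation:
    """A deformation with analytic displacement and displacement gradient.

    ``displacement(X, Y, Z)`` returns the mm displacement array of shape
    ``(..., 3)`` at world points; ``gradient(X, Y, Z)`` the dimensionless
    displacement-gradient tensor ``(..., 3, 3)``; ``jacobian_closed_form``
    evaluates det(I + grad) at world points.
    """

    kind: Literal["affine", "axial_sinusoid", "radial", "sum"]
    parameters: dict
    displacement: Callable[..., np.ndarray] = field(repr=False)
    gradient: Callable[..., np.ndarray] = field(repr=False)

    def jacobian_closed_form(self, X, Y, Z) -> np.ndarray:
        """det(I + nabla u) at world points (mm); exact, not finite-differenced."""
        G = self.gradient(X, Y, Z)
        J = np.eye(3) + G
        return np.linalg.det(J)

    def __add__(self, other: "AnalyticDeformation") -> "AnalyticDeformation":
        return AnalyticDeformation(
            kind="sum",
            parameters={"terms": (self.parameters, other.parameters)},
            displacement=lambda X, Y, Z: self.displacement(X, Y, Z)
            + other.displacement(X, Y, Z),
            gradient=lambda X, Y, Z: self.gradient(X, Y, Z) + other.gradient(X, Y, Z),
        )

    def sample(self, geom: GridGeometry) -> DisplacementField:
        """Evaluate the displacement at every voxel center of ``geom``."""
        X, Y, Z = geom.voxel_centers()
        u = self.displacement(X, Y, Z)
        vec = np.empty(geom.dims + (3,), dtype=np.float64)
        vec[...] = u
        return DisplacementField(geometry=geom, vectors=vec)

    def truth_jacobian(self, geom: GridGeometry) -> ScalarVolume:
        """Closed-form Jacobian evaluated at every voxel center."""
        X, Y, Z = geom.voxel_centers()
        vals = np.empty(geom.dims, dtype=np.float64)
        vals[...] = self.jacobian_closed_form(X, Y, Z)
        return ScalarVolume(geometry=geom, values=vals)


def _grid_center(geom: GridGeometry) -> np.ndarray:
    return np.array(
        [o + s * (d - 1) / 2.0 for o, s, d in zip(geom.origin, geom.spacing, geom.dims)]
    )


def affine_deformation(
    A: np.ndarray, t: Sequence[float], center: Sequence[float]
) -> AnalyticDeformation:
    """u(x) = A (x - center) + t, with constant gradient A."""
    A = np.asarray(A, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    c = np.asarray(center, dtype=np.float64)
    if A.shape != (3, 3) or t.shape != (3,):
        raise ValueError("A must be 3x3 and t a 3-vector")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(t))):
        raise ValueError("affine parameters must be finite")

    def disp(X, Y, Z):
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        out = np.empty(np.broadcast(X, Y, Z).shape + (3,), dtype=np.float64)
        for i in range(3):
            out[..., i] = A[i, 0] * dx + A[i, 1] * dy + A[i, 2] * dz + t[i]
        return out

    def grad(X, Y, Z):
        shape = np.broadcast(X, Y, Z).shape
        out = np.empty(shape + (3, 3), dtype=np.float64)
        out[...] = A
        return out

    return AnalyticDeformation(
        kind="affine", parameters={"A": A, "t": t, "center": c}, displacement=disp, gradient=grad
    )


def sinusoid_deformation(a: float, k: float, axis: str) -> AnalyticDeformation:
    """u_axis(x) = a sin(k x_axis); Jacobian 1 + a k cos(k x_axis)."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {tuple(_AXES)}, got {axis!r}")
    if not (np.isfinite(a) and np.isfinite(k)):
        raise ValueError("sinusoid parameters must be finite")
    if abs(a * k) >= 1:
        raise ValueError(
            f"|a*k| = {abs(a * k):.3g} >= 1 would fold the field (negative Jacobian)"
        )
    ax = _AXES[axis]

    def disp(X, Y, Z):
        coord = (X, Y, Z)[ax]
        out = np.zeros(np.broadcast(X, Y, Z).shape + (3,), dtype=np.float64)
        out[..., ax] = a * np.sin(k * coord)
        return out

    def grad(X, Y, Z):
        coord = (X, Y, Z)[ax]
        out = np.zeros(np.broadcast(X, Y, Z).shape + (3, 3), dtype=np.float64)
        out[..., ax, ax] = a * k * np.cos(k * coord)
        return out

    return AnalyticDeformation(
        kind="axial_sinusoid",
        parameters={"a": a, "k": k, "axis": axis},
        displacement=disp,
        gradient=grad,
    )


def make_affine_field(
    A: np.ndarray, t: Sequence[float], geom: GridGeometry = DEFAULT_GRID
) -> tuple[DisplacementField, AnalyticDeformation]:
    """Affine displacement u(x) = A (x - x_c) + t about the grid center x_c.

    The closed-form Jacobian is det(I + A) everywhere.  Returns the sampled
    field together with its analytic description.
    """
    deform = affine_deformation(A, t, _grid_center(geom))
    return deform.sample(geom), deform


def make_axial_sinusoid_field(
    a: float, k: float, axis: str = "z", geom: GridGeometry = DEFAULT_GRID
) -> tuple[DisplacementField, AnalyticDeformation]:
    """Single-axis sinusoidal compression/expansion wave.

    Displacement only along ``axis``: u = a sin(k x_axis), Jacobian
    1 + a k cos(k x_axis).  Mimics diaphragm-like nonuniform compression.
    Requires |a k| < 1 so the Jacobian stays positive.
    """
    deform = sinusoid_deformation(a, k, axis)
    return deform.sample(geom), deform


def make_sphere_mask(
    center: Sequence[float],
    radius: float,
    geom: GridGeometry = DEFAULT_GRID,
    label: str = "sphere",
) -> StructureMask:
    """Phantom organ: voxels whose centers lie within ``radius`` mm of ``center``."""
    if radius <= max(geom.spacing):
        raise ValueError(
            f"radius {radius} mm must exceed the largest voxel spacing {max(geom.spacing)} mm"
        )
    c = np.asarray(center, dtype=np.float64)
    X, Y, Z = geom.voxel_centers()
    r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    occ = r2 <= radius**2
    if not occ.any():
        raise ValueError("sphere does not cover any voxel center (outside grid?)")
    return StructureMask(geometry=geom, occupancy=occ, label=label)


def fold_deformation(
    center: Sequence[float], radius: float, strength: float
) -> AnalyticDeformation:
    """Compactly supported radial inversion bump.

    u(x) = -strength * (x - c) * w(rho), rho = |x - c| / radius, with the
    C^1 bump w(rho) = (1 - rho^2)^2 inside the ball and 0 outside.  At the
    center the displacement gradient is -strength * I, so the Jacobian there
    is (1 - strength)^3 — negative whenever strength > 1.  Outside the ball
    the deformation is exactly zero.
    """
    c = np.asarray(center, dtype=np.float64)
    R = float(radius)
    s = float(strength)

    def _parts(X, Y, Z):
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        rho2 = (dx * dx + dy * dy + dz * dz) / (R * R)
        inside = rho2 < 1.0
        w = np.where(inside, (1.0 - rho2) ** 2, 0.0)
        return dx, dy, dz, rho2, inside, w

    def disp(X, Y, Z):
        dx, dy, dz, rho2, inside, w = _parts(X, Y, Z)
        out = np.zeros(np.broadcast(X, Y, Z).shape + (3,), dtype=np.float64)
        out[..., 0] = -s * dx * w
        out[..., 1] = -s * dy * w
        out[..., 2] = -s * dz * w
        return out

    def grad(X, Y, Z):
        # d/dx_j [ -s d_i w(rho) ] = -s ( delta_ij w + d_i d_j w'(rho^2) * 2 / R^2 )
        # with w as a function of rho^2: w = (1 - rho2)^2, dw/drho2 = -2 (1 - rho2)
        dx, dy, dz, rho2, inside, w = _parts(X, Y, Z)
        dwdr2 = np.where(inside, -2.0 * (1.0 - rho2), 0.0)
        d = np.stack([dx, dy, dz], axis=-1)
        shape = np.broadcast(X, Y, Z).shape
        out = np.zeros(shape + (3, 3), dtype=np.float64)
        for i in range(3):
            for j in range(3):
                out[..., i, j] = -s * (
                    (w if i == j else 0.0) + d[..., i] * d[..., j] * dwdr2 * 2.0 / (R * R)
                )
        return out

    return AnalyticDeformation(
        kind="radial",
        parameters={"center": c, "radius": R, "strength": s},
        displacement=disp,
        gradient=grad,
    )


def inject_fold(
    dvf: DisplacementField,
    center: Sequence[float],
    radius: float,
    strength: float,
) -> DisplacementField:
    """Superpose a folding defect onto a field.

    Adds a compactly supported radial inversion bump centered at ``center``
    (mm) with support radius ``radius`` (mm).  For ``strength > 1`` the bump
    alone has a negative Jacobian at its center; outside the ball the field
    is unchanged bit-exactly.  The bump region must intersect the grid and
    the radius must span at least 3 voxels of the coarsest axis.
    """
    geom = dvf.geometry
    if radius < 3 * min(geom.spacing):
        raise ValueError(f"fold radius {radius} mm must span >= 3 voxels")
    c = np.asarray(center, dtype=np.float64)
    lo = np.array(geom.origin)
    hi = lo + (np.array(geom.dims) - 1) * np.array(geom.spacing)
    if np.any(c + radius < lo) or np.any(c - radius > hi):
        raise ValueError("fold bump region lies entirely outside the grid")
    bump = fold_deformation(c, radius, strength)
    add = bump.sample(geom)
    return DisplacementField(geometry=geom, vectors=dvf.vectors + add.vectors)


# ---------------------------------------------------------------------------
# Synthetic cohorts: each case stands in for one patient's exhale/inhale
# pair registered by two algorithms.
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic case.

    ``jacobian_a`` is the closed-form Jacobian of ``field_a`` at voxel
    centers; ``volume_ratio`` maps structure label to the true total
    volume-change factor over that mask (mask-mean of the closed-form
    Jacobian); ``sd_map_cm`` is the exact pointwise discrepancy between
    the two fields, in cm.
    """

    jacobian_a: ScalarVolume
    volume_ratio: dict[str, float]
    sd_map_cm: ScalarVolume
    peak_discrepancy_mm: float


@dataclass
class SyntheticCase:
    """One synthetic "patient": two DVFs over shared anatomy, with truth."""

    case_id: str
    field_a: DisplacementField
    field_b: DisplacementField
    masks: list[StructureMask]
    truth: SyntheticTruth
    seed: int
    deformation_a: AnalyticDeformation = field(repr=False, default=None)


def _random_smooth_deformation(
    rng: np.random.Generator, geom: GridGeometry
) -> AnalyticDeformation:
    """Affine + up to 3 axial sinusoids, all with analytic gradients."""
    # mild anisotropic volume change: diagonal-dominant A with det(I+A) > 0
    diag = rng.uniform(-0.10, 0.10, size=3)
    off = rng.uniform(-0.02, 0.02, size=(3, 3))
    A = np.diag(diag) + off - np.diag(np.diag(off))
    t = rng.uniform(-3.0, 3.0, size=3)
    deform = affine_deformation(A, t, _grid_center(geom))
    extent = [s * (d - 1) for s, d in zip(geom.spacing, geom.dims)]
    for axis in rng.permutation(["x", "y", "z"])[: rng.integers(1, 4)]:
        # wavelength comparable to the grid extent: low-frequency, smooth
        lam = rng.uniform(0.6, 1.5) * extent[_AXES[axis]]
        k = 2 * np.pi / lam
        ak = rng.uniform(0.05, 0.25)  # |a k| well below folding
        deform = deform + sinusoid_deformation(ak / k, k, axis)
    return deform


def _band_limited_perturbation(
    rng: np.random.Generator, geom: GridGeometry, peak_mm: float
) -> np.ndarray:
    """Smooth random vector perturbation scaled to exact peak magnitude (mm)."""
    if peak_mm == 0:
        return np.zeros(geom.dims + (3,), dtype=np.float64)
    X, Y, Z = geom.voxel_centers()
    extent = [s * (d - 1) for s, d in zip(geom.spacing, geom.dims)]
    out = np.zeros(geom.dims + (3,), dtype=np.float64)
    n_modes = int(rng.integers(4, 9))  # sum of <= 8 low-frequency sinusoids
    for _ in range(n_modes):
        comp = int(rng.integers(0, 3))
        kvec = [2 * np.pi / (rng.uniform(0.8, 2.0) * e) for e in extent]
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.3, 1.0)
        out[..., comp] += amp * (
            np.sin(kvec[0] * X + phase[0])
            * np.sin(kvec[1] * Y + phase[1])
            * np.sin(kvec[2] * Z + phase[2])
        )
    mag = np.sqrt((out**2).sum(axis=-1))
    out *= peak_mm / mag.max()
    return out


def make_synthetic_cohort(
    n_patients: int,
    seed: int,
    discrepancy: float = 0.0,
    geom: GridGeometry = DEFAULT_GRID,
) -> list[SyntheticCase]:
    """Deterministic multi-patient cohort of paired synthetic DVFs.

    Each case holds ``field_a`` (a randomized smooth affine+sinusoid mix
    standing in for one registration algorithm's output) and ``field_b``
    = ``field_a`` + a band-limited perturbation of exact peak magnitude
    ``discrepancy`` mm (the second algorithm).  Two phantom structures are
    attached per case: a large "lung"-like sphere and a small "gtv" sphere.
    ``discrepancy = 0`` makes the two fields identical.  The cohort is a
    pure function of ``(n_patients, seed, discrepancy)``.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    center = _grid_center(geom)
    extent = np.array([s * (d - 1) for s, d in zip(geom.spacing, geom.dims)])
    cases: list[SyntheticCase] = []
    for p in range(n_patients):
        # fixed per-patient stream offset for reproducible fixtures
        rng = np.random.default_rng([int(seed), p])
        deform_a = _random_smooth_deformation(rng, geom)
        field_a = deform_a.sample(geom)
        pert = _band_limited_perturbation(rng, geom, float(discrepancy))
        field_b = DisplacementField(geometry=geom, vectors=field_a.vectors + pert)

        lung = make_sphere_mask(
            center + rng.uniform(-0.02, 0.02, 3) * extent,
            0.30 * extent.min(),
            geom,
            label="lung",
        )
        gtv = make_sphere_mask(
            center + rng.uniform(-0.10, 0.10, 3) * extent,
            0.12 * extent.min(),
            geom,
            label="gtv",
        )
        truth_j = deform_a.truth_jacobian(geom)
        ratios = {
            m.label: float(truth_j.values[m.occupancy].mean()) for m in (lung, gtv)
        }
        sd_cm = ScalarVolume(
            geometry=geom, values=np.sqrt((pert**2).sum(axis=-1)) / 10.0
        )
        cases.append(
            SyntheticCase(
                case_id=f"synth{p:02d}",
                field_a=field_a,
                field_b=field_b,
                masks=[lung, gtv],
                truth=SyntheticTruth(
                    jacobian_a=truth_j,
                    volume_ratio=ratios,
                    sd_map_cm=sd_cm,
                    peak_discrepancy_mm=float(discrepancy),
                ),
                seed=int(seed),
                deformation_a=deform_a,
            )
        )
    return cases
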
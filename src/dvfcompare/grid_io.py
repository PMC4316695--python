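"""Voxel-grid geometry and volumetric I/O for displacement fields and masks.

All volumes in a comparison must live on one axis-aligned voxel lattice
(:class:`GridGeometry`).  Displacements are stored in millimetres with
component order ``(x, y, z)`` matching array axes ``(column, row, slice)``;
vector arrays therefore have shape ``(nx, ny, nz, 3)``.

Supported on-disk formats are NIfTI (via nibabel) and MetaImage MHD/MHA
(via SimpleITK).  Oblique grids (non-identity direction matrices) are
rejected: every voxel-wise operation downstream presumes world axes
aligned with the lattice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "DisplacementField",
    "ScalarVolume",
    "StructureMask",
    "GridMismatchError",
    "assert_same_grid",
    "read_displacement_field",
    "write_displacement_field",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_mask",
    "write_mask",
]

#: Default tolerance (mm) when comparing spacings/origins of two grids.
GRID_TOL_MM = 1e-3

#: Threshold above which a float-stored mask voxel counts as occupied.
MASK_BINARIZE_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """Two volumes do not share a voxel lattice; voxel-wise ops are undefined."""


@dataclass(frozen=True)
class GridGeometry:
    """An axis-aligned regular voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z).  Each must be >= 2.
    spacing
        Voxel edge lengths in mm along (x, y, z).  Strictly positive.
    origin
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must be 3-tuples")
        if any(d < 2 for d in self.dims):
            raise ValueError(f"all dims must be >= 2, got {self.dims}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        if any(not np.isfinite(o) for o in self.origin):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers as three broadcastable axes."""
        axes = []
        for d, s, o in zip(self.dims, self.spacing, self.origin):
            axes.append(o + s * np.arange(d, dtype=np.float64))
        x = axes[0][:, None, None]
        y = axes[1][None, :, None]
        z = axes[2][None, None, :]
        return x, y, z


def assert_same_grid(a: GridGeometry, b: GridGeometry, tol: float = GRID_TOL_MM) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` describe one lattice.

    Dims must match exactly; spacing and origin within ``tol`` mm per component.
    """
    if a.dims != b.dims:
        raise GridMismatchError(f"grid dims differ: {a.dims} vs {b.dims}")
    for name in ("spacing", "origin"):
        va, vb = getattr(a, name), getattr(b, name)
        if any(abs(x - y) > tol for x, y in zip(va, vb)):
            raise GridMismatchError(f"grid {name} differs beyond {tol} mm: {va} vs {vb}")


def _check_volume(geometry: GridGeometry, arr: np.ndarray, ncomp: int | None) -> np.ndarray:
    expected = geometry.dims if ncomp is None else geometry.dims + (ncomp,)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != expected:
        raise ValueError(f"array shape {arr.shape} does not match grid {expected}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values")
    return arr


@dataclass
class DisplacementField:
    """Dense per-voxel displacement u(x) in mm on a :class:`GridGeometry`.

    ``vectors[i, j, k]`` is the 3-vector (ux, uy, uz) at voxel (i, j, k).
    The mapped point of voxel center x is x + u(x).
    """

    geometry: GridGeometry
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vectors = _check_volume(self.geometry, self.vectors, 3)


@dataclass
class ScalarVolume:
    """One real value per voxel (Jacobian map, spatial-discrepancy map, ...)."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _check_volume(self.geometry, self.values, None)


@dataclass
class StructureMask:
    """Binary occupancy volume for one contoured structure."""

    geometry: GridGeometry
    occupancy: np.ndarray = field(repr=False)
    label: str = "structure"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.geometry.dims:
            raise ValueError(
                f"mask shape {occ.shape} does not match grid {self.geometry.dims}"
            )
        if occ.dtype != bool:
            uniq = np.unique(occ)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("occupancy must be strictly binary (0/1)")
            occ = occ.astype(bool)
        self.occupancy = occ

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume


# ---------------------------------------------------------------------------
# Format back-ends.  Internally everything is (nx, ny, nz[, 3]) float64 with
# an axis-aligned world frame; the two dialects are normalized to that.
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "metaimage")

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mhd", ".mha")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    lower = str(path).lower()
    if lower.endswith(_NIFTI_EXT):
        return "nifti"
    if lower.endswith(_META_EXT):
        return "metaimage"
    raise ValueError(f"cannot infer format from extension of {path!r}")


def _read_nifti(path: str) -> tuple[np.ndarray, GridGeometry]:
    import nibabel as nib

    img = nib.load(path)
    affine = img.affine
    rot = affine[:3, :3]
    spacing = tuple(float(s) for s in np.abs(np.diag(rot)))
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6) or np.any(np.diag(rot) <= 0):
        raise ValueError(
            f"{path}: oblique or flipped direction matrix not supported; "
            "grids must be axis-aligned"
        )
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: undefined or non-positive voxel spacing")
    origin = tuple(float(o) for o in affine[:3, 3])
    data = np.asarray(img.dataobj, dtype=np.float64)
    # vector volumes may be stored (nx, ny, nz, 3) or NIfTI-style (nx, ny, nz, 1, 3)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    geom = GridGeometry(dims=tuple(int(d) for d in data.shape[:3]), spacing=spacing, origin=origin)
    return data, geom


def _write_nifti(path: str, data: np.ndarray, geom: GridGeometry, vector: bool) -> None:
    import nibabel as nib

    affine = np.diag(list(geom.spacing) + [1.0])
    affine[:3, 3] = geom.origin
    if vector:
        # 5-D with singleton time axis + vector intent, the NIfTI vector dialect
        stored = np.asarray(data, dtype=np.float64)[:, :, :, None, :]
        img = nib.Nifti1Image(stored, affine)
        img.header.set_intent("vector")
    else:
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)


def _read_metaimage(path: str) -> tuple[np.ndarray, GridGeometry]:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {img.GetDimension()}-D")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(f"{path}: non-identity direction matrix not supported")
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
    if arr.ndim == 4:
        data = np.transpose(arr, (2, 1, 0, 3)).astype(np.float64)
    else:
        data = np.transpose(arr, (2, 1, 0)).astype(np.float64)
    geom = GridGeometry(dims=tuple(int(d) for d in data.shape[:3]), spacing=spacing, origin=origin)
    return data, geom


def _write_metaimage(path: str, data: np.ndarray, geom: GridGeometry, vector: bool) -> None:
    import SimpleITK as sitk

    data = np.asarray(data, dtype=np.float64)
    if vector:
        arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr, isVector=True)
    else:
        arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr)
    img.SetSpacing(geom.spacing)
    img.SetOrigin(geom.origin)
    sitk.WriteImage(img, path)


def _read(path: str, fmt: str | None) -> tuple[np.ndarray, GridGeometry]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    return _read_nifti(path) if fmt == "nifti" else _read_metaimage(path)


def _write(path: str, data: np.ndarray, geom: GridGeometry, fmt: str | None, vector: bool) -> None:
    fmt = _infer_format(path, fmt)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise OSError(f"destination not writable: {path}")
    if fmt == "nifti":
        _write_nifti(path, data, geom, vector)
    else:
        _write_metaimage(path, data, geom, vector)


def read_displacement_field(path: str, format: str | None = None) -> DisplacementField:
    """Read a 3-component vector volume as a :class:`DisplacementField`.

    The header's spacing and origin populate the geometry; components are
    assumed to be millimetres (both supported dialects store mm).  Raises if
    the file holds a scalar or non-3-component volume.
    """
    data, geom = _read(path, format)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(
            f"{path}: not a vector field (expected 3 components, "
            f"got shape {data.shape})"
        )
    return DisplacementField(geometry=geom, vectors=data)


def write_displacement_field(
    field: DisplacementField, path: str, format: str | None = None
) -> None:
    """Write a displacement field losslessly (float64 storage)."""
    _write(path, field.vectors, field.geometry, format, vector=True)


def read_scalar_volume(path: str, format: str | None = None) -> ScalarVolume:
    """Read a single-component volume as a :class:`ScalarVolume`."""
    data, geom = _read(path, format)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(f"{path}: expected a scalar volume, got {data.shape[3]} components")
        data = data[:, :, :, 0]
    return ScalarVolume(geometry=geom, values=data)


def write_scalar_volume(vol: ScalarVolume, path: str, format: str | None = None) -> None:
    _write(path, vol.values, vol.geometry, format, vector=False)


def read_mask(path: str, format: str | None = None, label: str = "structure") -> StructureMask:
    """Read a binary structure mask.

    Any stored voxel value above :data:`MASK_BINARIZE_THRESHOLD` maps to
    occupancy 1 — robust to interpolation residue in float-stored masks.
    """
    data, geom = _read(path, format)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(f"{path}: expected a scalar mask, got {data.shape[3]} components")
        data = data[:, :, :, 0]
    occ = data > MASK_BINARIZE_THRESHOLD
    return StructureMask(geometry=geom, occupancy=occ, label=label)


def write_mask(mask: StructureMask, path: str, format: str | None = None) -> None:
    _write(path, mask.occupancy.astype(np.float64), mask.geometry, format, vector=False)
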
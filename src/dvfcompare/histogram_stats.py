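"""Volume-histogram statistics over structures.

A volume histogram (JVH for Jacobian values, SDVH for spatial
discrepancies) distributes a structure's volume over the values a map
takes on it.  The summary statistics a QA report needs are:

* the volume-weighted mean — for a Jacobian map this is the structure's
  total fractional volume change, (1/V) sum_i v_i J_i;
* the volume-weighted standard deviation — the spread of local volume
  change, the quantity that differs most between registration algorithms;
* fractional-volume tail boundaries J_X / (SD)_X — the minimum value in
  the top-X% sub-volume (high tail) or the maximum value in the
  bottom-X% sub-volume (low tail).

Tail boundaries are computed from exact weighted order statistics, never
from binned histograms, so they are independent of any binning choice;
histograms exist for reporting and plotting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .structure_ops import StructureSamples

__all__ = [
    "VolumeHistogram",
    "TailBoundary",
    "build_histogram",
    "weighted_mean",
    "weighted_std",
    "tail_boundary",
    "sd_boundary_series",
    "jvh_ratio",
    "DEFAULT_X_LIST",
]

#: Default fractional-volume percentages for discrepancy boundary series,
#: 2.5..30% plus the 35% summary boundary.
DEFAULT_X_LIST: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)

#: Default bin count for report histograms (plotting only; all statistics
#: are bin-free).
DEFAULT_N_BINS = 200


@dataclass(frozen=True)
class VolumeHistogram:
    """Differential volume histogram: per-bin volume in mm^3."""

    bin_edges: np.ndarray
    bin_volumes: np.ndarray
    total_volume: float
    label: str = "structure"
    map_name: str = ""

    @property
    def bin_fractions(self) -> np.ndarray:
        return self.bin_volumes / self.total_volume


@dataclass(frozen=True)
class TailBoundary:
    """Boundary value of the top/bottom X% sub-volume of a distribution."""

    X: float
    side: Literal["low", "high"]
    value: float


def build_histogram(
    samples: StructureSamples,
    n_bins: int = DEFAULT_N_BINS,
    range: tuple[float, float] | None = None,
) -> VolumeHistogram:
    """Differential volume histogram of sample values weighted by volume.

    Default range spans [min, max] of the samples with a right-inclusive
    last bin (numpy convention), so the bin volumes always sum to the
    structure's total volume exactly.
    """
    if len(samples) == 0:
        raise ValueError("cannot histogram empty samples")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if range is not None and not (range[1] > range[0]):
        raise ValueError(f"histogram range must increase, got {range}")
    volumes, edges = np.histogram(
        samples.values, bins=n_bins, range=range, weights=samples.weights
    )
    return VolumeHistogram(
        bin_edges=edges,
        bin_volumes=volumes,
        total_volume=samples.total_volume,
        label=samples.label,
    )


def weighted_mean(samples: StructureSamples) -> float:
    """Volume-weighted mean, sum(v_i x_i) / sum(v_i).

    Over a Jacobian map this equals the structure's total volume-change
    factor V_after / V_before under the flow-of-tissue interpretation.
    """
    if len(samples) == 0:
        raise ValueError("empty samples")
    return float(np.average(samples.values, weights=samples.weights))


def weighted_std(samples: StructureSamples) -> float:
    """Volume-weighted population standard deviation.

    sqrt( sum v_i (x_i - mean)^2 / sum v_i ).  Population convention: with
    the >1e4 voxels of any real structure the n-1 correction is negligible,
    and the population form keeps small-fixture tests exact.
    """
    m = weighted_mean(samples)
    var = np.average((samples.values - m) ** 2, weights=samples.weights)
    return float(np.sqrt(var))


def tail_boundary(
    samples: StructureSamples, X: float, side: Literal["low", "high"]
) -> TailBoundary:
    """Boundary value of the X% fractional-volume tail.

    High side: sort values descending and accumulate volume until it first
    reaches >= X% of the total; the boundary is the value of that last
    included sample — the minimum value inside the top-X% sub-volume.
    Low side is the mirror: the maximum value inside the bottom-X%
    sub-volume.  No interpolation between sample values is performed.
    """
    if len(samples) == 0:
        raise ValueError("empty samples")
    if not 0 < X < 100:
        raise ValueError(f"X must be in (0, 100), got {X}")
    if side not in ("low", "high"):
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    order = np.argsort(samples.values, kind="stable")
    if side == "high":
        order = order[::-1]
    cum = np.cumsum(samples.weights[order])
    target = (X / 100.0) * samples.total_volume
    # first sample whose inclusion reaches the target volume
    idx = int(np.searchsorted(cum, target - 1e-12 * samples.total_volume))
    idx = min(idx, len(cum) - 1)
    return TailBoundary(X=float(X), side=side, value=float(samples.values[order[idx]]))


def sd_boundary_series(
    samples: StructureSamples, X_list: Sequence[float] = DEFAULT_X_LIST
) -> list[TailBoundary]:
    """High-side tail boundaries (SD)_X for a series of volume fractions.

    Each value is the smallest discrepancy inside the worst-X% sub-volume;
    the series is non-increasing in X.
    """
    return [tail_boundary(samples, X, "high") for X in X_list]


def jvh_ratio(samples: StructureSamples, contour_volume_ratio: float) -> float:
    """Mean Jacobian normalized to the contour-measured volume change.

    A ratio near 1 means the registration's mean Jacobian reproduces the
    total volume change observed from the delineated contours.
    """
    if not contour_volume_ratio > 0:
        raise ValueError(f"contour volume ratio must be > 0, got {contour_volume_ratio}")
    return weighted_mean(samples) / contour_volume_ratio
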
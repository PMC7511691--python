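"""The two objectives: weighted total effort and the aggregated environmental metric.

Effort encodes the user-perceived difficulty (technical, financial,
socio-political) of reducing each pressure in each region.  Weights come
either as direct per-cell values or from pairwise comparisons ("how much
harder is reducing manure in region A than in region B?") resolved with the
analytic hierarchy process (principal eigenvector + consistency ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basin import Bounds, Strategy, ValidationError

__all__ = [
    "EffortWeights",
    "total_effort",
    "normalized_effort",
    "weights_from_pairwise",
    "cell_weights",
    "aggregate_metric",
    "AGGREGATION_METRICS",
    "InconsistencyWarning",
]

#: The five selectable aggregation operators for the environmental objective.
AGGREGATION_METRICS = ("mean", "median", "q3", "max", "threshold")

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
                8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
                14: 1.57, 15: 1.59}


class InconsistencyWarning(UserWarning):
    """Pairwise judgments are intransitive beyond the conventional CR > 0.1."""


@dataclass(frozen=True)
class EffortWeights:
    """Relative difficulty weight per (region, sector) cell; default all 1."""

    regions: tuple[str, ...]
    sectors: tuple[str, ...]
    values: np.ndarray
    provenance: str = "direct"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.regions), len(self.sectors)):
            raise ValidationError(
                f"weights shape {arr.shape} != ({len(self.regions)}, {len(self.sectors)})"
            )
        if np.any(arr < 0):
            raise ValidationError("effort weights must be non-negative")
        if not np.any(arr > 0):
            warnings.warn("all effort weights are zero: total effort is identically 0")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def equal(cls, regions: Sequence[str], sectors: Sequence[str]) -> "EffortWeights":
        return cls(tuple(regions), tuple(sectors), np.ones((len(regions), len(sectors))))

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.regions), columns=list(self.sectors))


def total_effort(weights: EffortWeights, strategy: Strategy) -> float:
    """E = sum_{a,s} w[a,s] * r[a,s] — linear, monotone in every rate."""
    strategy._check_axes(weights.regions, weights.sectors)
    return float(np.sum(weights.values * strategy.rates))


def normalized_effort(weights: EffortWeights, strategy: Strategy, bounds: Bounds) -> float:
    """Effort rescaled to [0, 1] by the maximum attainable within bounds."""
    emax = total_effort(weights, bounds.max_strategy())
    if emax == 0:
        return 0.0
    return total_effort(weights, strategy) / emax


def _check_reciprocal(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("pairwise matrix must be square")
    if P.shape[0] < 2:
        raise ValidationError("pairwise matrix needs at least 2 items")
    if np.any(P <= 0):
        raise ValidationError("pairwise matrix entries must be positive")
    if not np.allclose(np.diag(P), 1.0, atol=1e-9):
        raise ValidationError("pairwise matrix diagonal must be 1")
    if not np.allclose(P * P.T, 1.0, rtol=1e-9, atol=1e-9):
        raise ValidationError("pairwise matrix is not reciprocal (p[i,j] != 1/p[j,i])")


def weights_from_pairwise(P, warn: bool = True) -> tuple[np.ndarray, float, float]:
    """AHP weights from a reciprocal pairwise comparison matrix.

    Returns ``(weights, lambda_max, CR)``: the normalized principal right
    eigenvector (sums to 1), the principal eigenvalue, and the consistency
    ratio ``CR = ((lambda_max - n) / (n - 1)) / RI(n)``.  Emits an
    :class:`InconsistencyWarning` when CR exceeds the conventional 0.1.
    """
    if isinstance(P, pd.DataFrame):
        P = P.to_numpy(dtype=float)
    P = np.asarray(P, dtype=float)
    _check_reciprocal(P)
    n = P.shape[0]
    eigvals, eigvecs = np.linalg.eig(P)
    k = int(np.argmax(eigvals.real))
    lam_max = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()
    ci = (lam_max - n) / (n - 1)
    ri = RANDOM_INDEX.get(n)
    if ri is None:
        raise ValidationError(f"no random consistency index tabulated for n = {n}")
    cr = 0.0 if ri == 0.0 else max(ci, 0.0) / ri
    if warn and cr > 0.1:
        warnings.warn(
            f"pairwise judgments look inconsistent (CR = {cr:.3f} > 0.1); "
            "consider revising the comparisons",
            InconsistencyWarning,
        )
    return w, lam_max, cr


def cell_weights(
    region_w: Sequence[float],
    sector_w: Sequence[float],
    regions: Sequence[str],
    sectors: Sequence[str],
) -> EffortWeights:
    """Combine region-wise and sector-wise difficulties into per-cell weights.

    w[a, s] = region_w[a] * sector_w[s], rescaled so the mean cell weight is 1
    (keeps effort magnitudes comparable across weightings).
    """
    rw = np.asarray(region_w, dtype=float)
    sw = np.asarray(sector_w, dtype=float)
    if np.any(rw < 0) or np.any(sw < 0):
        raise ValidationError("weight vectors must be non-negative")
    if rw.sum() == 0 or sw.sum() == 0:
        raise ValidationError("weight vectors must not be all zero")
    if len(rw) != len(regions) or len(sw) != len(sectors):
        raise ValidationError("weight vector lengths must match region/sector counts")
    cells = np.outer(rw, sw)
    cells = cells / cells.mean()
    return EffortWeights(tuple(regions), tuple(sectors), cells, provenance="pairwise_product")


def aggregate_metric(
    values,
    metric: str,
    threshold: float | None = None,
    threshold_mode: str = "sum",
) -> float:
    """Reduce per-catchment indicator values to the scalar environmental objective.

    ``metric`` is one of mean, median, q3 (linear-interpolation quantile at
    0.75), max, or threshold.  The threshold operator sums the values of the
    catchments strictly exceeding ``threshold`` (0 when none does); with
    ``threshold_mode="excess"`` it sums the exceedances ``v - T`` instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot aggregate an empty value set")
    if metric == "mean":
        return float(arr.mean())
    if metric == "median":
        return float(np.median(arr))
    if metric == "q3":
        return float(np.quantile(arr, 0.75))  # linear interpolation
    if metric == "max":
        return float(arr.max())
    if metric == "threshold":
        if threshold is None:
            raise ValidationError("threshold metric requires a threshold value")
        over = arr[arr > threshold]
        if threshold_mode == "sum":
            return float(over.sum())
        if threshold_mode == "excess":
            return float((over - threshold).sum())
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    raise ValidationError(f"unknown aggregation metric {metric!r}; choose from {AGGREGATION_METRICS}")
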
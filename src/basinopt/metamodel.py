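"""Linear sensitivity metamodel: the fast surrogate used inside the optimizer.

Instead of re-running an environmental model for every candidate strategy, we
probe it once per driver (one (region, sector) pair) with a small stepwise
reduction and store the per-unit indicator decrease in a sensitivity matrix.
Prediction is then a single matrix-vector product:

    v[c] = max(0, v0[c] - sum_d S[c, d] * r_d)

For the bundled linear engines (nitrogen routing, WEI) the surrogate is exact
to floating-point accuracy for any strategy, not just small ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .basin import Basin, Strategy, ValidationError

__all__ = ["LinearMetamodel", "build_metamodel", "aggregate_values"]

Engine = Callable[[Strategy], pd.Series]


@dataclass
class LinearMetamodel:
    """Baseline indicator values plus a driver sensitivity matrix.

    Attributes
    ----------
    units : catchment (or region) ids the indicator is defined over.
    regions, sectors : decision-table axes; the driver index is the row-major
        flattening (region-major, sectors in canonical order).
    baseline : indicator value per unit under the zero strategy (v0 >= 0).
    sensitivity : (n_units, n_drivers) matrix, S >= 0; column d holds the
        indicator decrease per unit reduction fraction of driver d.
    step : probe fraction used to build the matrix (default 0.01, i.e. the
        1%-reduction convention).
    """

    units: tuple[str, ...]
    regions: tuple[str, ...]
    sectors: tuple[str, ...]
    baseline: np.ndarray
    sensitivity: np.ndarray
    step: float = 0.01

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        n_units = len(self.units)
        n_drivers = len(self.regions) * len(self.sectors)
        if self.baseline.shape != (n_units,):
            raise ValidationError("baseline length does not match units")
        if self.sensitivity.shape != (n_units, n_drivers):
            raise ValidationError(
                f"sensitivity shape {self.sensitivity.shape} != ({n_units}, {n_drivers})"
            )
        if np.any(self.baseline < 0):
            raise ValidationError("baseline indicator values must be non-negative")
        if np.any(self.sensitivity < -1e-9):
            raise ValidationError("sensitivity matrix has negative entries (non-monotone engine)")
        self.sensitivity = np.maximum(self.sensitivity, 0.0)

    @property
    def driver_index(self) -> list[tuple[str, str]]:
        return [(a, s) for a in self.regions for s in self.sectors]

    @property
    def n_drivers(self) -> int:
        return len(self.regions) * len(self.sectors)

    def predict(self, strategy: Strategy) -> pd.Series:
        """Indicator per unit under ``strategy``; clamped at zero after summation."""
        strategy._check_axes(self.regions, self.sectors)
        v = self.baseline - self.sensitivity @ strategy.flat
        return pd.Series(np.maximum(v, 0.0), index=list(self.units))

    def predict_flat(self, flat_rates: np.ndarray) -> np.ndarray:
        """Prediction straight from a flat rate vector (GA hot path, no labels)."""
        return np.maximum(self.baseline - self.sensitivity @ flat_rates, 0.0)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "driver_index": [[a, s] for a, s in self.driver_index],
            "units": list(self.units),
            "baseline": {u: v for u, v in zip(self.units, self.baseline.tolist())},
            "sensitivity": self.sensitivity.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "LinearMetamodel":
        driver_index = [(a, s) for a, s in d["driver_index"]]
        regions = tuple(dict.fromkeys(a for a, _ in driver_index))
        sectors = tuple(dict.fromkeys(s for _, s in driver_index))
        if [(a, s) for a in regions for s in sectors] != driver_index:
            raise ValidationError("driver_index is not a region-major product order")
        units = tuple(d["units"])
        baseline = np.array([d["baseline"][u] for u in units], dtype=float)
        return cls(units, regions, sectors, baseline, np.array(d["sensitivity"]), float(d["step"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearMetamodel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def build_metamodel(
    engine: Engine,
    regions: Sequence[str],
    sectors: Sequence[str],
    step: float = 0.01,
) -> LinearMetamodel:
    """Probe ``engine`` driver by driver and assemble the sensitivity matrix.

    ``engine`` maps a :class:`Strategy` over (regions, sectors) to a Series of
    non-negative indicator values over fixed units.  Column d of the matrix is
    ``(v0 - engine(step on driver d)) / step``.
    """
    if not 0 < step <= 1:
        raise ValidationError("step must lie in (0, 1]")
    regions = tuple(regions)
    sectors = tuple(sectors)
    v0 = engine(Strategy.zero(regions, sectors))
    if (v0 < 0).any():
        raise ValidationError("engine returned negative baseline values")
    units = tuple(str(u) for u in v0.index)
    n_drivers = len(regions) * len(sectors)
    S = np.empty((len(units), n_drivers))
    for d in range(n_drivers):
        flat = np.zeros(n_drivers)
        flat[d] = step
        v = engine(Strategy.from_flat(flat, regions, sectors))
        if (v < 0).any():
            raise ValidationError("engine returned negative values")
        S[:, d] = (v0.to_numpy() - v.to_numpy()) / step
    return LinearMetamodel(units, regions, sectors, v0.to_numpy(), S, step)


def aggregate_values(
    values: pd.Series, level: str, basin: Basin
) -> pd.DataFrame:
    """Summaries (mean, median, min, max, count) by region or for the basin.

    ``values`` must be indexed by catchment id; ``level`` is ``"region"`` or
    ``"basin"`` (one row).
    """
    values = values.astype(float)
    unknown = set(values.index.astype(str)) - set(basin.catchments.index)
    if unknown:
        raise ValidationError(f"values refer to unknown catchments: {sorted(unknown)}")
    stats = ["mean", "median", "min", "max", "count"]
    if level == "basin":
        agg = values.agg(stats)
        return pd.DataFrame([agg.to_dict()], index=pd.Index(["basin"], name="group"))
    if level == "region":
        groups = basin.catchments.loc[values.index, "region_id"]
        out = values.groupby(groups).agg(stats)
        out.index.name = "group"
        return out
    raise ValidationError(f"unknown aggregation level {level!r}")
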
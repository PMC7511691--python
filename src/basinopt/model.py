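"""Model/Results facade over the basin engines, metamodel and optimizer.

:class:`PressureReductionModel` is constructed from a :class:`~basinopt.basin.Basin`
plus the analysis configuration (module, bounds, effort weights, aggregation
metric); its :meth:`~PressureReductionModel.fit` runs the NSGA-II search and
returns :class:`ParetoResults`, which carries the trade-off front, baseline
diagnostics, reference strategy families and plotting.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .basin import (
    Basin,
    Bounds,
    Strategy,
    ValidationError,
    classify_tn,
    classify_wei,
    compute_wei,
    route_nitrogen,
)
from .metamodel import LinearMetamodel, aggregate_values, build_metamodel
from .objectives import EffortWeights, aggregate_metric
from .optimizer import (
    ComparisonReport,
    OptimizerConfig,
    ParetoFront,
    compare_strategies,
    nsga2_optimize,
    prior_appraisal,
    random_strategies,
    uniform_sweep,
)

__all__ = ["PressureReductionModel", "ParetoResults"]


class PressureReductionModel:
    """Trade-off model for one basin, one module, one analysis configuration.

    Parameters
    ----------
    basin : the catchment network (quality) and/or region water table (quantity).
    module : ``"quality"`` (TN concentration) or ``"quantity"`` (WEI).
    bounds : maximum allowed reduction per (region, sector); a scalar applies
        everywhere (default 0.5, i.e. up to 50% reduction).
    weights : per-cell effort weights; default all equal to 1.
    metric : aggregation of the per-unit indicator into the environmental
        objective — mean, median, q3, max or threshold.
    threshold : the threshold value T when ``metric="threshold"`` (e.g. 5 mg/L).
    step : probe fraction for the sensitivity matrix (default 0.01).
    """

    def __init__(
        self,
        basin: Basin,
        module: str = "quality",
        bounds: Bounds | float = 0.5,
        weights: EffortWeights | None = None,
        metric: str = "median",
        threshold: float | None = None,
        threshold_mode: str = "sum",
        step: float = 0.01,
    ) -> None:
        if module not in ("quality", "quantity"):
            raise ValidationError(f"unknown module {module!r}")
        if module == "quantity" and basin.region_water is None:
            raise ValidationError("quantity module requires a region water table")
        self.basin = basin
        self.module = module
        self.regions = basin.regions
        self.sectors = basin.sectors(module)
        if isinstance(bounds, (int, float)):
            bounds = Bounds.uniform(self.regions, self.sectors, float(bounds))
        if bounds.regions != self.regions or tuple(bounds.sectors) != self.sectors:
            raise ValidationError("bounds axes do not match the basin/module")
        self.bounds = bounds
        self.weights = weights if weights is not None else EffortWeights.equal(self.regions, self.sectors)
        if self.weights.regions != self.regions or self.weights.sectors != self.sectors:
            raise ValidationError("weight axes do not match the basin/module")
        self.metric = metric
        self.threshold = threshold
        self.threshold_mode = threshold_mode
        self.step = step
        self._metamodel: LinearMetamodel | None = None

    @classmethod
    def from_csv(
        cls, catchments_path, region_water_path=None, pathways=None, **kwargs
    ) -> "PressureReductionModel":
        from .io import read_basin

        return cls(read_basin(catchments_path, region_water_path, pathways), **kwargs)

    # -- engines and surrogate -------------------------------------------
    def engine(self, strategy: Strategy) -> pd.Series:
        """The direct environmental model: TN per catchment or WEI per region."""
        if self.module == "quality":
            return route_nitrogen(self.basin, strategy)["tn"]
        return compute_wei(self.basin, strategy)

    @property
    def metamodel(self) -> LinearMetamodel:
        if self._metamodel is None:
            self._metamodel = build_metamodel(self.engine, self.regions, self.sectors, self.step)
        return self._metamodel

    @property
    def n_decision_variables(self) -> int:
        return len(self.regions) * len(self.sectors)

    # -- baseline diagnostics --------------------------------------------
    def baseline_values(self) -> pd.Series:
        return self.engine(Strategy.zero(self.regions, self.sectors))

    def baseline_env(self) -> float:
        return aggregate_metric(
            self.baseline_values(), self.metric, self.threshold, self.threshold_mode
        )

    def baseline_report(self) -> dict[str, pd.DataFrame]:
        """Current-conditions tables: indicator, class and (quality) aggregates."""
        values = self.baseline_values()
        if self.module == "quality":
            cls = classify_tn(values)
            per_unit = pd.DataFrame({"tn": values, "quality_class": cls})
            per_unit.index.name = "catchment"
            out = {
                "per_unit": per_unit,
                "region_aggregates": aggregate_values(values, "region", self.basin),
                "basin_aggregates": aggregate_values(values, "basin", self.basin),
            }
        else:
            cls = classify_wei(values)
            per_unit = pd.DataFrame({"wei": values, "stress_class": cls})
            per_unit.index.name = "region"
            out = {"per_unit": per_unit}
        return out

    def _config(self, front_size, generations, seed, **kwargs) -> OptimizerConfig:
        return OptimizerConfig(
            bounds=self.bounds,
            metric=self.metric,
            threshold=self.threshold,
            threshold_mode=self.threshold_mode,
            front_size=front_size,
            generations=generations,
            seed=seed,
            **kwargs,
        )

    # -- the fit ----------------------------------------------------------
    def fit(
        self, front_size: int = 50, generations: int = 200, seed: int = 0, **kwargs
    ) -> "ParetoResults":
        """Search for the Pareto front of (effort, environmental outcome)."""
        config = self._config(front_size, generations, seed, **kwargs)
        front = nsga2_optimize(self.metamodel, self.weights, config)
        return ParetoResults(self, front, config)

    def prior_appraisal(self, front_size=50, generations=100, seed=0,
                        levels=(0.90, 0.75, 0.50), n_runs=20):
        """Equal-effort appraisal of reduction shares at reference levels."""
        config = self._config(front_size, generations, seed)
        return prior_appraisal(self.metamodel, config, levels, n_runs)


class ParetoResults:
    """The fitted trade-off front plus diagnostics and reference families."""

    def __init__(self, model: PressureReductionModel, front: ParetoFront, config: OptimizerConfig):
        self.model = model
        self.pareto_front = front
        self.config = config
        self.baseline_env = front.metadata["baseline_env"]

    @property
    def front(self) -> pd.DataFrame:
        """One row per front member: objectives plus the rate columns."""
        return self.pareto_front.to_frame()

    @property
    def entries(self) -> pd.DataFrame:
        return self.pareto_front.entries

    @property
    def strategies(self) -> list[Strategy]:
        return self.pareto_front.strategies

    def __len__(self) -> int:
        return len(self.pareto_front)

    def strategy(self, i: int) -> Strategy:
        return self.pareto_front.strategies[i]

    def uniform_sweep(self, n_steps: int = 21) -> pd.DataFrame:
        return uniform_sweep(self.model.metamodel, self.model.weights, self.config, n_steps)

    def random_strategies(self, n: int = 200, seed: int | None = None):
        return random_strategies(self.model.metamodel, self.model.weights, self.config, n, seed)

    def compare(self, i: int, j: int, threshold: float = 5.0) -> ComparisonReport:
        return compare_strategies(
            self.model.metamodel,
            self.model.basin,
            self.strategy(i),
            self.strategy(j),
            self.model.weights,
            self.model.module,
            threshold,
        )

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statistical results table."""
        m = self.model
        e = self.entries
        lines = []
        title = "Pressure Reduction Trade-off Analysis"
        lines.append(title.center(58))
        lines.append("=" * 58)
        metric = m.metric + (f" (T={m.threshold})" if m.metric == "threshold" else "")
        rows = [
            ("Module:", m.module, "Regions:", len(m.regions)),
            ("Units:", len(m.metamodel.units), "Sectors:", len(m.sectors)),
            ("Decision variables:", m.n_decision_variables, "Metric:", metric),
            ("Front size:", len(self), "Generations:", self.config.generations),
            ("Seed:", self.config.seed, "", ""),
        ]
        for a, b, c, d in rows:
            lines.append(f"{a:<20}{b!s:<12}{c:<14}{d!s}")
        lines.append("-" * 58)
        lines.append(f"Baseline environmental metric: {self.baseline_env:.4f}")
        lines.append(f"Best attainable metric:        {e['env_metric'].min():.4f}")
        lines.append(f"Effort range on front:         {e['effort_raw'].min():.4f} - "
                     f"{e['effort_raw'].max():.4f}")
        lines.append("-" * 58)
        lines.append(f"{'effort_raw':>12}{'effort_norm':>13}{'env_metric':>12}")
        show = e if len(e) <= 12 else pd.concat([e.head(6), e.tail(6)])
        prev = None
        for idx, row in show.iterrows():
            if prev is not None and idx != prev + 1:
                lines.append(f"{'...':>12}{'...':>13}{'...':>12}")
            lines.append(
                f"{row['effort_raw']:>12.4f}{row['effort_normalized']:>13.4f}"
                f"{row['env_metric']:>12.4f}"
            )
            prev = idx
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None, n_random: int = 200, n_steps: int = 21, seed: int | None = None):
        """Objective-space scatter: front (blue), uniform (green), random (red)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        rand, _ = self.random_strategies(n_random, seed)
        ax.scatter(rand["effort_raw"], rand["env_metric"], s=10, c="tab:red",
                   alpha=0.5, label="random strategies")
        sweep = self.uniform_sweep(n_steps)
        ax.plot(sweep["effort_raw"], sweep["env_metric"], "o-", ms=4,
                c="tab:green", label="uniform effort")
        e = self.entries
        ax.plot(e["effort_raw"], e["env_metric"], "o", ms=5, c="tab:blue",
                label="Pareto front")
        ax.set_xlabel("total effort")
        ylabel = "TN" if self.model.module == "quality" else "WEI"
        ax.set_ylabel(f"environmental metric ({self.model.metric} {ylabel})")
        ax.legend(frameon=False)
        return ax

    def to_csv(self, path) -> None:
        self.pareto_front.to_csv(path)
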
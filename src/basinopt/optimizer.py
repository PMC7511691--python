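"""NSGA-II search for effort / environmental-outcome trade-offs.

Both objectives are minimized: total weighted effort, and the chosen
aggregation of the metamodel-predicted indicator (mean, median, q3, max, or
sum above a threshold).  The optimizer is the classic elitist non-dominated
sorting GA: dominance ranking, crowding distance, binary crowded-tournament
selection, simulated binary crossover and polynomial mutation, with a
(mu + lambda) environmental selection.

Population size equals the requested Pareto-front size.  The initial
population always contains the two corners of the search box (the zero
strategy and the maximum-reduction strategy), which with elitism pins the
front to its natural endpoints: the current situation at zero effort and the
maximum attainable improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .basin import Basin, Bounds, Strategy, ValidationError, route_nitrogen, compute_wei
from .metamodel import LinearMetamodel
from .objectives import EffortWeights, aggregate_metric, total_effort, AGGREGATION_METRICS

__all__ = [
    "OptimizerConfig",
    "ParetoFront",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "nsga2_optimize",
    "uniform_sweep",
    "random_strategies",
    "prior_appraisal",
    "PriorAppraisal",
    "compare_strategies",
    "ComparisonReport",
    "hypervolume",
]


# ---------------------------------------------------------------------------
# dominance machinery
# ---------------------------------------------------------------------------

def dominates(p: Sequence[float], q: Sequence[float]) -> bool:
    """True iff p is at least as good as q in both objectives and better in one."""
    p0, p1 = p
    q0, q1 = q
    return p0 <= q0 and p1 <= q1 and (p0 < q0 or p1 < q1)


def fast_nondominated_sort(points) -> list[list[int]]:
    """Partition objective pairs into successive non-dominated fronts.

    Returns fronts as lists of indices into ``points``; front 0 is the
    non-dominated set, front k the non-dominated set once fronts 0..k-1 are
    removed.  Every index appears exactly once.
    """
    F = np.asarray(points, dtype=float)
    if F.ndim != 2 or F.shape[1] != 2 or F.shape[0] == 0:
        raise ValidationError("need a non-empty (n, 2) array of objective pairs")
    n = F.shape[0]
    # pairwise dominance via broadcasting
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dom = dom.sum(axis=0)  # how many dominate j
    fronts: list[list[int]] = []
    current = np.flatnonzero(n_dom == 0)
    assigned = np.zeros(n, dtype=bool)
    while current.size:
        fronts.append(current.tolist())
        assigned[current] = True
        n_dom = n_dom - dom[current].sum(axis=0)
        n_dom[assigned] = -1
        current = np.flatnonzero(n_dom == 0)
    return fronts


def crowding_distance(front_points) -> np.ndarray:
    """NSGA-II crowding distance of each member of one front.

    Boundary members per objective get +inf; interior members accumulate the
    normalized gap between their neighbours.  Objectives with zero range
    contribute nothing, so a front of identical points yields inf for the two
    stable-sort boundary members and 0 for the rest.  Ties are ordered by
    (value, index) so the result is deterministic.
    """
    F = np.asarray(front_points, dtype=float)
    n = F.shape[0]
    if n == 0:
        raise ValidationError("empty front")
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for m in range(F.shape[1]):
        order = np.lexsort((np.arange(n), F[:, m]))
        vals = F[order, m]
        d[order[0]] = np.inf
        d[order[-1]] = np.inf
        rng = vals[-1] - vals[0]
        if rng > 0:
            gaps = (vals[2:] - vals[:-2]) / rng
            d[order[1:-1]] += gaps
    return d


def hypervolume(points, ref: Sequence[float]) -> float:
    """2-D dominated hypervolume (minimization) w.r.t. reference point ``ref``."""
    F = np.asarray(points, dtype=float)
    if F.size == 0:
        return 0.0
    F = F[(F[:, 0] <= ref[0]) & (F[:, 1] <= ref[1])]
    if F.shape[0] == 0:
        return 0.0
    fronts = fast_nondominated_sort(F)
    nd = F[fronts[0]]
    nd = nd[np.lexsort((nd[:, 1], nd[:, 0]))]
    # drop duplicates / weakly dominated in f2
    keep = []
    best2 = np.inf
    for row in nd:
        if row[1] < best2:
            keep.append(row)
            best2 = row[1]
    nd = np.array(keep)
    f1 = np.append(nd[:, 0], ref[0])
    return float(np.sum((f1[1:] - f1[:-1]) * (ref[1] - nd[:, 1])))


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """GA settings; defaults are the conventional real-coded NSGA-II choices."""

    bounds: Bounds
    metric: str = "median"
    threshold: float | None = None
    threshold_mode: str = "sum"
    front_size: int = 50
    generations: int = 200
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_prob: float | None = None  # default 1 / n_drivers
    mutation_eta: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.front_size < 4:
            raise ValidationError("front_size must be at least 4")
        if self.generations < 1:
            raise ValidationError("generations must be at least 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValidationError("crossover probability must lie in [0, 1]")
        if self.crossover_eta < 0 or self.mutation_eta < 0:
            raise ValidationError("distribution indices must be non-negative")
        if self.mutation_prob is not None and not 0 <= self.mutation_prob <= 1:
            raise ValidationError("mutation probability must lie in [0, 1]")
        if self.metric not in AGGREGATION_METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.metric == "threshold" and self.threshold is None:
            raise ValidationError("threshold metric requires a threshold value")

    def summary_dict(self) -> dict:
        return {
            "metric": self.metric,
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "front_size": self.front_size,
            "generations": self.generations,
            "crossover_prob": self.crossover_prob,
            "crossover_eta": self.crossover_eta,
            "mutation_prob": self.mutation_prob,
            "mutation_eta": self.mutation_eta,
            "seed": self.seed,
        }


@dataclass
class ParetoFront:
    """Non-dominated (strategy, effort, environmental metric) triples.

    ``entries`` is sorted by effort ascending with columns ``effort_raw``,
    ``effort_normalized`` and ``env_metric``; ``strategies[i]`` is the
    decision table behind row i.
    """

    entries: pd.DataFrame
    strategies: list[Strategy]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        F = self.entries[["effort_raw", "env_metric"]].to_numpy()
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j and dominates(F[i], F[j]):
                    raise ValidationError("Pareto front contains dominated entries")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def objectives(self) -> np.ndarray:
        return self.entries[["effort_raw", "env_metric"]].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """One row per member: objectives plus one ``region__sector`` rate column."""
        rows = []
        for (_, e), s in zip(self.entries.iterrows(), self.strategies):
            row = {
                "effort_raw": e["effort_raw"],
                "effort_normalized": e["effort_normalized"],
                "env_metric": e["env_metric"],
            }
            for a_i, a in enumerate(s.regions):
                for s_i, sec in enumerate(s.sectors):
                    row[f"{a}__{sec}"] = s.rates[a_i, s_i]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# the GA itself
# ---------------------------------------------------------------------------

class _Evaluator:
    """Objective evaluation on flat rate vectors (the GA hot path)."""

    def __init__(self, meta: LinearMetamodel, weights: EffortWeights, config: OptimizerConfig):
        if weights.regions != meta.regions or weights.sectors != meta.sectors:
            raise ValidationError("weights and metamodel axes do not match")
        b = config.bounds
        if b.regions != meta.regions or b.sectors != meta.sectors:
            raise ValidationError("bounds and metamodel axes do not match")
        self.meta = meta
        self.weights = weights
        self.config = config
        self.w_flat = weights.flat
        self.upper = b.flat.copy()
        self.emax = float(self.w_flat @ self.upper)

    def objectives(self, x: np.ndarray) -> tuple[float, float]:
        env = aggregate_metric(
            self.meta.predict_flat(x),
            self.config.metric,
            self.config.threshold,
            self.config.threshold_mode,
        )
        return float(self.w_flat @ x), env

    def norm_effort(self, effort: float) -> float:
        return 0.0 if self.emax == 0 else effort / self.emax


def _sbx(p1: np.ndarray, p2: np.ndarray, upper: np.ndarray, eta: float,
         prob: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0, upper] with per-pair probability."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for i in range(len(p1)):
        if upper[i] <= 0 or rng.random() > 0.5:
            continue
        x1, x2 = min(p1[i], p2[i]), max(p1[i], p2[i])
        if x2 - x1 < 1e-14:
            continue
        lo, hi = 0.0, upper[i]
        u = rng.random()
        beta = 1.0 + 2.0 * (x1 - lo) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else \
            (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        ch1 = 0.5 * ((x1 + x2) - bq * (x2 - x1))
        beta = 1.0 + 2.0 * (hi - x2) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else \
            (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        ch2 = 0.5 * ((x1 + x2) + bq * (x2 - x1))
        ch1, ch2 = np.clip(ch1, lo, hi), np.clip(ch2, lo, hi)
        if rng.random() > 0.5:
            ch1, ch2 = ch2, ch1
        c1[i], c2[i] = ch1, ch2
    return c1, c2


def _poly_mutation(x: np.ndarray, upper: np.ndarray, eta: float, prob: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Polynomial mutation on [0, upper] with per-gene probability."""
    y = x.copy()
    for i in range(len(x)):
        if upper[i] <= 0 or rng.random() > prob:
            continue
        lo, hi = 0.0, upper[i]
        delta1 = (y[i] - lo) / (hi - lo)
        delta2 = (hi - y[i]) / (hi - lo)
        u = rng.random()
        mut_pow = 1.0 / (eta + 1.0)
        if u < 0.5:
            val = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - delta1) ** (eta + 1.0)
            deltaq = val ** mut_pow - 1.0
        else:
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - delta2) ** (eta + 1.0)
            deltaq = 1.0 - val ** mut_pow
        y[i] = np.clip(y[i] + deltaq * (hi - lo), lo, hi)
    return y


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_nondominated_sort(F)
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return rank, crowd


def _tournament(rank, crowd, i, j) -> int:
    """Crowded comparison; deterministic tie-break by index."""
    if rank[i] != rank[j]:
        return i if rank[i] < rank[j] else j
    if crowd[i] != crowd[j]:
        return i if crowd[i] > crowd[j] else j
    return min(i, j)


def nsga2_optimize(
    meta: LinearMetamodel,
    weights: EffortWeights,
    config: OptimizerConfig,
) -> ParetoFront:
    """Run NSGA-II and return the final non-dominated front.

    Reproducible given ``config.seed``; every returned strategy respects the
    bounds.  The front is deduplicated on identical objective vectors and
    sorted by effort ascending.
    """
    ev = _Evaluator(meta, weights, config)
    rng = np.random.default_rng(config.seed)
    n = meta.n_drivers
    pop_size = config.front_size
    upper = ev.upper
    mut_prob = config.mutation_prob if config.mutation_prob is not None else 1.0 / n

    # corners + random fill
    pop = [np.zeros(n), upper.copy()]
    while len(pop) < pop_size:
        pop.append(rng.uniform(0.0, 1.0, n) * upper)
    pop = pop[:pop_size]
    F = np.array([ev.objectives(x) for x in pop])

    history = {"best_effort": [], "best_env": []}
    rank, crowd = _rank_and_crowd(F)
    for _gen in range(config.generations):
        history["best_effort"].append(float(F[:, 0].min()))
        history["best_env"].append(float(F[:, 1].min()))
        # variation
        offspring: list[np.ndarray] = []
        while len(offspring) < pop_size:
            idx = rng.integers(0, pop_size, size=4)
            p1 = pop[_tournament(rank, crowd, int(idx[0]), int(idx[1]))]
            p2 = pop[_tournament(rank, crowd, int(idx[2]), int(idx[3]))]
            c1, c2 = _sbx(p1, p2, upper, config.crossover_eta, config.crossover_prob, rng)
            offspring.append(_poly_mutation(c1, upper, config.mutation_eta, mut_prob, rng))
            if len(offspring) < pop_size:
                offspring.append(_poly_mutation(c2, upper, config.mutation_eta, mut_prob, rng))
        off_F = np.array([ev.objectives(x) for x in offspring])
        # (mu + lambda) environmental selection
        all_pop = pop + offspring
        all_F = np.vstack([F, off_F])
        fronts = fast_nondominated_sort(all_F)
        new_idx: list[int] = []
        for front in fronts:
            if len(new_idx) + len(front) <= pop_size:
                new_idx.extend(front)
            else:
                cd = crowding_distance(all_F[front])
                order = sorted(range(len(front)), key=lambda k: (-cd[k], front[k]))
                new_idx.extend(front[k] for k in order[: pop_size - len(new_idx)])
                break
        pop = [all_pop[i] for i in new_idx]
        F = all_F[new_idx]
        rank, crowd = _rank_and_crowd(F)
    history["best_effort"].append(float(F[:, 0].min()))
    history["best_env"].append(float(F[:, 1].min()))

    # final non-dominated set, deduplicated on objectives
    nd = fast_nondominated_sort(F)[0]
    seen: dict[bytes, int] = {}
    for i in sorted(nd, key=lambda i: (F[i, 0], F[i, 1], pop[i].tobytes())):
        key = F[i].tobytes()
        if key not in seen:
            seen[key] = i
    final = list(seen.values())[: config.front_size]

    baseline_env = aggregate_metric(
        meta.baseline, config.metric, config.threshold, config.threshold_mode
    )
    entries = pd.DataFrame(
        {
            "effort_raw": F[final, 0],
            "effort_normalized": [ev.norm_effort(F[i, 0]) for i in final],
            "env_metric": F[final, 1],
        }
    ).reset_index(drop=True)
    strategies = [Strategy.from_flat(pop[i], meta.regions, meta.sectors) for i in final]
    meta_info = {"config": config.summary_dict(), "baseline_env": baseline_env, "history": history}
    return ParetoFront(entries, strategies, meta_info)


# ---------------------------------------------------------------------------
# reference strategy families
# ---------------------------------------------------------------------------

def uniform_sweep(
    meta: LinearMetamodel,
    weights: EffortWeights,
    config: OptimizerConfig,
    n_steps: int = 21,
) -> pd.DataFrame:
    """Uniform-effort reference: the same rate everywhere, capped at the bounds.

    For u on an even grid over [0, 1] (including both ends), the strategy is
    r[a, s] = min(u, rmax[a, s]).  Returns (u, effort_raw, effort_normalized,
    env_metric) per grid point.
    """
    if n_steps < 2:
        raise ValidationError("n_steps must be at least 2")
    ev = _Evaluator(meta, weights, config)
    rows = []
    for u in np.linspace(0.0, 1.0, n_steps):
        x = np.minimum(u, ev.upper)
        eff, env = ev.objectives(x)
        rows.append({"u": u, "effort_raw": eff, "effort_normalized": ev.norm_effort(eff),
                     "env_metric": env})
    return pd.DataFrame(rows)


def random_strategies(
    meta: LinearMetamodel,
    weights: EffortWeights,
    config: OptimizerConfig,
    n: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[Strategy]]:
    """n strategies with rates drawn Uniform(0, rmax) per driver, reproducibly."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    ev = _Evaluator(meta, weights, config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, strategies = [], []
    for _ in range(n):
        x = rng.uniform(0.0, 1.0, meta.n_drivers) * ev.upper
        eff, env = ev.objectives(x)
        rows.append({"effort_raw": eff, "effort_normalized": ev.norm_effort(eff),
                     "env_metric": env})
        strategies.append(Strategy.from_flat(x, meta.regions, meta.sectors))
    return pd.DataFrame(rows), strategies


# ---------------------------------------------------------------------------
# prior appraisal
# ---------------------------------------------------------------------------

@dataclass
class PriorAppraisal:
    """Distributions of effort shares by sector and region per reference level.

    ``sector_shares[level]`` / ``region_shares[level]`` are DataFrames with
    (min, q1, median, q3, max) rows summarising the share of total reduction
    allotted to each sector / region across the attained runs;
    ``raw_sector_shares`` keeps the per-run shares for downstream analysis.
    """

    levels: tuple[float, ...]
    sector_shares: dict
    region_shares: dict
    raw_sector_shares: dict
    raw_region_shares: dict
    n_runs: int
    n_unreachable: dict
    n_degenerate: dict


def _summaries(samples: pd.DataFrame) -> pd.DataFrame:
    q = samples.quantile([0.0, 0.25, 0.5, 0.75, 1.0], interpolation="linear")
    q.index = ["min", "q1", "median", "q3", "max"]
    return q


def prior_appraisal(
    meta: LinearMetamodel,
    config: OptimizerConfig,
    levels: Sequence[float] = (0.90, 0.75, 0.50),
    n_runs: int = 20,
) -> PriorAppraisal:
    """Equal-effort appraisal of where reductions go at reference outcome levels.

    For each of ``n_runs`` GA runs (distinct seeds, equal weights, median
    metric) and each level L, pick the minimum-effort front member whose
    median indicator is at most L x its baseline value, and record the share
    of total reduction per sector and per region.  Runs where a level is
    unattainable within bounds are counted, not silently dropped; all-zero
    qualifying strategies (e.g. L = 1) are reported as degenerate.
    """
    for lv in levels:
        if not 0 < lv <= 1:
            raise ValidationError("reference levels must lie in (0, 1]")
    weights = EffortWeights.equal(meta.regions, meta.sectors)
    base_cfg = config.summary_dict()
    baseline_median = aggregate_metric(meta.baseline, "median")
    sector_rows = {lv: [] for lv in levels}
    region_rows = {lv: [] for lv in levels}
    unreachable = {lv: 0 for lv in levels}
    degenerate = {lv: 0 for lv in levels}
    for run in range(n_runs):
        cfg = OptimizerConfig(
            bounds=config.bounds,
            metric="median",
            front_size=base_cfg["front_size"],
            generations=base_cfg["generations"],
            crossover_prob=base_cfg["crossover_prob"],
            crossover_eta=base_cfg["crossover_eta"],
            mutation_prob=base_cfg["mutation_prob"],
            mutation_eta=base_cfg["mutation_eta"],
            seed=config.seed + run,
        )
        front = nsga2_optimize(meta, weights, cfg)
        env = front.entries["env_metric"].to_numpy()
        eff = front.entries["effort_raw"].to_numpy()
        for lv in levels:
            ok = np.flatnonzero(env <= lv * baseline_median + 1e-12)
            if ok.size == 0:
                unreachable[lv] += 1
                continue
            best = ok[np.argmin(eff[ok])]
            strat = front.strategies[best]
            tot = strat.rates.sum()
            if tot <= 0:
                degenerate[lv] += 1
                continue
            sector_rows[lv].append(strat.rates.sum(axis=0) / tot)
            region_rows[lv].append(strat.rates.sum(axis=1) / tot)
    sector_shares, region_shares, raw_s, raw_r = {}, {}, {}, {}
    for lv in levels:
        s_df = pd.DataFrame(sector_rows[lv], columns=list(meta.sectors))
        r_df = pd.DataFrame(region_rows[lv], columns=list(meta.regions))
        raw_s[lv], raw_r[lv] = s_df, r_df
        sector_shares[lv] = _summaries(s_df) if len(s_df) else s_df
        region_shares[lv] = _summaries(r_df) if len(r_df) else r_df
    return PriorAppraisal(tuple(levels), sector_shares, region_shares, raw_s, raw_r,
                          n_runs, unreachable, degenerate)


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Side-by-side view of two strategies against the baseline."""

    rates: pd.DataFrame
    region_effort: pd.DataFrame
    per_unit: pd.DataFrame
    basin_aggregates: pd.DataFrame

    def to_csv(self, directory) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("comparison_rates.csv", self.rates),
            ("comparison_region_effort.csv", self.region_effort),
            ("comparison_per_unit.csv", self.per_unit),
            ("comparison_basin_aggregates.csv", self.basin_aggregates),
        ]:
            p = directory / name
            df.to_csv(p, lineterminator="\n")
            written.append(p)
        return written

    def summary(self) -> str:
        lines = ["Strategy comparison", "===================", "",
                 "Total effort: a = {:.4f}, b = {:.4f}".format(
                     self.region_effort["effort_a"].sum(),
                     self.region_effort["effort_b"].sum()),
                 "", "Basin aggregates (baseline / a / b):"]
        for metric, row in self.basin_aggregates.iterrows():
            lines.append(
                f"  {metric:>10}: {row['baseline']:.4f} / {row['strategy_a']:.4f} / {row['strategy_b']:.4f}"
            )
        return "\n".join(lines)


def compare_strategies(
    meta: LinearMetamodel,
    basin: Basin,
    s1: Strategy,
    s2: Strategy,
    weights: EffortWeights,
    module: str = "quality",
    threshold: float = 5.0,
) -> ComparisonReport:
    """Compare two strategies: rates, effort by region, indicators, aggregates.

    Per-unit indicators are recomputed with the direct engine (nitrogen
    routing or WEI), not the metamodel, so the report reflects the model the
    metamodel summarizes.  ``threshold`` feeds the threshold aggregate row.
    """
    s1._check_axes(meta.regions, meta.sectors)
    s2._check_axes(meta.regions, meta.sectors)
    cells = pd.MultiIndex.from_product([meta.regions, meta.sectors], names=["region", "sector"])
    rates = pd.DataFrame(
        {"strategy_a": s1.flat, "strategy_b": s2.flat, "delta": s2.flat - s1.flat},
        index=cells,
    )
    eff = pd.DataFrame(
        {
            "effort_a": (weights.values * s1.rates).sum(axis=1),
            "effort_b": (weights.values * s2.rates).sum(axis=1),
        },
        index=pd.Index(meta.regions, name="region"),
    )
    if module == "quality":
        base = route_nitrogen(basin, Strategy.zero(meta.regions, meta.sectors))["tn"]
        v1 = route_nitrogen(basin, s1)["tn"]
        v2 = route_nitrogen(basin, s2)["tn"]
    elif module == "quantity":
        base = compute_wei(basin, Strategy.zero(meta.regions, meta.sectors))
        v1 = compute_wei(basin, s1)
        v2 = compute_wei(basin, s2)
    else:
        raise ValidationError(f"unknown module {module!r}")
    per_unit = pd.DataFrame(
        {
            "baseline": base,
            "strategy_a": v1,
            "strategy_b": v2,
            "delta_a": v1 - base,
            "delta_b": v2 - base,
        }
    )
    per_unit.index.name = "unit"
    agg_rows = {}
    for metric in AGGREGATION_METRICS:
        T = threshold if metric == "threshold" else None
        agg_rows[metric] = {
            "baseline": aggregate_metric(base, metric, T),
            "strategy_a": aggregate_metric(v1, metric, T),
            "strategy_b": aggregate_metric(v2, metric, T),
        }
    basin_agg = pd.DataFrame(agg_rows).T
    basin_agg.index.name = "metric"
    return ComparisonReport(rates, eff, per_unit, basin_agg)
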
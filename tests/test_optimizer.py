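"""NSGA-II machinery: dominance, sorting, crowding, search and baselines."""

import numpy as np
import pytest

from basinopt import (
    Bounds,
    EffortWeights,
    OptimizerConfig,
    Strategy,
    build_metamodel,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
    hypervolume,
    nsga2_optimize,
    prior_appraisal,
    random_strategies,
    route_nitrogen,
    uniform_sweep,
    compare_strategies,
)
from basinopt.basin import QUALITY_SECTOR_IDS, ValidationError
from basinopt.synthetic import SynthConfig, generate_basin


def _quality_meta(basin, step=0.01):
    return build_metamodel(lambda s: route_nitrogen(basin, s)["tn"],
                           basin.regions, QUALITY_SECTOR_IDS, step)


def _peel_oracle(points):
    """Brute-force dominance peeling: repeatedly strip the non-dominated set."""
    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        nd = [
            i for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(nd))
        remaining = [i for i in remaining if i not in nd]
    return fronts


class TestDominance:
    @pytest.mark.parametrize(
        "p,q,expected",
        [((1, 5), (2, 5), True), ((1, 5), (1, 5), False), ((1, 9), (2, 5), False),
         ((1, 4), (2, 5), True), ((2, 5), (1, 5), False)],
    )
    def test_pairs(self, p, q, expected):
        assert dominates(p, q) is expected


class TestNondominatedSort:
    def test_single_point(self):
        assert fast_nondominated_sort([(1.0, 2.0)]) == [[0]]

    def test_strictly_decreasing_curve_is_one_front(self):
        pts = [(x, 10 - x) for x in range(10)]
        assert fast_nondominated_sort(pts) == [sorted(range(10))]

    def test_matches_peeling_oracle_on_random_points(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, size=(50, 2))
        got = fast_nondominated_sort(pts)
        expected = _peel_oracle([tuple(p) for p in pts])
        assert [sorted(f) for f in got] == expected

    def test_every_index_appears_once(self):
        rng = np.random.default_rng(9)
        pts = rng.integers(0, 5, size=(30, 2)).astype(float)
        fronts = fast_nondominated_sort(pts)
        flat = sorted(i for f in fronts for i in f)
        assert flat == list(range(30))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fast_nondominated_sort(np.empty((0, 2)))


class TestCrowdingDistance:
    def test_two_or_fewer_points_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 2)])))
        assert np.all(np.isinf(crowding_distance([(1, 2), (3, 4)])))

    def test_four_evenly_spaced_points(self):
        pts = [(0.0, 3.0), (1.0, 2.0), (2.0, 1.0), (3.0, 0.0)]
        d = crowding_distance(pts)
        assert np.isinf(d[0]) and np.isinf(d[3])
        # each interior point: gap 2/3 in each objective
        assert d[1] == pytest.approx(4 / 3)
        assert d[2] == pytest.approx(4 / 3)

    def test_identical_points_follow_tie_rule(self):
        d = crowding_distance([(1.0, 1.0)] * 5)
        assert np.isinf(d).sum() == 2  # stable-sort boundaries
        assert np.all(d[~np.isinf(d)] == 0)


class TestHypervolume:
    def test_single_point_rectangle(self):
        assert hypervolume([(1.0, 1.0)], (3.0, 4.0)) == pytest.approx(6.0)

    def test_two_point_staircase(self):
        # union of [0,2]x[2,3] and [1,2]x[0,3]: 2 + 3 - 1 overlap
        assert hypervolume([(0.0, 2.0), (1.0, 0.0)], (2.0, 3.0)) == pytest.approx(4.0)

    def test_dominated_points_do_not_add(self):
        hv1 = hypervolume([(0.0, 2.0), (1.0, 0.0)], (2.0, 3.0))
        hv2 = hypervolume([(0.0, 2.0), (1.0, 0.0), (1.5, 2.5)], (2.0, 3.0))
        assert hv1 == pytest.approx(hv2)


@pytest.fixture(scope="module")
def ga_setup():
    basin = generate_basin(SynthConfig(n_catchments=25, n_regions=2, seed=21))
    meta = _quality_meta(basin)
    weights = EffortWeights.equal(basin.regions, QUALITY_SECTOR_IDS)
    bounds = Bounds.uniform(basin.regions, QUALITY_SECTOR_IDS, 0.5)
    return basin, meta, weights, bounds


class TestNSGA2:
    def test_seed_determinism(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=16, generations=20, seed=5)
        f1 = nsga2_optimize(meta, weights, cfg)
        f2 = nsga2_optimize(meta, weights, cfg)
        assert f1.entries.equals(f2.entries)
        for a, b in zip(f1.strategies, f2.strategies):
            np.testing.assert_array_equal(a.rates, b.rates)

    def test_empty_search_space_collapses_to_baseline(self, ga_setup):
        _, meta, weights, _ = ga_setup
        zero_bounds = Bounds.uniform(meta.regions, meta.sectors, 0.0)
        cfg = OptimizerConfig(bounds=zero_bounds, front_size=8, generations=5, seed=0)
        front = nsga2_optimize(meta, weights, cfg)
        assert len(front) == 1
        assert front.entries["effort_raw"].iloc[0] == 0.0
        assert front.entries["env_metric"].iloc[0] == pytest.approx(
            front.metadata["baseline_env"])

    def test_front_endpoints_single_driver(self, ga_setup):
        """With one free driver the front spans (0, baseline) to (rmax, best)."""
        _, meta, weights, _ = ga_setup
        rmax = np.zeros((len(meta.regions), len(meta.sectors)))
        rmax[0, 0] = 0.5
        bounds = Bounds(meta.regions, meta.sectors, rmax)
        # mean metric: strictly decreasing in the driver, so the corner is optimal
        cfg = OptimizerConfig(bounds=bounds, metric="mean", front_size=16,
                              generations=30, seed=2)
        front = nsga2_optimize(meta, weights, cfg)
        e = front.entries
        assert e["effort_raw"].min() == pytest.approx(0.0)
        assert e["env_metric"].iloc[0] == pytest.approx(front.metadata["baseline_env"])
        assert e["effort_raw"].max() == pytest.approx(0.5)
        best = meta.predict(bounds.max_strategy())
        from basinopt import aggregate_metric
        assert e["env_metric"].min() == pytest.approx(aggregate_metric(best, "mean"))

    def test_strategies_respect_bounds(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=12, generations=15, seed=1)
        front = nsga2_optimize(meta, weights, cfg)
        for s in front.strategies:
            assert bounds.contains(s)

    def test_front_internally_nondominated(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=20, generations=25, seed=3)
        front = nsga2_optimize(meta, weights, cfg)
        F = front.objectives
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not dominates(F[i], F[j])

    def test_elitism_best_objectives_never_worsen(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=16, generations=30, seed=4)
        front = nsga2_optimize(meta, weights, cfg)
        h = front.metadata["history"]
        assert np.all(np.diff(h["best_effort"]) <= 1e-12)
        assert np.all(np.diff(h["best_env"]) <= 1e-12)

    def test_matches_exhaustive_pareto_set_on_discretized_problem(self, ga_setup):
        _, meta, weights, _ = ga_setup
        rmax = np.zeros((len(meta.regions), len(meta.sectors)))
        rmax[0, 0] = 0.5
        rmax[1, 2] = 0.5
        bounds = Bounds(meta.regions, meta.sectors, rmax)
        # front size comparable to the discretized reference set, else the
        # hypervolume comparison is resolution-limited rather than a search test
        cfg = OptimizerConfig(bounds=bounds, front_size=64, generations=150, seed=6)
        front = nsga2_optimize(meta, weights, cfg)
        # exhaustive enumeration over 21 levels per driver
        from basinopt import aggregate_metric
        grid = np.linspace(0, 0.5, 21)
        pts = []
        for g1 in grid:
            for g2 in grid:
                flat = np.zeros(meta.n_drivers)
                flat[meta.driver_index.index((meta.regions[0], meta.sectors[0]))] = g1
                flat[meta.driver_index.index((meta.regions[1], meta.sectors[2]))] = g2
                env = aggregate_metric(meta.predict_flat(flat), "median")
                pts.append((weights.flat @ flat, env))
        pts = np.array(pts)
        exact = pts[fast_nondominated_sort(pts)[0]]
        ref = (pts[:, 0].max() * 1.01, front.metadata["baseline_env"] * 1.01)
        hv_exact = hypervolume(exact, ref)
        hv_ga = hypervolume(front.objectives, ref)
        assert hv_ga >= 0.99 * hv_exact


class TestReferenceFamilies:
    def test_uniform_sweep_monotone(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=8, generations=1, seed=0)
        sweep = uniform_sweep(meta, weights, cfg, n_steps=11)
        assert sweep["u"].iloc[0] == 0.0 and sweep["u"].iloc[-1] == 1.0
        assert sweep["effort_raw"].iloc[0] == 0.0
        assert np.all(np.diff(sweep["effort_raw"]) >= -1e-12)
        assert np.all(np.diff(sweep["env_metric"]) <= 1e-12)

    def test_random_strategies_reproducible_and_bounded(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=8, generations=1, seed=0)
        df1, strats1 = random_strategies(meta, weights, cfg, 10, seed=99)
        df2, _ = random_strategies(meta, weights, cfg, 10, seed=99)
        assert df1.equals(df2)
        for s in strats1:
            assert bounds.contains(s)

    def test_no_random_strategy_dominates_converged_front(self, ga_setup):
        _, meta, weights, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=24, generations=80, seed=7)
        front = nsga2_optimize(meta, weights, cfg)
        rand, _ = random_strategies(meta, weights, cfg, 200, seed=123)
        F = front.objectives
        R = rand[["effort_raw", "env_metric"]].to_numpy()
        tol = 1e-9
        for r in R:
            for f in F:
                assert not (r[0] <= f[0] - tol and r[1] <= f[1] - tol)


class TestPriorAppraisal:
    def test_shares_and_counts(self, ga_setup):
        _, meta, _, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=12, generations=25, seed=0)
        pa = prior_appraisal(meta, cfg, levels=(0.9, 0.75), n_runs=3)
        for lv in (0.9, 0.75):
            raw = pa.raw_sector_shares[lv]
            n = len(raw) + pa.n_unreachable[lv] + pa.n_degenerate[lv]
            assert n == 3
            if len(raw):
                np.testing.assert_allclose(raw.sum(axis=1), 1.0, atol=1e-9)
                summary = pa.sector_shares[lv]
                assert list(summary.index) == ["min", "q1", "median", "q3", "max"]

    def test_level_one_is_degenerate_or_zero_effort(self, ga_setup):
        _, meta, _, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=8, generations=10, seed=0)
        pa = prior_appraisal(meta, cfg, levels=(1.0,), n_runs=2)
        # the zero strategy qualifies at level 1.0: every run is degenerate
        assert pa.n_degenerate[1.0] == 2

    def test_unattainable_level_counted(self, ga_setup):
        _, meta, _, _ = ga_setup
        tiny = Bounds.uniform(meta.regions, meta.sectors, 0.01)
        cfg = OptimizerConfig(bounds=tiny, front_size=8, generations=10, seed=0)
        pa = prior_appraisal(meta, cfg, levels=(0.5,), n_runs=2)
        assert pa.n_unreachable[0.5] == 2

    def test_invalid_level_rejected(self, ga_setup):
        _, meta, _, bounds = ga_setup
        cfg = OptimizerConfig(bounds=bounds, front_size=8, generations=5, seed=0)
        with pytest.raises(ValidationError):
            prior_appraisal(meta, cfg, levels=(1.5,), n_runs=1)


class TestCompareStrategies:
    def test_identical_strategies_zero_delta(self, ga_setup):
        basin, meta, weights, _ = ga_setup
        s = Strategy.uniform(meta.regions, meta.sectors, 0.2)
        rep = compare_strategies(meta, basin, s, s, weights)
        assert np.allclose(rep.rates["delta"], 0.0)
        assert np.allclose(rep.per_unit["strategy_a"], rep.per_unit["strategy_b"])

    def test_zero_strategy_column_equals_baseline(self, ga_setup):
        basin, meta, weights, _ = ga_setup
        z = Strategy.zero(meta.regions, meta.sectors)
        s = Strategy.uniform(meta.regions, meta.sectors, 0.4)
        rep = compare_strategies(meta, basin, z, s, weights)
        assert np.allclose(rep.per_unit["strategy_a"], rep.per_unit["baseline"])
        assert np.allclose(rep.per_unit["delta_a"], 0.0)
        assert (rep.per_unit["delta_b"] <= 1e-12).all()

    def test_basin_aggregates_cover_all_metrics(self, ga_setup):
        basin, meta, weights, _ = ga_setup
        s = Strategy.uniform(meta.regions, meta.sectors, 0.3)
        rep = compare_strategies(meta, basin, s, s, weights)
        assert set(rep.basin_aggregates.index) == {"mean", "median", "q3", "max", "threshold"}
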
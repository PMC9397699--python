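import math

import numpy as np
import pytest

from chaolle.chaotic_maps import ChaoticMap
from chaolle.optimizers import (BENCHMARK_FUNCTIONS, IWDConfig, SearchSpace,
                                Team, TWConfig, benchmark_suite, ctw_step,
                                iwd_optimize, optimize, tw_initialize,
                                tw_step, tw_weights)


def _space(d=2, lo=-5.0, hi=5.0):
    return SearchSpace(np.full(d, lo), np.full(d, hi))


class _ConstRng:
    """Generator stub returning a constant uniform stream."""

    def __init__(self, c):
        self.c = c

    def random(self, shape=None):
        return self.c if shape is None else np.full(shape, self.c)


class TestInitialize:
    def test_rand_zero_gives_lower_bound(self):
        teams = tw_initialize(_space(), 4, _ConstRng(0.0))
        for t in teams:
            np.testing.assert_array_equal(t.position, [-5.0, -5.0])

    def test_rand_one_gives_upper_bound(self):
        teams = tw_initialize(_space(), 4, _ConstRng(1.0))
        for t in teams:
            np.testing.assert_array_equal(t.position, [5.0, 5.0])

    def test_seed_reproducible(self):
        a = tw_initialize(_space(), 6, 42)
        b = tw_initialize(_space(), 6, 42)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.position, tb.position)

    def test_positions_inside_box(self):
        for t in tw_initialize(_space(3, -1, 2), 50, 7):
            assert np.all(t.position >= -1) and np.all(t.position <= 2)


class TestWeights:
    def test_two_team_endpoints(self):
        np.testing.assert_allclose(tw_weights([10.0, 0.0]), [1.0, 2.0])

    def test_affine_interior(self):
        np.testing.assert_allclose(tw_weights([4.0, 2.0, 0.0]),
                                   [1.0, 1.5, 2.0])

    def test_equal_fitness_convention(self):
        np.testing.assert_allclose(tw_weights([3.0, 3.0, 3.0]),
                                   [1.5, 1.5, 1.5])

    def test_range_and_unique_endpoints(self):
        rng = np.random.default_rng(0)
        f = rng.random(20)
        w = tw_weights(f)
        assert np.all((w >= 1.0) & (w <= 2.0))
        assert np.sum(w == 2.0) == 1 and np.sum(w == 1.0) == 1

    def test_maximization_orientation(self):
        np.testing.assert_allclose(tw_weights([10.0, 0.0], minimize=False),
                                   [2.0, 1.0])

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            tw_weights([1.0, math.inf])


class TestSteps:
    def _teams(self, positions, fitnesses):
        teams = [Team(np.asarray(p, dtype=float), f)
                 for p, f in zip(positions, fitnesses)]
        for t, w in zip(teams, tw_weights([t.fitness for t in teams])):
            t.weight = float(w)
        return teams

    def test_equal_weights_pure_perturbation(self):
        # with equal weights the pulling force vanishes; motion is only
        # the (centered) random term
        teams = self._teams([[0.0, 0.0], [1.0, 1.0]], [5.0, 5.0])
        cfg = TWConfig(n_teams=2, seed=0)
        out = tw_step(teams, _space(), cfg, np.random.default_rng(0))
        pull_free = out - np.array([t.position for t in teams])
        assert np.all(np.abs(pull_free) < cfg.beta * 10.0)

    def test_heavier_team_pulls_lighter_toward_it(self):
        # d=1: disable the perturbation via a constant noise stream, which
        # centers to zero; only the pull remains
        teams = self._teams([[0.0], [2.0]], [5.0, 1.0])  # team 1 heavier
        cfg = TWConfig(n_teams=2, seed=0)
        out = tw_step(teams, SearchSpace([-5.0], [5.0]), cfg, _ConstRng(0.3))
        assert out[0, 0] > 0.0           # lighter moved toward x=2
        assert out[1, 0] == 2.0          # heavier did not move

    def test_ctw_tw_bitwise_reduction_with_constant_streams(self):
        # a constant chaotic map and a constant uniform stream produce the
        # same (zero, after centering) perturbation: steps agree bitwise
        teams = self._teams([[0.0, 1.0], [2.0, -1.0], [0.5, 0.5]],
                            [3.0, 1.0, 2.0])
        cfg = TWConfig(n_teams=3, seed=0)

        class _ConstMap(ChaoticMap):
            def __init__(self):
                pass

            def next_value(self, mix=None):
                return 0.37

        a = tw_step(teams, _space(), cfg, _ConstRng(0.37), iteration=2)
        b = ctw_step(teams, _space(), cfg, _ConstMap(), iteration=2)
        np.testing.assert_array_equal(a, b)

    def test_positions_clamped_to_box(self):
        teams = self._teams([[4.9, 4.9], [-4.9, -4.9]], [1.0, 2.0])
        cfg = TWConfig(n_teams=2, beta=0.99, seed=0)
        out = tw_step(teams, _space(), cfg, np.random.default_rng(1))
        assert np.all(out >= -5.0) and np.all(out <= 5.0)


class TestOptimize:
    def test_budget_contract_exact_counting(self):
        calls = []

        def fn(x):
            calls.append(1)
            return float(np.sum(x ** 2))

        res = optimize(fn, _space(), "tw",
                       TWConfig(n_teams=10, max_evaluations=100, seed=0))
        assert len(calls) <= 100
        assert res.n_evaluations == len(calls)

    def test_history_monotone_best_so_far(self):
        fn = BENCHMARK_FUNCTIONS["rastrigin"][0]
        res = optimize(fn, _space(), "ctw",
                       TWConfig(max_evaluations=500, seed=3,
                                map_id="tent"))
        best = [b for _, b in res.history]
        assert all(x >= y for x, y in zip(best, best[1:]))

    def test_constant_fitness_flat_history(self):
        res = optimize(lambda x: 1.0, _space(), "tw",
                       TWConfig(max_evaluations=200, seed=1))
        assert res.best_f == 1.0
        assert {b for _, b in res.history} == {1.0}

    def test_random_method_works(self):
        res = optimize(BENCHMARK_FUNCTIONS["sphere"][0], _space(), "random",
                       TWConfig(max_evaluations=2000, seed=5))
        assert res.best_f < 0.1

    def test_non_finite_fitness_treated_as_worst(self):
        def fn(x):
            return math.nan if x[0] > 0 else float(np.sum(x ** 2))

        with pytest.warns(UserWarning, match="non-finite"):
            res = optimize(fn, _space(), "tw",
                           TWConfig(max_evaluations=200, seed=2))
        assert math.isfinite(res.best_f)

    def test_integer_mask_rounds_at_evaluation(self):
        seen = []

        def fn(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))

        space = SearchSpace([2.0, 2.0], [10.0, 10.0],
                            integer_mask=[True, False])
        optimize(fn, space, "tw", TWConfig(n_teams=5, max_evaluations=50,
                                           seed=0))
        firsts = np.array([x[0] for x in seen])
        np.testing.assert_array_equal(firsts, np.round(firsts))

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown method"):
            optimize(lambda x: 0.0, _space(), "annealing")

    def test_sphere_converges_single_seed(self):
        fn = BENCHMARK_FUNCTIONS["sphere"][0]
        for method in ("tw", "ctw"):
            res = optimize(fn, _space(2, -5.12, 5.12), method,
                           TWConfig(seed=0, map_id="logistic"))
            assert res.best_f < 1e-3


class TestIWD:
    def test_single_layer_recovers_optimum(self):
        candidates = [np.array([1.0, 2.0, 3.0, 4.0, 5.0])]
        for seed in range(20):
            cfg = IWDConfig(n_drops=5, max_iterations=50, seed=seed,
                            max_evaluations=250)
            res = iwd_optimize(lambda x: abs(x[0] - 4.0), candidates, cfg)
            assert res.best_x[0] == 4.0

    def test_uniform_probabilities_for_equal_soil(self):
        from chaolle.optimizers import _iwd_probabilities
        p = _iwd_probabilities(np.full(7, 123.0), eps=1e-4)
        np.testing.assert_allclose(p, 1 / 7, rtol=1e-6)
        # degenerate all-zero mass falls back to uniform
        p0 = _iwd_probabilities(np.full(3, np.inf), eps=1e-4)
        np.testing.assert_allclose(p0, 1 / 3)

    def test_budget_respected(self):
        calls = []
        layers = [np.arange(10.0), np.arange(10.0)]
        cfg = IWDConfig(max_evaluations=97, max_iterations=10 ** 9, seed=0)
        iwd_optimize(lambda x: (calls.append(1), float(x @ x))[1], layers,
                     cfg)
        assert len(calls) <= 97

    def test_empty_layer_raises(self):
        with pytest.raises(ValueError, match="layer"):
            iwd_optimize(lambda x: 0.0, [np.array([])], IWDConfig())


class TestBenchmarkSuite:
    def test_reported_error_non_negative_for_known_minima(self):
        df = benchmark_suite(methods=("random",), functions=("sphere",),
                             reps=3, budget=300)
        assert (df["median_error"] >= 0).all()

    def test_zero_reps_empty_table(self):
        df = benchmark_suite(methods=("random",), functions=("sphere",),
                             reps=0, budget=100)
        assert len(df) == 0

    def test_table_layout(self):
        df = benchmark_suite(methods=("random", "tw"),
                             functions=("sphere", "levy"), reps=2,
                             budget=200)
        assert set(df.index.get_level_values("method")) == {"random", "tw"}
        assert set(df.index.get_level_values("function")) == {"sphere", "levy"}
        assert list(df.columns) == ["median_error", "iqr_error"]


def test_benchmark_function_minima_locations():
    # frozen global minima: f(x*) = 0 at the stated optimum
    x0 = {"sphere": [0, 0], "rosenbrock": [1, 1], "rastrigin": [0, 0],
          "ackley": [0, 0], "griewank": [0, 0], "schwefel_222": [0, 0],
          "levy": [1, 1], "zakharov": [0, 0], "sum_squares": [0, 0]}
    for name, x in x0.items():
        fn = BENCHMARK_FUNCTIONS[name][0]
        assert fn(np.asarray(x, dtype=float)) == pytest.approx(0.0, abs=1e-9)


def test_ctw_not_worse_than_random_on_rastrigin():
    # multimodal 2-D benchmark: the chaotic search's basin-hopping phase
    # must at least match blind uniform sampling at the same budget
    fn = BENCHMARK_FUNCTIONS["rastrigin"][0]
    space = _space(2, -5.12, 5.12)
    ctw = [optimize(fn, space, "ctw",
                    TWConfig(seed=s, map_id="logistic")).best_f
           for s in range(20)]
    rnd = [optimize(fn, space, "random", TWConfig(seed=s)).best_f
           for s in range(20)]
    assert np.median(ctw) <= np.median(rnd)
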
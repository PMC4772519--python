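"""Optimizer tests: LM local solver, discrete selection, global DSLM."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from phagodyn import (
    BenchmarkProblem,
    DiscretizationGrid,
    dslm_minimize,
    lm_minimize,
    select_dimension,
)


class TestLMMinimize:
    def test_linear_least_squares_in_three_iterations(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        x_star, *_ = np.linalg.lstsq(A, y, rcond=None)
        bounds = (-10 * np.ones(4), 10 * np.ones(4))
        res = lm_minimize(lambda x: y - A @ x, np.zeros(4), bounds)
        assert res.outer_iterations <= 3
        assert np.allclose(res.x_best, x_star, atol=1e-8)

    def test_scalar_shift(self):
        res = lm_minimize(lambda x: x - 3.0, [0.0], ([-10.0], [10.0]))
        assert res.x_best[0] == pytest.approx(3.0, abs=1e-8)
        assert res.f_best == pytest.approx(0.0, abs=1e-12)

    def test_rosenbrock_valley(self):
        def resid(x):
            return np.array([10.0 * (x[1] - x[0] ** 2), 1.0 - x[0]])

        bounds = (-10 * np.ones(2), 10 * np.ones(2))
        res = lm_minimize(resid, [-1.2, 1.0], bounds)
        assert res.f_best < 1e-10
        assert np.allclose(res.x_best, [1.0, 1.0], atol=1e-5)
        # independent cross-check: scipy's trust-region reflective solver
        ref = least_squares(resid, [-1.2, 1.0], bounds=([-10, -10], [10, 10]))
        assert res.f_best <= 2 * ref.cost + 1e-10  # cost = F/2

    def test_monotone_trace_and_never_worse_than_start(self):
        prob = BenchmarkProblem("rastrigin", 3)
        rng = np.random.default_rng(5)
        for _ in range(5):
            x0 = rng.uniform(-5.12, 5.12, 3)
            res = lm_minimize(prob.residual_fn, x0, prob.bounds, jac=prob.jac_fn)
            trace = np.array(res.score_trace)
            assert np.all(np.diff(trace) <= 0)
            assert res.f_best <= trace[0]
            assert res.f_best == pytest.approx(
                float(prob.residual_fn(res.x_best) @ prob.residual_fn(res.x_best))
            )

    def test_raises_on_bad_start(self):
        def resid(x):
            raise RuntimeError("model failure")

        with pytest.raises((RuntimeError, ValueError)):
            lm_minimize(resid, [0.0], ([-1.0], [1.0]))

    def test_respects_box(self):
        # unconstrained optimum at x=3 lies outside the box [−1, 2]
        res = lm_minimize(lambda x: x - 3.0, [0.0], ([-1.0], [2.0]))
        assert res.x_best[0] == pytest.approx(2.0, abs=1e-8)


class TestDiscretizationGrid:
    def test_cells_cover_box_exactly(self):
        g = DiscretizationGrid(np.array([0.0]), np.array([1.0]), 4)
        assert np.allclose(g.edges[0], [0.0, 0.25, 0.5, 0.75, 1.0])
        assert g.cell_index(0, 0.0) == 0
        assert g.cell_index(0, 1.0) == 3  # upper edge belongs to last cell
        assert g.cell_index(0, 0.25) == 1  # internal edges open on the left

    def test_mark_range_inclusive_and_monotone(self):
        g = DiscretizationGrid(np.array([0.0]), np.array([1.0]), 10)
        g.mark_range(0, 7, 2)
        assert np.array_equal(np.flatnonzero(g.marks[0]), np.arange(2, 8))
        before = g.fraction_marked()
        g.mark_range(0, 0, 0)
        assert g.fraction_marked() >= before


class TestSelectDimension:
    def test_finds_global_basin_of_1d_rastrigin(self):
        prob = BenchmarkProblem("rastrigin", 1)
        grid = DiscretizationGrid(*prob.bounds, 20)
        x0 = np.array([4.52])  # a far local minimum
        x, f, calls = select_dimension(
            0, x0, grid, prob.residual_fn, prob.bounds, jac=prob.jac_fn
        )
        assert abs(x[0]) < 1e-6
        assert f < 1e-8
        assert np.all(grid.marks[0])  # the sweep visited or marked every cell
        assert calls <= 20

    def test_convex_bowl_matches_single_lm(self):
        resid = lambda x: np.array([x[0] - 0.7])
        bounds = (np.array([-2.0]), np.array([2.0]))
        grid = DiscretizationGrid(*bounds, 8)
        x, f, _ = select_dimension(0, np.array([-1.5]), grid, resid, bounds)
        single = lm_minimize(resid, [-1.5], bounds)
        assert x[0] == pytest.approx(single.x_best[0], abs=1e-8)

    def test_fully_marked_dimension_is_free(self):
        resid = lambda x: np.array([x[0]])
        bounds = (np.array([-1.0]), np.array([1.0]))
        grid = DiscretizationGrid(*bounds, 5)
        grid.marks[0][:] = True
        x0 = np.array([0.3])
        x, f, calls = select_dimension(0, x0, grid, resid, bounds)
        assert calls == 0
        assert np.array_equal(x, x0)


class TestDSLMMinimize:
    def test_rastrigin_2d_reaches_global_minimum(self):
        prob = BenchmarkProblem("rastrigin", 2)
        res = dslm_minimize(prob.residual_fn, prob.bounds, seed=3, jac=prob.jac_fn)
        assert prob.value(res.x_best) < 1e-6

    def test_michalewicz_2d_reaches_known_minimum(self):
        prob = BenchmarkProblem("michalewicz", 2)
        best = min(
            prob.value(
                dslm_minimize(prob.residual_fn, prob.bounds, seed=s, jac=prob.jac_fn).x_best
            )
            for s in range(1, 11)
        )
        assert best == pytest.approx(-1.8013, abs=1e-3)

    def test_convex_problem_converges_in_two_sweeps(self):
        resid = lambda x: x - np.array([0.3, -0.2, 1.1])
        bounds = (-2 * np.ones(3), 2 * np.ones(3))
        res = dslm_minimize(resid, bounds, seed=1)
        single = lm_minimize(resid, np.zeros(3), bounds)
        assert res.f_best == pytest.approx(single.f_best, abs=1e-10)
        assert res.outer_iterations <= 2

    def test_deterministic_given_seed(self):
        prob = BenchmarkProblem("michalewicz", 3)
        a = dslm_minimize(prob.residual_fn, prob.bounds, seed=9, jac=prob.jac_fn)
        b = dslm_minimize(prob.residual_fn, prob.bounds, seed=9, jac=prob.jac_fn)
        assert np.array_equal(a.x_best, b.x_best)
        assert a.score_trace == b.score_trace
        assert a.lm_calls == b.lm_calls

    def test_monotone_trace_and_linear_budget(self):
        prob = BenchmarkProblem("rastrigin", 4)
        res = dslm_minimize(prob.residual_fn, prob.bounds, n_cells=15, seed=2,
                            jac=prob.jac_fn)
        trace = np.array(res.score_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        budget = 4 * 15 + 1
        assert all(c <= budget for c in res.lm_calls_per_sweep)

    def test_doubling_cells_never_hurts(self):
        """Discretization density prunes launches but not solution quality."""
        prob = BenchmarkProblem("michalewicz", 2)
        f20 = prob.value(
            dslm_minimize(prob.residual_fn, prob.bounds, n_cells=20, seed=4,
                          jac=prob.jac_fn).x_best
        )
        f40 = prob.value(
            dslm_minimize(prob.residual_fn, prob.bounds, n_cells=40, seed=4,
                          jac=prob.jac_fn).x_best
        )
        assert f40 <= f20 + 1e-6

    def test_degenerate_box_returns_point_without_iterating(self):
        point = np.array([0.4, 1.2])
        resid = lambda x: x - np.array([1.0, 1.0])
        res = dslm_minimize(resid, (point, point), seed=0)
        assert np.array_equal(res.x_best, point)
        assert res.outer_iterations == 0
        assert res.lm_calls == 0
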
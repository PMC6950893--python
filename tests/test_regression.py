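"""LR / NLR / LGR estimator behavior against analytic and brute-force oracles."""

import itertools

import numpy as np
import pytest

from glvnet import (
    AbundanceSeries, GLVLinearRegression, GLVNonlinearRegression,
    GLVParameters, LatentGradientRegression, PenaltyConfig, SignConstraintSet,
    estimate_gradients_spline, fit_lgr, fit_lr, select_penalty_loocv,
    simulate_glv,
)
from glvnet.preprocessing import LatentGradients
from glvnet.regression import _initial_state
from glvnet.synthetic import SyntheticSpec


def exact_gradients(truth, series):
    """d ln x/dt = alpha + beta x, the gLV identity at the samples."""
    return LatentGradients(g=truth.alpha[:, None] + truth.beta @ series.values)


class TestLinearRegression:
    def test_exact_gradient_consistency(self, rng):
        """If g is exactly alpha + beta X the regression recovers the truth."""
        truth = GLVParameters(
            alpha=np.array([0.5, -0.2]),
            beta=np.array([[-1.0, -0.3], [0.4, -0.8]]),
        )
        times = np.linspace(0.0, 8.0, 17)
        x = simulate_glv(truth, np.array([0.3, 0.5]), times)
        g = exact_gradients(truth, x)
        est = fit_lr(x, g=g)
        assert np.allclose(est.alpha, truth.alpha, atol=1e-6)
        assert np.allclose(est.beta, truth.beta, atol=1e-6)

    def test_dense_logistic_recovery_from_spline_gradients(self):
        truth = GLVParameters(alpha=[1.0], beta=[[-1.0]])
        times = np.linspace(0.0, 10.0, 200)
        x = simulate_glv(truth, [0.05], times)
        est = fit_lr(x)
        assert abs(est.alpha[0] - 1.0) < 0.01
        assert abs(est.beta[0, 0] + 1.0) < 0.01

    def test_active_bound_matches_grid_search(self):
        """A truly positive coupling constrained negative lands on the bound,
        agreeing with a brute-force search over the constrained region."""
        rng = np.random.default_rng(3)
        m = 30
        x1 = rng.uniform(0.2, 1.0, m)
        x2 = rng.uniform(0.2, 1.0, m)
        # true model for species 1: g = -0.5 x1 + 0.8 x2 (alpha pinned to 0)
        g1 = -0.5 * x1 + 0.8 * x2
        values = np.vstack([x1, x2])
        series = AbundanceSeries(("s1", "s2"), np.arange(m, dtype=float),
                                 values[:, np.argsort(np.arange(m))])
        cons = SignConstraintSet(
            alpha_sign=np.array(["zero", "zero"], dtype=object),
            beta_sign=np.array([["negative", "negative"],
                                ["zero", "negative"]], dtype=object),
        )
        g = LatentGradients(g=np.vstack([g1, -0.5 * x2]))
        est = fit_lr(series, g=g, constraints=cons)
        assert est.beta[0, 1] == pytest.approx(0.0, abs=1e-9)
        # brute force over (beta_11, beta_12) in the constrained quadrant
        grid = np.linspace(-2.0, 0.0, 201)
        best = min(
            ((b11, b12) for b11 in grid for b12 in grid),
            key=lambda p: np.sum((p[0] * x1 + p[1] * x2 - g1) ** 2),
        )
        assert est.beta[0, 0] == pytest.approx(best[0], abs=0.01)
        assert est.beta[0, 1] == pytest.approx(best[1], abs=0.01)

    def test_ridge_penalty_shrinks_off_diagonals(self, benchmark, benchmark_series):
        _, cons = benchmark
        plain = GLVLinearRegression(constraints=cons).fit(benchmark_series)
        ridged = GLVLinearRegression(
            constraints=cons, lambda_beta=10.0
        ).fit(benchmark_series)
        off = ~np.eye(3, dtype=bool)
        assert np.sum(np.abs(ridged.beta_[off])) < np.sum(np.abs(plain.beta_[off]))


class TestNonlinearRegression:
    def test_truth_is_a_fixed_point(self, benchmark, benchmark_series):
        spec, cons = benchmark
        est = GLVNonlinearRegression(constraints=cons).fit(
            benchmark_series, init=spec.truth
        )
        assert est.objective_trace_[0] < 1e-10
        assert np.allclose(est.alpha_, spec.truth.alpha, atol=1e-4)
        assert np.allclose(est.beta_, spec.truth.beta, atol=1e-4)

    def test_logistic_recovery_from_perturbed_init(self):
        truth = GLVParameters(alpha=[1.0], beta=[[-1.0]])
        times = np.linspace(0.0, 10.0, 25)
        x = simulate_glv(truth, [0.1], times)
        init = GLVParameters(alpha=[1.1], beta=[[-0.9]])
        est = GLVNonlinearRegression().fit(x, init=init)
        assert abs(est.alpha_[0] - 1.0) < 1e-3
        assert abs(est.beta_[0, 0] + 1.0) < 1e-3

    def test_infeasible_init_rejected(self, benchmark, benchmark_series):
        _, cons = benchmark
        bad = GLVParameters(alpha=[-1.0, 0.5, 0.5], beta=np.eye(3) * -1.0)
        with pytest.raises(ValueError):
            GLVNonlinearRegression(constraints=cons).fit(benchmark_series, init=bad)


class TestLatentGradientRegression:
    def test_exact_initialization_converges_immediately(self, benchmark, benchmark_series):
        spec, cons = benchmark
        g0 = exact_gradients(spec.truth, benchmark_series)
        est = LatentGradientRegression(constraints=cons).fit(
            benchmark_series, init_gradients=g0
        )
        assert est.n_iter_ <= 3
        assert est.objective_trace_[-1] < 1e-8

    def test_objective_trace_monotone(self, benchmark_lgr):
        trace = benchmark_lgr.objective_trace
        assert np.all(np.diff(trace) <= 1e-12)

    def test_sign_feasibility_of_fit(self, benchmark, benchmark_lgr):
        _, cons = benchmark
        assert cons.is_satisfied_by(benchmark_lgr.params, atol=1e-12)

    def test_local_optimality_of_solution(self, benchmark, benchmark_series, benchmark_lgr):
        """Perturbing the optimized gradients in random directions never
        improves the objective (probe of the trust-region solution)."""
        spec, cons = benchmark
        rng = np.random.default_rng(1)
        base = fit_objective(benchmark_series, benchmark_lgr.gradients.g, cons)
        for _ in range(5):
            step = rng.normal(0, 1e-3, benchmark_lgr.gradients.g.shape)
            probe = fit_objective(
                benchmark_series, benchmark_lgr.gradients.g + step, cons
            )
            assert probe >= base - 1e-10

    def test_spline_init_gives_good_inner_lr(self, benchmark, benchmark_series):
        """Noise-free gLV data: spline gradients start the inner regression
        close enough for a strong first fit."""
        _, cons = benchmark
        from glvnet.metrics import adjusted_r2

        g0 = estimate_gradients_spline(benchmark_series)
        est = GLVLinearRegression(constraints=cons).fit(
            benchmark_series, gradients=g0
        )
        pred = est.alpha_[:, None] + est.beta_ @ benchmark_series.values
        assert adjusted_r2(g0.g, pred, cons.n_free_parameters()) > 0.9


def fit_objective(series, g, cons):
    """Recompute the LGR objective at a gradient matrix (independent path)."""
    from glvnet.regression import _inner_lr, _params_from_theta

    theta, _ = _inner_lr(series.values, g, cons, PenaltyConfig())
    xhat = simulate_glv(
        _params_from_theta(theta), _initial_state(series.values), series.times
    ).values
    return float(np.sum((xhat - series.values) ** 2))


@pytest.fixture(scope="module")
def short_series(benchmark):
    spec, cons = benchmark
    short = SyntheticSpec(
        truth=spec.truth, x0=spec.x0, sample_interval=5.0, horizon=50.0,
        diffusion=spec.diffusion,
    )
    return short.simulate_deterministic(), cons


class TestPenaltySelection:

    def test_single_candidate_returned(self, short_series):
        x, cons = short_series
        only = PenaltyConfig(0.1, 0.2)
        assert select_penalty_loocv(x, cons, [only]) is only

    def test_noise_free_data_selects_zero_penalty(self, short_series):
        """On noise-free data regularization can only hurt, and the winner
        equals an exhaustive recomputation of held-out errors."""
        x, cons = short_series
        grid = [PenaltyConfig(a, b) for a in (0.0, 10.0) for b in (0.0, 10.0)]
        winner = select_penalty_loocv(x, cons, grid)
        assert winner.lambda_alpha == 0.0 and winner.lambda_beta == 0.0
        # independent brute force over the same grid
        mid = x.n_times // 2
        keep = np.ones(x.n_times, dtype=bool)
        keep[mid] = False
        train = x.subset_times(keep)
        sses = []
        for cfg in grid:
            res = fit_lgr(train, constraints=cons, penalty=cfg)
            xhat = simulate_glv(
                res.params, _initial_state(train.values), x.times
            ).values
            sses.append(float(np.sum((x.values[:, mid] - xhat[:, mid]) ** 2)))
        assert grid[int(np.argmin(sses))] is winner
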
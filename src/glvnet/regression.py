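"""gLV parameterization by linear, nonlinear and latent gradient regression.

Three estimators fit the community model to a species-by-time matrix under
per-coefficient sign restrictions and an optional ridge penalty (diagonal
self-limitation terms are never penalized):

* :class:`GLVLinearRegression` (LR) -- the classical gradient-matching
  approach: regress numerically estimated log-abundance derivatives on
  ``[1; X]`` per species, a bounded linear least-squares problem.
* :class:`GLVNonlinearRegression` (NLR) -- bound-constrained trust-region
  nonlinear least squares over the coefficients themselves, minimizing the
  simulated-versus-observed residual.
* :class:`LatentGradientRegression` (LGR) -- the same simulation residual, but
  searched over the *latent gradients* g: every trial g is mapped to
  coefficients by the inner constrained linear regression, the model is
  simulated, and g is updated by a Levenberg-Marquardt-type trust-region step.
  Optimizing g instead of the coefficients sidesteps the error amplification
  of finite-difference gradients on sparse noisy data.

All estimators follow scikit-learn conventions: ``fit`` accepts either an
:class:`~glvnet.series.AbundanceSeries` or a (n_times, n_species) array plus a
``times`` keyword, fitted attributes carry trailing underscores, and
``get_params``/``set_params`` work as usual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, least_squares
from sklearn.base import BaseEstimator

from .dynamics import SimulationDiverged, simulate_glv
from .metrics import adjusted_r2, smape
from .params import GLVParameters, SignConstraintSet
from .preprocessing import LatentGradients, default_floor, estimate_gradients_spline
from .series import AbundanceSeries

logger = logging.getLogger(__name__)

_FAILED_RESIDUAL = 1e6  # sentinel residual for diverged trial simulations
_BOUND_TOL = 1e-10


@dataclass(frozen=True)
class PenaltyConfig:
    """Ridge penalty weights for growth rates and off-diagonal interactions."""

    lambda_alpha: float = 0.0
    lambda_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_alpha < 0 or self.lambda_beta < 0:
            raise ValueError("penalty coefficients must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one gLV fit: coefficients, diagnostics and convergence."""

    params: GLVParameters
    gradients: LatentGradients | None
    objective_trace: np.ndarray
    adjusted_r2: float
    smape: float
    converged: bool


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _unpack(X, times):
    """Normalize input to (values N x M, times, species_ids)."""
    if isinstance(X, AbundanceSeries):
        return X.values, X.times, X.species_ids
    values = np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise ValueError("X must be 2-D")
    values = values.T  # samples-as-rows convention -> species x time
    if times is None:
        times = np.arange(values.shape[1], dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    if times.size != values.shape[1]:
        raise ValueError("times length does not match the number of samples")
    return values, times, None


def _initial_state(values: np.ndarray) -> np.ndarray:
    """First observed abundances, floored away from the absorbing zero state."""
    x0 = values[:, 0].copy()
    floors = default_floor(values)
    zero = x0 == 0.0
    if np.any(zero & (values.max(axis=1) > 0)):
        x0[zero] = floors[zero]
    return x0


def _penalty_weights(n: int, penalty: PenaltyConfig) -> np.ndarray:
    """sqrt-penalty per coefficient in theta order [alpha_i, beta_i1..beta_iN]."""
    w = np.zeros((n, n + 1))
    w[:, 0] = np.sqrt(penalty.lambda_alpha)
    w[:, 1:] = np.sqrt(penalty.lambda_beta)
    w[np.arange(n), np.arange(n) + 1] = 0.0  # self-limitation unpenalized
    return w


def _solve_species_lr(A, target, lo, hi, pen_sqrt):
    """Bounded, penalized linear least squares for one species' coefficients.

    Returns the full coefficient vector (fixed-zero entries included) and the
    boolean mask of locally varying (interior, non-fixed) coefficients.
    """
    fixed = (lo == 0.0) & (hi == 0.0)
    free = ~fixed
    theta = np.zeros(lo.size)
    if not np.any(free):
        return theta, np.zeros(lo.size, dtype=bool)
    A_f = A[:, free]
    pen_f = pen_sqrt[free]
    if np.all(pen_f == 0.0) and np.linalg.matrix_rank(A_f) < A_f.shape[1]:
        logger.warning("rank-deficient design with zero penalty; least-norm solution used")
    rows = [A_f]
    b = [target]
    if np.any(pen_f > 0):
        rows.append(np.diag(pen_f))
        b.append(np.zeros(pen_f.size))
    res = lsq_linear(
        np.vstack(rows), np.concatenate(b), bounds=(lo[free], hi[free]),
        method="bvls" if np.vstack(rows).shape[0] >= A_f.shape[1] else "trf",
        tol=1e-12,
    )
    theta[free] = res.x
    interior = np.zeros(lo.size, dtype=bool)
    at_bound = (
        (np.isfinite(lo[free]) & (res.x <= lo[free] + _BOUND_TOL))
        | (np.isfinite(hi[free]) & (res.x >= hi[free] - _BOUND_TOL))
    )
    interior[free] = ~at_bound
    return theta, interior


def _inner_lr(values, g, constraints, penalty):
    """Map latent gradients to coefficients by per-species constrained LR."""
    n, m = values.shape
    A = np.hstack([np.ones((m, 1)), values.T])
    w = _penalty_weights(n, penalty)
    theta = np.zeros((n, n + 1))
    interior = np.zeros((n, n + 1), dtype=bool)
    for i in range(n):
        lo, hi = constraints.bounds_row(i)
        theta[i], interior[i] = _solve_species_lr(A, g[i], lo, hi, w[i])
    return theta, interior


def _theta_sensitivity(values, interior_row, pen_sqrt_row):
    """d theta_i / d g_i for the locally active set of the inner regression."""
    m = values.shape[1]
    A = np.hstack([np.ones((m, 1)), values.T])
    s = interior_row
    D = np.zeros((interior_row.size, m))
    if np.any(s):
        A_s = A[:, s]
        normal = A_s.T @ A_s + np.diag(pen_sqrt_row[s] ** 2)
        D[s] = np.linalg.pinv(normal) @ A_s.T
    return D


def _params_from_theta(theta, species_ids=None) -> GLVParameters:
    return GLVParameters(
        alpha=theta[:, 0], beta=theta[:, 1:],
        species_ids=tuple(species_ids) if species_ids else None,
    )


def _fit_statistics(values, times, x0, params, n_free):
    """Simulate the fitted model and score it; divergence scores worst-case."""
    try:
        xhat = simulate_glv(params, x0, times).values
    except SimulationDiverged:
        return -np.inf, 1.0
    return adjusted_r2(values, xhat, n_free), smape(values, xhat)


def _running_min(history: list[float]) -> np.ndarray:
    """Accepted-step objective trace: the prefix minimum of all evaluations."""
    if not history:
        return np.empty(0)
    return np.minimum.accumulate(np.asarray(history))


class _BaseGLVRegressor(BaseEstimator):
    """Shared fit/predict plumbing for the three gLV estimators."""

    def _resolve_constraints(self, n: int) -> SignConstraintSet:
        if self.constraints is None:
            return SignConstraintSet.unconstrained(n)
        if self.constraints.n_species != n:
            raise ValueError(
                f"constraints cover {self.constraints.n_species} species, data has {n}"
            )
        return self.constraints

    @property
    def params_(self) -> GLVParameters:
        return GLVParameters(alpha=self.alpha_, beta=self.beta_, species_ids=self.species_ids_)

    def predict(self, times=None, x0=None) -> np.ndarray:
        """Simulate the fitted model; returns an (n_times, n_species) array."""
        if times is None:
            times = self.times_
        if x0 is None:
            x0 = self.x0_
        return simulate_glv(self.params_, x0, np.asarray(times, dtype=float)).values.T

    def predict_series(self, times=None, x0=None) -> AbundanceSeries:
        if times is None:
            times = self.times_
        if x0 is None:
            x0 = self.x0_
        return simulate_glv(
            self.params_, x0, np.asarray(times, dtype=float),
            species_ids=self.species_ids_,
        )

    def score(self, X=None, y=None, times=None) -> float:
        """Adjusted R^2 of the simulated trajectories against ``X``.

        With no argument, scores the training data seen by ``fit``.
        """
        if X is None:
            return self.adjusted_r2_
        values, t, _ = _unpack(X, times)
        xhat = simulate_glv(self.params_, _initial_state(values), t).values
        return adjusted_r2(values, xhat, self.n_free_parameters_)

    def _store_common(self, theta, values, times, species_ids, constraints):
        n = values.shape[0]
        self.alpha_ = theta[:, 0]
        self.beta_ = theta[:, 1:]
        self.species_ids_ = tuple(species_ids) if species_ids else tuple(
            f"sp{i+1}" for i in range(n)
        )
        self.times_ = times
        self.x0_ = _initial_state(values)
        self.n_features_in_ = n
        self.n_free_parameters_ = constraints.n_free_parameters()
        self.adjusted_r2_, self.smape_ = _fit_statistics(
            values, times, self.x0_, self.params_, self.n_free_parameters_
        )


# ---------------------------------------------------------------------------
# linear regression (gradient matching)
# ---------------------------------------------------------------------------

class GLVLinearRegression(_BaseGLVRegressor):
    """Classical gradient-matching fit of a gLV model.

    Per species i, solves the bounded penalized linear least squares
    ``min || alpha_i + beta_i . X - g_i ||^2 + penalty`` where g_i are the
    log-abundance derivatives (supplied, or estimated by spline
    differentiation of the data).  Sign restrictions are enforced as box
    bounds, so with a zero penalty the solution is the exact constrained
    least-squares minimizer.

    Parameters
    ----------
    constraints : SignConstraintSet, optional
        Per-coefficient sign restrictions; default unconstrained.
    lambda_alpha, lambda_beta : float
        Ridge weights on growth rates and off-diagonal interactions.
    """

    def __init__(self, constraints: SignConstraintSet | None = None,
                 lambda_alpha: float = 0.0, lambda_beta: float = 0.0):
        self.constraints = constraints
        self.lambda_alpha = lambda_alpha
        self.lambda_beta = lambda_beta

    def fit(self, X, y=None, *, times=None, gradients: LatentGradients | None = None):
        values, t, ids = _unpack(X, times)
        constraints = self._resolve_constraints(values.shape[0])
        penalty = PenaltyConfig(self.lambda_alpha, self.lambda_beta)
        if gradients is None:
            series = X if isinstance(X, AbundanceSeries) else AbundanceSeries(
                species_ids=tuple(f"sp{i+1}" for i in range(values.shape[0])),
                times=t, values=values,
            )
            gradients = estimate_gradients_spline(series)
        g = gradients.g
        if g.shape != values.shape:
            raise ValueError("gradient matrix shape does not match the data")
        theta, _ = _inner_lr(values, g, constraints, penalty)
        self.gradients_ = gradients
        self._store_common(theta, values, t, ids, constraints)
        return self


# ---------------------------------------------------------------------------
# nonlinear regression over the coefficients
# ---------------------------------------------------------------------------

class GLVNonlinearRegression(_BaseGLVRegressor):
    """Trust-region nonlinear least squares over the gLV coefficients.

    Minimizes ``||X - Xhat(alpha, beta)||_F^2 + penalty`` with sign
    restrictions as box bounds, starting from a supplied initial
    parameterization (default: the constrained linear-regression fit).  A
    diverging trial simulation yields a large finite residual, so the trust
    region shrinks around it rather than aborting the fit.
    """

    def __init__(self, constraints: SignConstraintSet | None = None,
                 lambda_alpha: float = 0.0, lambda_beta: float = 0.0,
                 tol: float = 1e-8, max_iter: int = 100):
        self.constraints = constraints
        self.lambda_alpha = lambda_alpha
        self.lambda_beta = lambda_beta
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, times=None, init: GLVParameters | None = None):
        values, t, ids = _unpack(X, times)
        n = values.shape[0]
        constraints = self._resolve_constraints(n)
        penalty = PenaltyConfig(self.lambda_alpha, self.lambda_beta)
        if init is None:
            lr = GLVLinearRegression(
                constraints=constraints, lambda_alpha=self.lambda_alpha,
                lambda_beta=self.lambda_beta,
            ).fit(X, times=times)
            init = lr.params_
        theta0 = np.hstack([init.alpha[:, None], init.beta])
        if not constraints.is_satisfied_by(init, atol=1e-12):
            raise ValueError("initial parameters violate the sign constraints")
        lo = np.empty((n, n + 1))
        hi = np.empty((n, n + 1))
        for i in range(n):
            lo[i], hi[i] = constraints.bounds_row(i)
        fixed = (lo == 0.0) & (hi == 0.0)
        free = ~fixed
        w = _penalty_weights(n, penalty)
        x0 = _initial_state(values)
        history: list[float] = []

        def residual(theta_free):
            theta = np.zeros((n, n + 1))
            theta[free] = theta_free
            params = _params_from_theta(theta)
            try:
                xhat = simulate_glv(params, x0, t).values
                r = np.concatenate([(xhat - values).ravel(), (w * theta)[free]])
            except SimulationDiverged:
                r = np.full(values.size + int(free.sum()), _FAILED_RESIDUAL)
            history.append(float(np.sum(r ** 2)))
            return r

        n_free = int(free.sum())
        result = least_squares(
            residual, np.clip(theta0[free], lo[free], hi[free]),
            bounds=(lo[free], hi[free]), method="trf",
            ftol=self.tol, xtol=1e-12, gtol=1e-12,
            max_nfev=self.max_iter * (n_free + 1),
        )
        theta = np.zeros((n, n + 1))
        theta[free] = result.x
        self._store_common(theta, values, t, ids, constraints)
        self.objective_trace_ = _running_min(history)
        self.converged_ = bool(result.status > 0)
        self.n_iter_ = int(result.nfev)
        return self

    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_, gradients=None,
            objective_trace=self.objective_trace_,
            adjusted_r2=self.adjusted_r2_, smape=self.smape_,
            converged=self.converged_,
        )


# ---------------------------------------------------------------------------
# latent gradient regression
# ---------------------------------------------------------------------------

class LatentGradientRegression(_BaseGLVRegressor):
    """gLV fit by optimizing the latent log-abundance gradients.

    The objective ``||X - Xhat(alpha(g), beta(g))||_F^2 + J(alpha, beta)`` is
    minimized over the N x M gradient matrix g.  Each evaluation maps g to
    coefficients through the inner sign-constrained linear regression, then
    simulates the model from the first observation; g is updated by a
    trust-region (Levenberg-Marquardt-type) step.  The Jacobian with respect
    to g factors through the coefficients: d Xhat/d theta is computed by
    forward finite differences (one simulation per locally varying
    coefficient) and d theta/d g analytically from the inner regression's
    active set, which keeps the cost per iteration at O(N^2) simulations
    instead of O(N*M).

    Parameters
    ----------
    constraints : SignConstraintSet, optional
    lambda_alpha, lambda_beta : float
        Ridge weights (self-limitation terms are never penalized).
    tol : float
        Relative objective-change stopping tolerance of the outer loop.
    max_iter : int
        Cap on trust-region iterations.
    fd_step : float
        Relative forward-difference step for d Xhat/d theta.  The default
        balances truncation error against the ODE solver's own error; steps
        much smaller than sqrt(solver tolerance) make the Jacobian noisy.
    """

    def __init__(self, constraints: SignConstraintSet | None = None,
                 lambda_alpha: float = 0.0, lambda_beta: float = 0.0,
                 tol: float = 1e-8, max_iter: int = 100, fd_step: float = 1e-4):
        self.constraints = constraints
        self.lambda_alpha = lambda_alpha
        self.lambda_beta = lambda_beta
        self.tol = tol
        self.max_iter = max_iter
        self.fd_step = fd_step

    def fit(self, X, y=None, *, times=None, init_gradients: LatentGradients | None = None):
        values, t, ids = _unpack(X, times)
        n, m = values.shape
        constraints = self._resolve_constraints(n)
        penalty = PenaltyConfig(self.lambda_alpha, self.lambda_beta)
        if init_gradients is None:
            series = X if isinstance(X, AbundanceSeries) else AbundanceSeries(
                species_ids=tuple(f"sp{i+1}" for i in range(n)), times=t, values=values,
            )
            init_gradients = estimate_gradients_spline(series)
        g0 = init_gradients.g
        if g0.shape != values.shape:
            raise ValueError("gradient matrix shape does not match the data")
        x0 = _initial_state(values)
        w = _penalty_weights(n, penalty)
        w_flat = w.ravel()
        n_res = values.size + w_flat.size
        history: list[float] = []
        cache: dict[bytes, tuple] = {}

        def evaluate(gflat):
            key = gflat.tobytes()
            if key in cache:
                return cache[key]
            g = gflat.reshape(n, m)
            theta, interior = _inner_lr(values, g, constraints, penalty)
            params = _params_from_theta(theta)
            try:
                xhat = simulate_glv(params, x0, t).values
            except SimulationDiverged:
                xhat = None
            if len(cache) > 8:
                cache.clear()
            cache[key] = (theta, interior, xhat)
            return cache[key]

        def residual(gflat):
            theta, _, xhat = evaluate(gflat)
            if xhat is None:
                r = np.full(n_res, _FAILED_RESIDUAL)
            else:
                r = np.concatenate([(xhat - values).ravel(), w_flat * theta.ravel()])
            history.append(float(np.sum(r ** 2)))
            return r

        def jacobian(gflat):
            theta, interior, xhat = evaluate(gflat)
            if xhat is None:
                return np.zeros((n_res, gflat.size))
            # d theta_i / d g_i from the inner regression's active set
            D_blocks = [
                _theta_sensitivity(values, interior[i], w[i]) for i in range(n)
            ]
            # d Xhat / d theta by forward differences, one simulation per
            # locally varying coefficient
            J_data = np.zeros((values.size, n * (n + 1)))
            for i in range(n):
                for c in range(n + 1):
                    if not interior[i, c]:
                        continue
                    p = i * (n + 1) + c
                    h = self.fd_step * max(abs(theta[i, c]), 1.0)
                    theta_p = theta.copy()
                    theta_p[i, c] += h
                    try:
                        xhat_p = simulate_glv(_params_from_theta(theta_p), x0, t).values
                    except SimulationDiverged:
                        continue
                    J_data[:, p] = (xhat_p - xhat).ravel() / h
            # assemble d residual / d g through the block-diagonal d theta/d g
            J = np.zeros((n_res, gflat.size))
            for i in range(n):
                cols = slice(i * m, (i + 1) * m)
                block = J_data[:, i * (n + 1):(i + 1) * (n + 1)]
                J[:values.size, cols] = block @ D_blocks[i]
                rows = slice(values.size + i * (n + 1), values.size + (i + 1) * (n + 1))
                J[rows, cols] = w[i][:, None] * D_blocks[i]
            return J

        cost0 = float(np.sum(residual(g0.ravel()) ** 2))
        if cost0 <= 1e-18 * (1.0 + float(np.sum(values ** 2))):
            # the initialization is already an (essentially exact) optimum
            g_opt, converged, n_iter = g0.ravel(), True, 1
        else:
            result = least_squares(
                residual, g0.ravel(), jac=jacobian, method="trf",
                ftol=self.tol, xtol=1e-12, gtol=1e-14,
                max_nfev=self.max_iter,
            )
            g_opt, converged, n_iter = result.x, bool(result.status > 0), int(result.nfev)
        theta, _, _ = evaluate(g_opt)
        self.gradients_ = LatentGradients(g=g_opt.reshape(n, m))
        self._store_common(theta, values, t, ids, constraints)
        self.objective_trace_ = _running_min(history)
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_, gradients=self.gradients_,
            objective_trace=self.objective_trace_,
            adjusted_r2=self.adjusted_r2_, smape=self.smape_,
            converged=self.converged_,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_lr(x: AbundanceSeries, g: LatentGradients | None = None,
           constraints: SignConstraintSet | None = None,
           penalty: PenaltyConfig = PenaltyConfig()) -> GLVParameters:
    """Constrained linear-regression fit; see :class:`GLVLinearRegression`."""
    est = GLVLinearRegression(
        constraints=constraints, lambda_alpha=penalty.lambda_alpha,
        lambda_beta=penalty.lambda_beta,
    ).fit(x, gradients=g)
    return est.params_


def fit_nlr(x: AbundanceSeries, constraints: SignConstraintSet | None = None,
            init: GLVParameters | None = None,
            penalty: PenaltyConfig = PenaltyConfig()) -> FitResult:
    """Nonlinear-regression fit; see :class:`GLVNonlinearRegression`."""
    est = GLVNonlinearRegression(
        constraints=constraints, lambda_alpha=penalty.lambda_alpha,
        lambda_beta=penalty.lambda_beta,
    ).fit(x, init=init)
    return est.result_()


def fit_lgr(x: AbundanceSeries, constraints: SignConstraintSet | None = None,
            penalty: PenaltyConfig = PenaltyConfig(),
            init_g: LatentGradients | None = None,
            **kwargs) -> FitResult:
    """Latent-gradient-regression fit; see :class:`LatentGradientRegression`."""
    est = LatentGradientRegression(
        constraints=constraints, lambda_alpha=penalty.lambda_alpha,
        lambda_beta=penalty.lambda_beta, **kwargs,
    ).fit(x, init_gradients=init_g)
    return est.result_()


def select_penalty_loocv(
    x: AbundanceSeries,
    constraints: SignConstraintSet | None,
    grid: list[PenaltyConfig],
    **lgr_kwargs,
) -> PenaltyConfig:
    """Pick ridge weights by held-out error at the middle time point.

    For each candidate, LGR is fit on the series with the middle observation
    removed, the model is simulated over the full grid, and the candidate's
    score is the summed squared error at the held-out time.  The minimizer is
    returned; the caller refits on the complete series with it.
    """
    if not grid:
        raise ValueError("penalty grid is empty")
    if x.n_times < 5:
        raise ValueError("leave-one-out selection needs at least 5 time points")
    mid = x.n_times // 2
    keep = np.ones(x.n_times, dtype=bool)
    keep[mid] = False
    train = x.subset_times(keep)
    best, best_sse = None, np.inf
    failures = []
    for cfg in grid:
        try:
            res = fit_lgr(train, constraints=constraints, penalty=cfg, **lgr_kwargs)
            xhat = simulate_glv(res.params, _initial_state(train.values), x.times).values
        except (SimulationDiverged, ValueError) as exc:
            failures.append((cfg, str(exc)))
            continue
        sse = float(np.sum((x.values[:, mid] - xhat[:, mid]) ** 2))
        if sse < best_sse:
            best, best_sse = cfg, sse
    if best is None:
        raise RuntimeError(f"no penalty configuration converged; failures: {failures}")
    return best
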
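"""Confidence scores, ensemble summaries and exogenous-susceptibility fits.

The confidence score of a fitted coefficient is 1 minus the p-value of the
two-sided t-test that the coefficient is zero -- equivalently, 1 minus the
smallest significance level at which its nonlinear-regression confidence
interval touches zero.  Standard errors come from the finite-difference
Jacobian of the simulated trajectories at the estimate:

    se_p = s * sqrt([(J^T J)^-1]_pp),   s = ||X - Xhat||_F / sqrt(df),

with df = (number of data values) - (number of free coefficients); sign-fixed
zero coefficients are excluded from the count and reported with score 0.
Averaging scores over an ensemble gives a more conservative evidence measure
than any single member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .dynamics import SimulationDiverged, simulate_glv, simulate_glv_exogenous
from .ensemble import Ensemble, EnsembleMember
from .metrics import adjusted_r2  # noqa: F401  (public here as well)
from .params import GLVParameters, SignConstraintSet
from .regression import _initial_state
from .series import AbundanceSeries, ExogenousSeries

_FD_STEP = 1e-4


@dataclass(frozen=True)
class ConfidenceReport:
    """Per-coefficient estimates, t-based confidence scores and df."""

    alpha_estimate: np.ndarray
    beta_estimate: np.ndarray
    alpha_score: np.ndarray
    beta_score: np.ndarray
    df: int
    alpha_se: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    species_ids: tuple[str, ...] | None = None

    def alpha_interval(self, i: int, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for species i's growth rate."""
        if self.alpha_se is None:
            raise ValueError("standard errors unavailable")
        q = stats.t.ppf(0.5 + level / 2.0, self.df)
        half = q * self.alpha_se[i]
        return (self.alpha_estimate[i] - half, self.alpha_estimate[i] + half)

    def beta_interval(self, i: int, j: int, level: float = 0.95) -> tuple[float, float]:
        if self.beta_se is None:
            raise ValueError("standard errors unavailable")
        q = stats.t.ppf(0.5 + level / 2.0, self.df)
        half = q * self.beta_se[i, j]
        return (self.beta_estimate[i, j] - half, self.beta_estimate[i, j] + half)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per coefficient, heatmap-ready ordering
        (rows = affected species, columns = affecting species, growth last)."""
        ids = self.species_ids or tuple(f"sp{i+1}" for i in range(self.alpha_estimate.size))
        rows = []
        for i, si in enumerate(ids):
            for j, sj in enumerate(ids):
                rows.append({
                    "parameter": "beta", "species_row": si, "species_col": sj,
                    "estimate": self.beta_estimate[i, j],
                    "confidence": self.beta_score[i, j],
                })
            rows.append({
                "parameter": "alpha", "species_row": si, "species_col": "growth",
                "estimate": self.alpha_estimate[i],
                "confidence": self.alpha_score[i],
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SusceptibilityFit:
    """One-at-a-time susceptibility estimates with confidence scores."""

    epsilon: np.ndarray
    score: np.ndarray
    fitted: np.ndarray  # False where the coefficient was pinned or unidentifiable
    species_ids: tuple[str, ...] | None = None


def _t_scores(estimates: np.ndarray, ses: np.ndarray, df: int) -> np.ndarray:
    """Confidence score 1 - p for each estimate/standard-error pair."""
    scores = np.zeros_like(estimates, dtype=float)
    for k, (z, se) in enumerate(zip(estimates, ses)):
        if not np.isfinite(se):
            scores[k] = 0.0
        elif se == 0.0:
            scores[k] = 1.0 if z != 0.0 else 0.0
        else:
            p = 2.0 * stats.t.sf(abs(z) / se, df)
            scores[k] = 1.0 - p
    return np.clip(scores, 0.0, 1.0)


def parameter_confidence(
    params: GLVParameters,
    x: AbundanceSeries,
    constraints: SignConstraintSet | None = None,
    x0: np.ndarray | None = None,
    fd_step: float = _FD_STEP,
) -> ConfidenceReport:
    """t-based confidence scores for every free gLV coefficient.

    The Jacobian of the simulated trajectories with respect to the free
    coefficients is computed by forward finite differences at the estimate.
    Coefficients with no trajectory sensitivity (singular J^T J) are flagged
    with score 0 -- the data carry no information about them.
    """
    n = params.n_species
    if constraints is None:
        constraints = SignConstraintSet.unconstrained(n)
    theta = np.hstack([params.alpha[:, None], params.beta])
    free = np.ones((n, n + 1), dtype=bool)
    for i in range(n):
        lo, hi = constraints.bounds_row(i)
        free[i] = ~((lo == 0.0) & (hi == 0.0))
    n_free = int(free.sum())
    df = x.values.size - n_free
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if x0 is None:
        x0 = _initial_state(x.values)
    xhat = simulate_glv(params, x0, x.times).values
    resid_norm = float(np.linalg.norm(x.values - xhat))
    s = resid_norm / np.sqrt(df)

    J = np.zeros((x.values.size, n_free))
    flat_idx = np.where(free.ravel())[0]
    for col, p in enumerate(flat_idx):
        i, c = divmod(p, n + 1)
        h = fd_step * max(abs(theta[i, c]), 1.0)
        theta_p = theta.copy()
        theta_p[i, c] += h
        try:
            xhat_p = simulate_glv(
                GLVParameters(alpha=theta_p[:, 0], beta=theta_p[:, 1:]), x0, x.times
            ).values
        except SimulationDiverged:
            theta_p[i, c] = theta[i, c] - h
            xhat_p = simulate_glv(
                GLVParameters(alpha=theta_p[:, 0], beta=theta_p[:, 1:]), x0, x.times
            ).values
            h = -h
        J[:, col] = (xhat_p - xhat).ravel() / h

    jtj = J.T @ J
    rank = np.linalg.matrix_rank(jtj)
    cov = np.linalg.pinv(jtj)
    variances = np.clip(np.diag(cov), 0.0, None)
    ses = s * np.sqrt(variances)
    if rank < n_free:
        # parameters the trajectories are blind to get no information
        null_mask = np.linalg.norm(J, axis=0) < 1e-12 * max(1.0, np.linalg.norm(J))
        ses[null_mask] = np.inf
    scores_free = _t_scores(theta.ravel()[flat_idx], ses, df)

    score_full = np.zeros(n * (n + 1))
    score_full[flat_idx] = scores_free
    se_full = np.full(n * (n + 1), np.nan)
    se_full[flat_idx] = ses
    score_grid = score_full.reshape(n, n + 1)
    se_grid = se_full.reshape(n, n + 1)
    return ConfidenceReport(
        alpha_estimate=params.alpha.copy(), beta_estimate=params.beta.copy(),
        alpha_score=score_grid[:, 0].copy(), beta_score=score_grid[:, 1:].copy(),
        df=df, alpha_se=se_grid[:, 0].copy(), beta_se=se_grid[:, 1:].copy(),
        species_ids=params.species_ids or x.species_ids,
    )


def ensemble_confidence(
    e: Ensemble,
    x: AbundanceSeries,
    constraints: SignConstraintSet | None = None,
) -> ConfidenceReport:
    """Elementwise mean of per-member confidence scores (conservative)."""
    if len(e) == 0:
        raise ValueError("empty ensemble")
    reports = [
        parameter_confidence(m.params, x, constraints=constraints) for m in e.members
    ]
    return ConfidenceReport(
        alpha_estimate=np.mean([r.alpha_estimate for r in reports], axis=0),
        beta_estimate=np.mean([r.beta_estimate for r in reports], axis=0),
        alpha_score=np.mean([r.alpha_score for r in reports], axis=0),
        beta_score=np.mean([r.beta_score for r in reports], axis=0),
        df=reports[0].df,
        species_ids=reports[0].species_ids,
    )


def parameter_cv(e: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient of variation (sample sd / |mean|) across ensemble members.

    Parameters with zero ensemble mean are reported as NaN (undefined), not
    infinity.  Returns (alpha_cv, beta_cv).
    """
    if len(e) < 2:
        raise ValueError("CV needs at least two ensemble members")
    alphas, betas = e.parameter_stack()

    def cv(stack):
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        out = np.full_like(mean, np.nan)
        nz = mean != 0.0
        out[nz] = sd[nz] / np.abs(mean[nz])
        return out

    return cv(alphas), cv(betas)


def fit_susceptibility(
    member: EnsembleMember | GLVParameters,
    x: AbundanceSeries,
    exo: ExogenousSeries,
    constraints: SignConstraintSet | None = None,
    fd_step: float = _FD_STEP,
) -> SusceptibilityFit:
    """Fit each species' susceptibility to the exogenous series, one at a time.

    The endogenous coefficients stay frozen at the member's values; for each
    species i a single bound-constrained coefficient eps_i is fit (all other
    eps_j pinned at zero) and scored with df counting one free parameter.  An
    identically-zero exogenous series leaves every eps unidentifiable:
    zeros with score 0.
    """
    params = member.params if isinstance(member, EnsembleMember) else member
    n = params.n_species
    x0 = _initial_state(x.values)
    epsilon = np.zeros(n)
    scores = np.zeros(n)
    fitted = np.zeros(n, dtype=bool)
    if np.all(exo.values == 0.0):
        return SusceptibilityFit(
            epsilon=epsilon, score=scores, fitted=fitted,
            species_ids=params.species_ids or x.species_ids,
        )
    df = x.values.size - 1
    for i in range(n):
        lo, hi = (constraints.epsilon_bounds(i) if constraints is not None
                  else (-np.inf, np.inf))
        if lo == 0.0 and hi == 0.0:
            continue

        def residual(eps_i, i=i):
            eps = np.zeros(n)
            eps[i] = eps_i[0]
            try:
                xhat = simulate_glv_exogenous(
                    params.with_epsilon(eps), x0, x.times, exo
                ).values
            except SimulationDiverged:
                return np.full(x.values.size, 1e6)
            return (xhat - x.values).ravel()

        sol = least_squares(
            residual, np.array([0.0]), bounds=([lo], [hi]), method="trf",
            ftol=1e-10, xtol=1e-12,
        )
        eps_hat = float(sol.x[0])
        epsilon[i] = eps_hat
        fitted[i] = True
        r = residual(np.array([eps_hat]))
        s = float(np.linalg.norm(r)) / np.sqrt(df)
        h = fd_step * max(abs(eps_hat), 1.0)
        jcol = (residual(np.array([eps_hat + h])) - r) / h
        jtj = float(jcol @ jcol)
        if jtj <= 0:
            scores[i] = 0.0
            continue
        se = s / np.sqrt(jtj)
        scores[i] = _t_scores(np.array([eps_hat]), np.array([se]), df)[0]
    return SusceptibilityFit(
        epsilon=epsilon, score=scores, fitted=fitted,
        species_ids=params.species_ids or x.species_ids,
    )
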
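"""Perturbation ensembles: alternative parameterizations that fit almost equally well.

A single best-fit model understates the uncertainty left by noisy, sparse
data.  The ensemble procedure perturbs the best-fit coefficients with
log-normal multiplicative noise on their magnitudes (signs and constrained
zeros preserved), re-optimizes each perturbed candidate against the data by
bound-constrained trust-region nonlinear least squares, and keeps the
candidates whose symmetric mean absolute percentage error (sMAPE) stays below
a cutoff.  Ensemble means and standard deviations then support forecasting
and parameter-level uncertainty summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationDiverged, simulate_glv
from .metrics import smape
from .params import GLVParameters, SignConstraintSet
from .regression import FitResult, GLVNonlinearRegression, PenaltyConfig
from .series import AbundanceSeries

__all__ = [
    "EnsembleMember", "Ensemble", "ForecastResult",
    "perturb_parameters", "reoptimize", "build_ensemble", "forecast", "smape",
]


@dataclass(frozen=True)
class EnsembleMember:
    params: GLVParameters
    smape: float
    adjusted_r2: float
    provenance: int  # perturbation seed
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.smape <= 1.0):
            raise ValueError("sMAPE must lie in [0, 1]")


@dataclass(frozen=True)
class Ensemble:
    """Members retained below the sMAPE cutoff, plus the full error sample."""

    members: tuple[EnsembleMember, ...]
    cutoff: float
    all_smape: np.ndarray  # every candidate's error, for histogram inspection
    n_rejected: int

    def __post_init__(self) -> None:
        for m in self.members:
            if m.smape > self.cutoff:
                raise ValueError("ensemble member exceeds the sMAPE cutoff")
        object.__setattr__(self, "all_smape", np.asarray(self.all_smape, dtype=float))

    def __len__(self) -> int:
        return len(self.members)

    def parameter_stack(self) -> tuple[np.ndarray, np.ndarray]:
        """(alphas K x N, betas K x N x N) across members."""
        alphas = np.stack([m.params.alpha for m in self.members])
        betas = np.stack([m.params.beta for m in self.members])
        return alphas, betas


@dataclass(frozen=True)
class ForecastResult:
    times: np.ndarray
    mean: np.ndarray  # species x time
    sd: np.ndarray
    n_failed: int
    species_ids: tuple[str, ...] | None = None


def perturb_parameters(
    params: GLVParameters, sigma: float, seed: int | np.random.Generator = 0
) -> GLVParameters:
    """Multiply each nonzero coefficient's magnitude by a log-normal factor.

    The factor has log-mean 0 and log-sd ``sigma``; signs are reattached, so
    the perturbation never violates sign constraints, and exact zeros
    (constrained-out interactions) stay zero.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def jitter(arr):
        out = arr.copy()
        nz = arr != 0.0
        out[nz] = np.sign(arr[nz]) * np.abs(arr[nz]) * np.exp(
            sigma * rng.standard_normal(int(nz.sum()))
        )
        return out

    return GLVParameters(
        alpha=jitter(params.alpha),
        beta=jitter(params.beta),
        epsilon=jitter(params.epsilon) if params.epsilon is not None else None,
        species_ids=params.species_ids,
    )


def reoptimize(
    init: GLVParameters,
    x: AbundanceSeries,
    constraints: SignConstraintSet | None = None,
    penalty: PenaltyConfig = PenaltyConfig(),
    provenance: int = 0,
    **nlr_kwargs,
) -> EnsembleMember:
    """Re-fit a perturbed candidate by nonlinear least squares from ``init``.

    Non-convergence is flagged on the member rather than raised; such members
    either fail the cutoff naturally or surface in the report.
    """
    est = GLVNonlinearRegression(
        constraints=constraints, lambda_alpha=penalty.lambda_alpha,
        lambda_beta=penalty.lambda_beta, **nlr_kwargs,
    ).fit(x, init=init)
    return EnsembleMember(
        params=est.params_,
        smape=est.smape_,
        adjusted_r2=est.adjusted_r2_,
        provenance=provenance,
        converged=est.converged_,
    )


def build_ensemble(
    x: AbundanceSeries,
    best: FitResult | GLVParameters,
    n: int = 1000,
    sigma: float = 0.2,
    cutoff: float = 0.25,
    constraints: SignConstraintSet | None = None,
    penalty: PenaltyConfig = PenaltyConfig(),
    seed: int = 0,
    **nlr_kwargs,
) -> Ensemble:
    """Perturb-and-reoptimize ``n`` candidates and keep those under ``cutoff``.

    The full sMAPE sample is preserved for histogram inspection (the cutoff is
    a config choice made by looking at that histogram, not an automated one).
    Deterministic for fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    base = best.params if isinstance(best, FitResult) else best
    members = []
    errors = np.empty(n)
    for k in range(n):
        rng = np.random.default_rng([int(seed), k])
        candidate = perturb_parameters(base, sigma, rng)
        member = reoptimize(
            candidate, x, constraints=constraints, penalty=penalty,
            provenance=k, **nlr_kwargs,
        )
        errors[k] = member.smape
        if member.smape <= cutoff:
            members.append(member)
    if not members:
        raise RuntimeError(
            f"empty ensemble: no candidate reached sMAPE <= {cutoff}; "
            "consider a larger cutoff or a smaller sigma"
        )
    return Ensemble(
        members=tuple(members), cutoff=cutoff, all_smape=errors,
        n_rejected=n - len(members),
    )


def forecast(e: Ensemble, x0: np.ndarray, times_future: np.ndarray) -> ForecastResult:
    """Pointwise ensemble mean and sd of member simulations from ``x0``.

    Members whose simulation blows up over the horizon are excluded and
    counted; an error is raised only if every member fails.
    """
    if len(e) == 0:
        raise ValueError("forecast needs a non-empty ensemble")
    times_future = np.asarray(times_future, dtype=float)
    n_species = e.members[0].params.n_species
    if times_future.size == 0:
        return ForecastResult(
            times=times_future, mean=np.empty((n_species, 0)),
            sd=np.empty((n_species, 0)), n_failed=0,
            species_ids=e.members[0].params.species_ids,
        )
    trajectories = []
    failed = 0
    for m in e.members:
        try:
            trajectories.append(simulate_glv(m.params, x0, times_future).values)
        except SimulationDiverged:
            failed += 1
    if not trajectories:
        raise RuntimeError("every ensemble member diverged over the forecast horizon")
    stack = np.stack(trajectories)
    return ForecastResult(
        times=times_future,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0) if stack.shape[0] > 1 else np.zeros_like(stack[0]),
        n_failed=failed,
        species_ids=e.members[0].params.species_ids,
    )
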
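"""Synthetic benchmark communities and stochastic observation generation.

Two generators cover the testing needs of the inference stack: a fixed
3-species benchmark with a mixed predation / competition / self-limitation
topology and damped oscillatory dynamics, and a randomized N-species community
builder whose sign structure is derived from a generated trophic prior so the
entire food-web -> constraints -> inference chain can run end to end.

Environmental noise follows the Ito stochastic differential equation

    dX_i = (alpha_i + sum_j beta_ij X_j) X_i dt + sigma_i dW_i,

integrated by Euler-Maruyama on a fine internal grid, with states clipped at
zero, and subsampled to the observation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import simulate_glv
from .foodweb import TrophicPrior, build_summary_web, classify_trophic_levels, derive_sign_constraints
from .params import GLVParameters, SignConstraintSet
from .series import AbundanceSeries

#: benchmark coefficients; fixture constants of this repository.  Species 3 is
#: a predator of species 1 and 2 (negative column 3 on the prey rows, positive
#: row 3 on the prey columns), species 1 and 2 compete, every species
#: self-limits; growth is positive for the prey and negative for the predator.
BENCHMARK_ALPHA = np.array([0.66, 0.45, -0.54])
BENCHMARK_BETA = np.array([
    [-0.31, -0.10, -2.26],
    [-0.21, -0.90, -1.14],
    [1.84, 1.14, -0.08],
])
BENCHMARK_X0 = np.array([0.15, 0.6, 0.4])
BENCHMARK_INTERVAL = 5.0
BENCHMARK_HORIZON = 100.0
BENCHMARK_SIGMA = 1e-3


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus observation design for a synthetic community."""

    truth: GLVParameters
    x0: np.ndarray
    sample_interval: float
    horizon: float
    diffusion: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0, dtype=float)
        diffusion = np.broadcast_to(
            np.asarray(self.diffusion, dtype=float), (self.truth.n_species,)
        ).copy()
        if x0.shape != (self.truth.n_species,):
            raise ValueError("x0 length must match the number of species")
        if np.any(x0 < 0) or np.any(diffusion < 0):
            raise ValueError("x0 and diffusion must be non-negative")
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "diffusion", diffusion)

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.horizon / self.sample_interval))
        return np.linspace(0.0, n * self.sample_interval, n + 1)

    def simulate_deterministic(self) -> AbundanceSeries:
        return simulate_glv(self.truth, self.x0, self.times)


def make_benchmark_spec(seed: int = 0) -> tuple[SyntheticSpec, SignConstraintSet]:
    """The 3-species benchmark: x0=(0.15, 0.6, 0.4), samples every 5 time
    units on [0, 100] (21 observations), diffusion 0.001 per species."""
    truth = GLVParameters(alpha=BENCHMARK_ALPHA.copy(), beta=BENCHMARK_BETA.copy())
    spec = SyntheticSpec(
        truth=truth,
        x0=BENCHMARK_X0.copy(),
        sample_interval=BENCHMARK_INTERVAL,
        horizon=BENCHMARK_HORIZON,
        diffusion=np.full(3, BENCHMARK_SIGMA),
        seed=seed,
    )
    constraints = SignConstraintSet.from_signs(truth.alpha, truth.beta)
    return spec, constraints


def simulate_sde(spec: SyntheticSpec, seed: int | None = None, dt: float = 0.002) -> AbundanceSeries:
    """Euler-Maruyama integration of the noisy community model.

    Internal step ``dt`` (default 0.002), states clipped at zero after every
    step, output subsampled at the spec's observation times.  Raises if the
    trajectory blows up, naming the seed.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    times = spec.times
    alpha, beta, sigma = spec.truth.alpha, spec.truth.beta, spec.diffusion
    # align the internal grid with the observation grid
    per_obs = max(1, int(np.ceil(spec.sample_interval / dt)))
    h = spec.sample_interval / per_obs
    sqrt_h = np.sqrt(h)
    x = spec.x0.copy()
    out = np.empty((spec.truth.n_species, times.size))
    out[:, 0] = x
    ceiling = 1e6 * max(float(spec.x0.max()), 1.0)
    for k in range(1, times.size):
        noise = rng.standard_normal((per_obs, x.size))
        for s in range(per_obs):
            drift = (alpha + beta @ x) * x
            x = x + drift * h + sigma * sqrt_h * noise[s]
            np.clip(x, 0.0, None, out=x)
            if np.max(x) > ceiling:
                raise RuntimeError(
                    f"stochastic simulation blew up (seed={seed}, t~{times[k]})"
                )
        out[:, k] = x
    return AbundanceSeries(
        species_ids=spec.truth.species_ids or tuple(f"sp{i+1}" for i in range(x.size)),
        times=times, values=out,
    )


def make_community_spec(
    n_species: int,
    tiers: tuple[int, int, int] | None = None,
    seed: int = 0,
    sample_interval: float = 1.0,
    horizon: float = 30.0,
    diffusion: float = BENCHMARK_SIGMA,
    max_draws: int = 200,
) -> tuple[SyntheticSpec, TrophicPrior]:
    """Sample a stable, sign-feasible community with a matching trophic prior.

    Tier sizes default to a bottom-heavy split.  Interaction magnitudes are
    half-normal above a small floor (interactions too weak to shape dynamics
    are not ecologically meaningful links), with a dominant self-limitation
    diagonal.  Candidate parameterizations are rejected until the
    deterministic trajectories stay bounded (below 10x the larger of the
    fixed-point scale and the initial state), keep every species extant, and
    fluctuate non-monotonically for at least half the species -- the data
    regime the inference is meant for.  The default sampling design (interval
    1 over a horizon of 30) resolves the transient these communities exhibit.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    if tiers is None:
        n_top = 1 if n_species >= 3 else 0
        n_meso = 1 if n_species >= 4 else 0
        tiers = (n_species - n_meso - n_top, n_meso, n_top)
    if sum(tiers) != n_species:
        raise ValueError("tier sizes must sum to n_species")
    names = [f"sp{i+1}" for i in range(n_species)]
    tier_of = {}
    k = 0
    for tier_idx, count in enumerate(tiers):
        for _ in range(count):
            tier_of[names[k]] = tier_idx
            k += 1
    index = {
        s: 2.0 + tier_of[s] + 0.1 * rng.uniform(0, 1) for s in names
    }
    prior = TrophicPrior(trophic_index=index, known_predation=())
    assignment = classify_trophic_levels(prior)
    web = build_summary_web(assignment, prior)
    constraints = derive_sign_constraints(web)
    order = list(constraints.species_ids)
    n = len(order)
    for _ in range(max_draws):
        alpha = np.empty(n)
        beta = np.zeros((n, n))
        for i, sp in enumerate(order):
            low_tier = constraints.alpha_sign[i] == "positive"
            alpha[i] = rng.uniform(0.3, 1.0) if low_tier else -rng.uniform(0.1, 0.5)
            beta[i, i] = -rng.uniform(0.5, 1.0)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                sign = constraints.beta_sign[i, j]
                if sign == "negative":
                    is_predation = constraints.beta_sign[j, i] == "positive"
                    if is_predation:
                        beta[i, j] = -(0.25 + abs(rng.normal(0.0, 0.6)))
                    else:
                        beta[i, j] = -(0.15 + abs(rng.normal(0.0, 0.2)))
                elif sign == "positive":
                    beta[i, j] = 0.25 + abs(rng.normal(0.0, 0.6))
        truth = GLVParameters(alpha=alpha, beta=beta, species_ids=tuple(order))
        x0 = rng.uniform(0.2, 0.8, size=n)
        spec = SyntheticSpec(
            truth=truth, x0=x0, sample_interval=sample_interval,
            horizon=horizon, diffusion=np.full(n, diffusion), seed=seed,
        )
        try:
            traj = spec.simulate_deterministic()
        except Exception:
            continue
        try:
            scale = np.max(np.abs(truth.interior_fixed_point()))
        except np.linalg.LinAlgError:
            scale = 0.0
        bound = 10.0 * max(scale, float(x0.max()))
        if np.max(traj.values) >= bound:
            continue
        if np.min(traj.values.max(axis=1)) <= 1e-3:
            continue
        turning = [
            int(np.sum(np.diff(np.sign(np.diff(row))) != 0)) for row in traj.values
        ]
        if sum(t >= 1 for t in turning) < (n + 1) // 2:
            continue
        return spec, prior
    raise RuntimeError(f"no stable parameterization found in {max_draws} draws")
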
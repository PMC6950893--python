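"""Numerical solution of the generalized Lotka-Volterra equations.

The community model is

    dx_i/dt = (alpha_i + sum_j beta_ij x_j) x_i,

optionally extended with an exogenous perturbing species whose abundance
enters the growth term as ``epsilon_i * x_exo(t)``.  Trajectories are computed
with a stiff variable-order solver (LSODA) at rtol 1e-7 / atol 1e-9.  A state
exceeding a divergence ceiling aborts the integration and is reported as a
recoverable failure carrying the time of failure, which the latent-gradient
optimizer uses to reject unstable trial parameterizations.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import GLVParameters
from .series import AbundanceSeries, ExogenousSeries

RTOL = 1e-7
ATOL = 1e-9
#: trajectories are flagged divergent past this multiple of the reference scale
DIVERGENCE_FACTOR = 1e6


class SimulationDiverged(RuntimeError):
    """Integration blew up (unstable parameterization).

    Recoverable: carries the time at which the divergence ceiling was hit.
    """

    def __init__(self, time_of_failure: float):
        super().__init__(f"gLV simulation diverged at t={time_of_failure:.6g}")
        self.time_of_failure = float(time_of_failure)


def _glv_rhs(params: GLVParameters, exo_eval=None):
    alpha, beta = params.alpha, params.beta
    eps = params.epsilon

    if exo_eval is None or eps is None:
        def rhs(t, x):
            return (alpha + beta @ x) * x
    else:
        def rhs(t, x):
            return (alpha + eps * float(exo_eval(t)) + beta @ x) * x
    return rhs


def _simulate(
    params: GLVParameters,
    x0: np.ndarray,
    times: np.ndarray,
    exo_eval=None,
    species_ids=None,
) -> AbundanceSeries:
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if x0.shape != (params.n_species,):
        raise ValueError(f"x0 must have length {params.n_species}, got {x0.shape}")
    if np.any(x0 < 0):
        raise ValueError("x0 must be non-negative")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times.size == 0:
        return AbundanceSeries(
            species_ids=species_ids or params.species_ids or _default_ids(params.n_species),
            times=times, values=np.empty((params.n_species, 0)),
        )

    ceiling = DIVERGENCE_FACTOR * max(float(np.max(x0)), 1.0)

    def blown_up(t, x):
        return ceiling - float(np.max(np.abs(x)))

    blown_up.terminal = True
    blown_up.direction = -1

    t0 = float(times[0])
    rhs = _glv_rhs(params, exo_eval)
    sol = solve_ivp(
        rhs,
        (t0, float(times[-1])),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
        events=blown_up,
    )
    if sol.status == 1:  # terminated by the divergence event
        raise SimulationDiverged(float(sol.t_events[0][0]))
    if not sol.success:
        # step-size underflow and friends also signal instability
        raise SimulationDiverged(float(sol.t[-1]) if sol.t.size else t0)
    values = np.clip(sol.y, 0.0, None)  # clamp solver noise below zero
    values[x0 == 0.0, :] = 0.0  # absorbing state: extinct species stay extinct
    return AbundanceSeries(
        species_ids=species_ids or params.species_ids or _default_ids(params.n_species),
        times=times,
        values=values,
    )


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"sp{i+1}" for i in range(n))


def simulate_glv(
    params: GLVParameters,
    x0: np.ndarray,
    times: np.ndarray,
    species_ids=None,
) -> AbundanceSeries:
    """Solve the autonomous gLV system from ``x0`` sampled at ``times``.

    Any ``epsilon`` on ``params`` is ignored.  Raises
    :class:`SimulationDiverged` when the trajectory blows up.
    """
    return _simulate(params.with_epsilon(None), x0, times, species_ids=species_ids)


def simulate_glv_exogenous(
    params: GLVParameters,
    x0: np.ndarray,
    times: np.ndarray,
    exo: ExogenousSeries,
    species_ids=None,
) -> AbundanceSeries:
    """Solve the gLV system perturbed by an exogenous species.

    The exogenous abundance multiplies ``params.epsilon`` inside the growth
    term and is evaluated by the series' declared interpolation (monotone
    piecewise cubic inside the observed window, constant outside).
    """
    if params.epsilon is None:
        raise ValueError("params.epsilon is required for an exogenous simulation")
    return _simulate(params, x0, times, exo_eval=exo.interpolator(), species_ids=species_ids)
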
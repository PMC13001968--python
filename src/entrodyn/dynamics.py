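"""The autonomous three-state coupled-trait ODE system.

States
------
``N``        primary trait-like state, initialized from the first-wave
             pooled entropy index;
``P``        secondary coupled state;
``E_stress`` latent environmental-stress state.

Dynamics (time in years, all states dimensionless)::

    dN/dt = mu*N - s(N) * N,          s(N) = alpha*N + beta**2 * P
    dP/dt = mu*P - beta*P * E_met/G,  E_met = c1*P + c2*N + c3*E_stress
    dE/dt = gamma * E_stress * N / (N + K)

``mu`` is a baseline persistence rate shared by N and P; ``alpha`` is
self-limitation; ``beta`` couples the two traits (squared in the N
equation so the damping is nonnegative for either sign); ``c1..c3``
weight the aggregate cost term; ``G > 0`` sets the capacity scale;
``gamma`` amplifies stress through the saturating kernel ``N/(N+K)``
with ``K > 0``.  An optional sinusoidal term ``A*sin(omega*(t-t0))`` can
be added to ``E_stress`` *inside the cost term only* (scaled by ``c3``),
leaving the stress ODE itself unforced.

The uncoupled null model (``coupled=False``) removes every N<->P
pathway by forcing ``beta = c2 = c3 = 0``: N reduces to logistic decay
``dN/dt = mu*N - alpha*N**2`` and P to pure exponential persistence,
while E_stress still evolves but influences nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError, SimulationError

__all__ = [
    "CoupledTraitParams",
    "InitialCondition",
    "Trajectory",
    "selection_pressure",
    "metabolic_cost",
    "rhs",
    "simulate",
    "SET3_PARAMS",
]

#: states with any component beyond this magnitude abort the integration
BLOWUP_GUARD = 1e12


@dataclass(frozen=True)
class CoupledTraitParams:
    """Model coefficients.  See the module docstring for the equations."""

    mu: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    K: float = 0.5
    G: float = 1.0
    forcing_amplitude: float = 1.0
    forcing_omega: float = 1.0
    forcing_enabled: bool = False
    coupled: bool = True

    def __post_init__(self):
        if self.K <= 0:
            raise InvalidInputError(f"K must be > 0, got {self.K}")
        if self.G <= 0:
            raise InvalidInputError(f"G must be > 0, got {self.G}")
        for name in ("mu", "alpha", "beta", "gamma", "c1", "c2", "c3", "K", "G",
                     "forcing_amplitude", "forcing_omega"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"parameter {name} is not finite")

    def effective(self) -> "CoupledTraitParams":
        """Coefficients actually used: the uncoupled variant zeroes every
        N<->P pathway (beta, c2, c3)."""
        if self.coupled:
            return self
        return replace(self, beta=0.0, c2=0.0, c3=0.0)


#: the illustrative "third parameter set": a gently damped, weakly coupled
#: regime with the stress pathway switched off (c3 = 0); G is the default 1
SET3_PARAMS = CoupledTraitParams(
    mu=0.00001, alpha=0.098, beta=0.17117, gamma=0.03,
    c1=2.0, c2=0.21, c3=0.0, K=0.5, G=1.0,
)


@dataclass(frozen=True)
class InitialCondition:
    """Starting state at time ``t0`` (years)."""

    t0: float = 0.0
    N0: float = 0.0
    P0: float = 0.0
    E0: float = 0.0

    def __post_init__(self):
        for name in ("t0", "N0", "P0", "E0"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"initial condition {name} is not finite")
        if min(self.N0, self.P0, self.E0) < 0:
            raise InvalidInputError("initial states must be nonnegative")

    @property
    def state(self) -> np.ndarray:
        return np.array([self.N0, self.P0, self.E0], float)


@dataclass(frozen=True)
class Trajectory:
    """Integrated states evaluated at requested times."""

    times: np.ndarray
    N: np.ndarray
    P: np.ndarray
    E_stress: np.ndarray
    params_used: CoupledTraitParams
    init_used: InitialCondition

    def __len__(self) -> int:
        return len(self.times)

    @property
    def states(self) -> np.ndarray:
        """(n_times, 3) array of (N, P, E_stress) rows."""
        return np.column_stack([self.N, self.P, self.E_stress])

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "N": self.N, "P": self.P, "E_stress": self.E_stress}
        )


def selection_pressure(N: float, P: float, params: CoupledTraitParams) -> float:
    """Constraint term s(N) = alpha*N + beta**2 * P damping the growth of N."""
    p = params.effective()
    return p.alpha * N + p.beta ** 2 * P


def metabolic_cost(
    N: float, P: float, E_stress: float, params: CoupledTraitParams, t: float = 0.0,
    t0: float = 0.0,
) -> float:
    """Aggregate cost c1*P + c2*N + c3*E_stress damping the growth of P.

    With forcing enabled, ``A*sin(omega*(t - t0))`` is added to E_stress
    inside this term only.
    """
    p = params.effective()
    e = E_stress
    if p.forcing_enabled:
        e = e + p.forcing_amplitude * math.sin(p.forcing_omega * (t - t0))
    return p.c1 * P + p.c2 * N + p.c3 * e


def rhs(t: float, state, params: CoupledTraitParams, t0: float = 0.0) -> np.ndarray:
    """Time derivative (dN/dt, dP/dt, dE/dt) at absolute time ``t``."""
    N, P, E = float(state[0]), float(state[1]), float(state[2])
    if not (math.isfinite(N) and math.isfinite(P) and math.isfinite(E)):
        raise SimulationError(
            f"non-finite state at t={t}", t=t, state=np.asarray(state, float)
        )
    p = params.effective()
    dN = p.mu * N - (p.alpha * N + p.beta ** 2 * P) * N
    dP = p.mu * P - p.beta * P * metabolic_cost(N, P, E, params, t, t0) / p.G
    dE = p.gamma * E * N / (N + p.K)
    return np.array([dN, dP, dE])


def simulate(
    params: CoupledTraitParams,
    init: InitialCondition,
    eval_times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the system and evaluate it at ``eval_times``.

    Uses adaptive explicit Runge-Kutta (scipy ``solve_ivp``) from ``t0``
    to the last requested time.  ``eval_times`` must be strictly
    increasing with ``eval_times[0] >= t0``.  A state exceeding
    :data:`BLOWUP_GUARD` in magnitude raises :class:`SimulationError`
    with diagnostics instead of propagating NaNs.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, float))
    if eval_times.size == 0:
        raise InvalidInputError("eval_times is empty")
    if np.any(np.diff(eval_times) <= 0):
        raise InvalidInputError("eval_times must be strictly increasing")
    if eval_times[0] < init.t0 - 1e-12:
        raise InvalidInputError(
            f"eval_times[0]={eval_times[0]} precedes t0={init.t0}"
        )

    p = params.effective()
    mu, alpha, beta, gamma = p.mu, p.alpha, p.beta, p.gamma
    c1, c2, c3, K, G = p.c1, p.c2, p.c3, p.K, p.G
    beta_sq = beta * beta
    t0 = init.t0
    forcing = p.forcing_enabled
    A, omega = p.forcing_amplitude, p.forcing_omega

    def f(t, y):
        N, P, E = y
        e_cost = E
        if forcing:
            e_cost = E + A * math.sin(omega * (t - t0))
        dN = mu * N - (alpha * N + beta_sq * P) * N
        dP = mu * P - beta * P * (c1 * P + c2 * N + c3 * e_cost) / G
        dE = gamma * E * N / (N + K)
        return (dN, dP, dE)

    def blown_up(t, y):
        return BLOWUP_GUARD - max(abs(y[0]), abs(y[1]), abs(y[2]))

    blown_up.terminal = True

    if eval_times.size == 1 and abs(eval_times[0] - t0) <= 1e-12:
        states = init.state[None, :]
        return Trajectory(eval_times.copy(), states[:, 0], states[:, 1],
                          states[:, 2], params, init)

    sol = solve_ivp(
        f,
        (t0, float(eval_times[-1])),
        init.state,
        method=method,
        t_eval=eval_times,
        rtol=rtol,
        atol=atol,
        events=blown_up,
    )
    if sol.status == 1:  # blow-up event fired
        t_ev = float(sol.t_events[0][0])
        raise SimulationError(
            f"state magnitude exceeded {BLOWUP_GUARD:g} at t={t_ev:.6g}",
            t=t_ev,
            state=sol.y_events[0][0],
        )
    if not sol.success or sol.y.shape[1] != eval_times.size:
        raise SimulationError(f"integrator failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state in integrated trajectory")
    N, P, E = y[0].copy(), y[1].copy(), y[2].copy()
    if abs(eval_times[0] - t0) <= 1e-12:
        # pin the first sample exactly to the initial condition
        N[0], P[0], E[0] = init.N0, init.P0, init.E0
    return Trajectory(eval_times.copy(), N, P, E, params, init)
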
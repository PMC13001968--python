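"""Bounded multistart least-squares fitting of the coupled-trait model.

Two normalized entropy trajectories (one mapped to N, one to P) are fit
by minimizing the pooled sum of squared errors between the integrated
model and the observations at the wave times, using the bounded
limited-memory quasi-Newton optimizer (L-BFGS-B) with numerical
gradients.  A :class:`ParameterSpec` declares, per coefficient, whether
it is free, its fixed value otherwise, its box bounds and its start
value; multistart repeats the local fit from seeded uniform-in-bounds
random starts and reports the spread of attained objective values as a
cheap landscape/identifiability diagnostic.

Initialization follows the model's convention: N(t0) is pinned to the
first observed value of the N-mapped trait, and by default P(t0) to the
first observed value of the P-mapped trait; the stress baseline E0 is
free by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .dynamics import CoupledTraitParams, InitialCondition, simulate
from .errors import FitError, InvalidInputError, SimulationError

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "ParamEntry",
    "ParameterSpec",
    "ObservedTrajectories",
    "FitResult",
    "sse_objective",
    "fit_single",
    "fit_multistart",
]

#: canonical parameter order used for start/bound vectors
PARAM_NAMES = (
    "mu", "alpha", "beta", "gamma", "c1", "c2", "c3", "K", "G",
    "A", "omega", "N0", "P0", "E0",
)

#: default box bounds; wide enough to bracket every illustrative
#: parameter regime with ample margin
DEFAULT_BOUNDS = {
    "mu": (0.0, 1.0),
    "alpha": (0.0, 5.0),
    "beta": (-2.0, 2.0),
    "gamma": (0.0, 1.0),
    "c1": (0.0, 20.0),
    "c2": (0.0, 20.0),
    "c3": (0.0, 20.0),
    "K": (1e-3, 10.0),
    "G": (1e-3, 10.0),
    "A": (0.0, 5.0),
    "omega": (0.0, 2.0 * math.pi),
    "N0": (0.0, 1.0),
    "P0": (1e-4, 1.0),
    "E0": (1e-4, 1.0),
}

_DEFAULT_VALUES = {
    "mu": 0.05, "alpha": 0.1, "beta": 0.2, "gamma": 0.05,
    "c1": 1.0, "c2": 0.2, "c3": 0.1, "K": 0.5, "G": 1.0,
    "A": 1.0, "omega": 1.0, "N0": 0.5, "P0": 0.5, "E0": 0.01,
}

#: objective value returned when a trial point blows up the ODE
PENALTY_SSE = 1e6


@dataclass(frozen=True)
class ParamEntry:
    """One coefficient in a :class:`ParameterSpec`."""

    free: bool
    value: float
    lower: float
    upper: float
    start: Optional[float] = None

    def __post_init__(self):
        if self.lower > self.upper:
            raise InvalidInputError(f"lower {self.lower} > upper {self.upper}")
        if self.free:
            s = self.value if self.start is None else self.start
            if not (self.lower <= s <= self.upper):
                raise InvalidInputError(
                    f"start {s} outside bounds [{self.lower}, {self.upper}]"
                )

    @property
    def start_value(self) -> float:
        return self.value if self.start is None else self.start


@dataclass(frozen=True)
class ObservedTrajectories:
    """Observed (normalized-entropy) trajectories for the two traits."""

    wave_times: np.ndarray
    n_observed: np.ndarray
    p_observed: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.wave_times, float)
        n = np.asarray(self.n_observed, float)
        object.__setattr__(self, "wave_times", t)
        object.__setattr__(self, "n_observed", n)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("wave_times must be strictly increasing")
        if n.shape != t.shape:
            raise InvalidInputError("n_observed length mismatch with wave_times")
        if self.p_observed is not None:
            p = np.asarray(self.p_observed, float)
            if p.shape != t.shape:
                raise InvalidInputError("p_observed length mismatch with wave_times")
            object.__setattr__(self, "p_observed", p)

    @property
    def n_waves(self) -> int:
        return len(self.wave_times)

    def drop_wave(self, index: int) -> "ObservedTrajectories":
        """Remove one wave (for leave-one-wave-out refits)."""
        keep = np.ones(self.n_waves, bool)
        keep[index] = False
        return ObservedTrajectories(
            self.wave_times[keep],
            self.n_observed[keep],
            None if self.p_observed is None else self.p_observed[keep],
        )


class ParameterSpec:
    """Declarative description of which coefficients are estimated.

    Parameters
    ----------
    entries : dict[str, ParamEntry]
        One entry per name in :data:`PARAM_NAMES`; missing names get a
        fixed default.
    forcing_enabled, coupled : bool
        Structural flags forwarded to :class:`CoupledTraitParams`.
    """

    def __init__(self, entries=None, *, forcing_enabled=False, coupled=True):
        entries = dict(entries or {})
        full = {}
        for name in PARAM_NAMES:
            if name in entries:
                full[name] = entries.pop(name)
            else:
                lo, hi = DEFAULT_BOUNDS[name]
                full[name] = ParamEntry(False, _DEFAULT_VALUES[name], lo, hi)
        if entries:
            raise InvalidInputError(f"unknown parameter names: {sorted(entries)}")
        self.entries = full
        self.forcing_enabled = bool(forcing_enabled)
        self.coupled = bool(coupled)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _entry(name, free, value, start=None, bounds=None):
        lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS[name]
        return ParamEntry(free, value, lo, hi, start)

    @classmethod
    def full(cls, obs: ObservedTrajectories, *, forcing=False,
             p0_policy="data", n0_policy="data") -> "ParameterSpec":
        """All model coefficients free; N0/P0 pinned to first-wave data.

        With ``forcing=True`` the sinusoid amplitude and frequency are
        freed as well.
        """
        e = {}
        for name in ("mu", "alpha", "beta", "gamma", "c1", "c2", "c3", "K", "G"):
            e[name] = cls._entry(name, True, _DEFAULT_VALUES[name])
        e["A"] = cls._entry("A", forcing, _DEFAULT_VALUES["A"])
        e["omega"] = cls._entry("omega", forcing, _DEFAULT_VALUES["omega"])
        e["E0"] = cls._entry("E0", True, _DEFAULT_VALUES["E0"])
        e["N0"] = cls._init_entry("N0", n0_policy, obs.n_observed[0])
        p0_data = obs.p_observed[0] if obs.p_observed is not None else 0.5
        e["P0"] = cls._init_entry("P0", p0_policy, p0_data)
        return cls(e, forcing_enabled=forcing)

    @classmethod
    def reduced(cls, obs: ObservedTrajectories, *,
                p0_policy="data", n0_policy="data") -> "ParameterSpec":
        """Reduced parameterization: free (mu, alpha, gamma, E0, beta, c1);
        the remaining coefficients held at the illustrative-regime values
        c2=0.21, c3=0, K=0.5 and the default capacity scale G=1."""
        e = {}
        for name in ("mu", "alpha", "beta", "gamma", "c1"):
            e[name] = cls._entry(name, True, _DEFAULT_VALUES[name])
        e["E0"] = cls._entry("E0", True, _DEFAULT_VALUES["E0"])
        e["c2"] = cls._entry("c2", False, 0.21)
        e["c3"] = cls._entry("c3", False, 0.0)
        e["K"] = cls._entry("K", False, 0.5)
        e["G"] = cls._entry("G", False, 1.0)
        e["N0"] = cls._init_entry("N0", n0_policy, obs.n_observed[0])
        p0_data = obs.p_observed[0] if obs.p_observed is not None else 0.5
        e["P0"] = cls._init_entry("P0", p0_policy, p0_data)
        return cls(e)

    @classmethod
    def _init_entry(cls, name, policy, data_value):
        if policy == "data":
            return cls._entry(name, False, float(data_value))
        if policy == "free":
            lo, hi = DEFAULT_BOUNDS[name]
            start = min(max(float(data_value), lo), hi)
            return ParamEntry(True, start, lo, hi, start)
        if isinstance(policy, (int, float)):
            return cls._entry(name, False, float(policy))
        raise InvalidInputError(
            f"{name} policy must be 'data', 'free' or a number, got {policy!r}"
        )

    # -- vector interface -----------------------------------------------------

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in PARAM_NAMES if self.entries[n].free)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def bounds(self) -> list:
        return [(self.entries[n].lower, self.entries[n].upper)
                for n in self.free_names]

    @property
    def start_vector(self) -> np.ndarray:
        return np.array([self.entries[n].start_value for n in self.free_names])

    def with_entry(self, name: str, entry: ParamEntry) -> "ParameterSpec":
        e = dict(self.entries)
        e[name] = entry
        out = ParameterSpec.__new__(ParameterSpec)
        out.entries = e
        out.forcing_enabled = self.forcing_enabled
        out.coupled = self.coupled
        return out

    def uncoupled(self) -> "ParameterSpec":
        """The null-model counterpart: same entries, but every N<->P
        pathway (beta, c2, c3) is structurally zero at evaluation time."""
        out = self.with_entry("beta", self.entries["beta"])
        out.coupled = False
        return out

    def to_model(self, x, t0: float):
        """Map a free-parameter vector to (params, initial condition)."""
        x = np.asarray(x, float)
        if x.shape != (self.n_free,):
            raise InvalidInputError(
                f"expected vector of length {self.n_free}, got shape {x.shape}"
            )
        vals = {n: self.entries[n].value for n in PARAM_NAMES}
        vals.update(dict(zip(self.free_names, x)))
        params = CoupledTraitParams(
            mu=vals["mu"], alpha=vals["alpha"], beta=vals["beta"],
            gamma=vals["gamma"], c1=vals["c1"], c2=vals["c2"], c3=vals["c3"],
            K=vals["K"], G=vals["G"],
            forcing_amplitude=vals["A"], forcing_omega=vals["omega"],
            forcing_enabled=self.forcing_enabled, coupled=self.coupled,
        )
        init = InitialCondition(t0=t0, N0=vals["N0"], P0=vals["P0"], E0=vals["E0"])
        return params, init

    def to_dict(self) -> dict:
        return {
            "forcing_enabled": self.forcing_enabled,
            "coupled": self.coupled,
            "parameters": {
                n: {
                    "free": e.free, "value": e.value,
                    "lower": e.lower, "upper": e.upper, "start": e.start_value,
                }
                for n, e in self.entries.items()
            },
        }


@dataclass
class FitResult:
    """Outcome of a (multistart) fit."""

    params: CoupledTraitParams
    init: InitialCondition
    free_names: tuple
    x: np.ndarray
    sse: float
    rmse_n: float
    r2_n: Optional[float]
    rmse_p: Optional[float]
    r2_p: Optional[float]
    converged: bool
    message: str
    nfev: int = 0
    n_starts: int = 1
    seed: Optional[int] = None
    sse_starts: Optional[np.ndarray] = None

    @property
    def start_stats(self) -> Optional[dict]:
        """Mean/sd/min/max of attained SSE across multistart runs."""
        if self.sse_starts is None:
            return None
        s = np.asarray(self.sse_starts, float)
        s = s[np.isfinite(s)]
        return {
            "mean": float(s.mean()), "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0,
            "min": float(s.min()), "max": float(s.max()),
        }

    def to_dict(self) -> dict:
        d = {
            "free_names": list(self.free_names),
            "x": [float(v) for v in self.x],
            "parameters": {
                n: getattr(self.params, n)
                for n in ("mu", "alpha", "beta", "gamma", "c1", "c2", "c3", "K", "G")
            },
            "forcing": {
                "enabled": self.params.forcing_enabled,
                "amplitude": self.params.forcing_amplitude,
                "omega": self.params.forcing_omega,
            },
            "coupled": self.params.coupled,
            "init": {"t0": self.init.t0, "N0": self.init.N0,
                     "P0": self.init.P0, "E0": self.init.E0},
            "sse": self.sse,
            "rmse_n": self.rmse_n, "r2_n": self.r2_n,
            "rmse_p": self.rmse_p, "r2_p": self.r2_p,
            "converged": self.converged, "message": self.message,
            "nfev": self.nfev, "n_starts": self.n_starts, "seed": self.seed,
        }
        d["sse_start_stats"] = self.start_stats
        return d


def _residuals(params, init, obs, rtol, atol, method):
    traj = simulate(params, init, obs.wave_times, rtol=rtol, atol=atol,
                    method=method)
    res_n = traj.N - obs.n_observed
    res_p = None
    if obs.p_observed is not None:
        res_p = traj.P - obs.p_observed
    return res_n, res_p


def sse_objective(
    params: CoupledTraitParams,
    init: InitialCondition,
    obs: ObservedTrajectories,
    penalty: float = PENALTY_SSE,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> float:
    """Pooled squared error of both traits at the wave times.

    A trial point whose simulation blows up returns the finite
    ``penalty`` so optimizers can continue.  The objective integrates
    with LSODA by default: random multistart trial points can land in
    arbitrarily stiff corners of the box (e.g. small G with large
    couplings) where an explicit method grinds; the stiffness-switching
    integrator matches the explicit solution within tolerance on benign
    points.
    """
    try:
        res_n, res_p = _residuals(params, init, obs, rtol, atol, method)
    except SimulationError:
        return penalty
    sse = float(np.dot(res_n, res_n))
    if res_p is not None:
        sse += float(np.dot(res_p, res_p))
    if not math.isfinite(sse):
        return penalty
    return sse


def _fit_metrics(params, init, obs, rtol, atol, method):
    """(sse, rmse_n, r2_n, rmse_p, r2_p) at a parameter point."""
    try:
        res_n, res_p = _residuals(params, init, obs, rtol, atol, method)
    except SimulationError:
        return PENALTY_SSE, math.nan, None, math.nan, None
    sse_n = float(np.dot(res_n, res_n))
    rmse_n = math.sqrt(sse_n / res_n.size)
    sstot_n = float(np.sum((obs.n_observed - obs.n_observed.mean()) ** 2))
    r2_n = 1.0 - sse_n / sstot_n if sstot_n > 0 else None
    if res_p is None:
        return sse_n, rmse_n, r2_n, None, None
    sse_p = float(np.dot(res_p, res_p))
    rmse_p = math.sqrt(sse_p / res_p.size)
    sstot_p = float(np.sum((obs.p_observed - obs.p_observed.mean()) ** 2))
    r2_p = 1.0 - sse_p / sstot_p if sstot_p > 0 else None
    return sse_n + sse_p, rmse_n, r2_n, rmse_p, r2_p


def fit_single(
    spec: ParameterSpec,
    obs: ObservedTrajectories,
    start=None,
    *,
    maxiter: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t0: Optional[float] = None,
) -> FitResult:
    """One bounded L-BFGS-B descent from ``start`` (default: spec starts).

    Deterministic given the start; fixed parameters are never touched.
    ``t0`` overrides the integration origin (default: the first observed
    wave), which matters when the first wave has been held out.
    """
    x0 = spec.start_vector if start is None else np.asarray(start, float)
    if x0.shape != (spec.n_free,):
        raise InvalidInputError(
            f"start vector length {x0.size} != number of free parameters "
            f"{spec.n_free}"
        )
    for v, (lo, hi), name in zip(x0, spec.bounds, spec.free_names):
        if not (lo <= v <= hi):
            raise InvalidInputError(
                f"start value {v} for {name} outside bounds [{lo}, {hi}]"
            )
    t0 = float(obs.wave_times[0]) if t0 is None else float(t0)

    def fun(x):
        params, init = spec.to_model(x, t0)
        return sse_objective(params, init, obs, rtol=rtol, atol=atol,
                             method=method)

    if spec.n_free == 0:
        # nothing to optimize: evaluate the fully fixed model
        params, init = spec.to_model(x0, t0)
        sse, rmse_n, r2_n, rmse_p, r2_p = _fit_metrics(params, init, obs,
                                                       rtol, atol, method)
        return FitResult(
            params=params, init=init, free_names=(), x=x0, sse=sse,
            rmse_n=rmse_n, r2_n=r2_n, rmse_p=rmse_p, r2_p=r2_p,
            converged=True, message="no free parameters", nfev=1,
        )

    res = minimize(
        fun, x0, method="L-BFGS-B", bounds=spec.bounds,
        options={"maxiter": maxiter},
    )
    params, init = spec.to_model(res.x, t0)
    sse, rmse_n, r2_n, rmse_p, r2_p = _fit_metrics(params, init, obs, rtol,
                                                   atol, method)
    return FitResult(
        params=params, init=init, free_names=spec.free_names,
        x=np.asarray(res.x, float), sse=sse,
        rmse_n=rmse_n, r2_n=r2_n, rmse_p=rmse_p, r2_p=r2_p,
        converged=bool(res.success), message=str(res.message), nfev=int(res.nfev),
    )


def fit_multistart(
    spec: ParameterSpec,
    obs: ObservedTrajectories,
    n_starts: int = 32,
    seed: int = 20260319,
    **fit_options,
) -> FitResult:
    """Repeat :func:`fit_single` from seeded uniform-in-bounds starts.

    Starts are drawn sequentially from one generator, so extending
    ``n_starts`` under the same seed only appends new starts (the best
    SSE is nonincreasing in ``n_starts``).  Returns the best run,
    annotated with the SSE distribution across starts.
    """
    if n_starts < 1:
        raise InvalidInputError(f"n_starts must be >= 1, got {n_starts}")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    best = None
    sses = []
    failures = []
    for i in range(n_starts):
        x0 = lo + (hi - lo) * rng.random(spec.n_free)
        try:
            fit = fit_single(spec, obs, x0, **fit_options)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(f"start {i}: {exc}")
            sses.append(math.inf)
            continue
        sses.append(fit.sse)
        if best is None or fit.sse < best.sse:
            best = fit
    if best is None:
        raise FitError(
            "all multistart runs failed: " + "; ".join(failures)
        )
    best.n_starts = n_starts
    best.seed = seed
    best.sse_starts = np.asarray(sses)
    return best
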
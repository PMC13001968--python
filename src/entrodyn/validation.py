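"""Fit-quality metrics and structural validation procedures.

Provides per-trait goodness-of-fit metrics (RMSE, coefficient of
determination, Pearson correlation with a two-sided p-value, dynamic
time warping distance), leave-one-wave-out forecast validation, and
local +/-10% parameter-sensitivity scans around a fitted optimum.

R-squared is the regression convention ``1 - SSE/SStot`` about the
observed mean and may be negative for fits worse than the mean.  DTW is
the minimal textbook dialect: absolute-difference local cost, full
window, boundary-matched endpoints, no path-length normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats

from .dynamics import simulate
from .errors import InvalidInputError, UndefinedMetricError
from .estimation import (
    DEFAULT_BOUNDS,
    FitResult,
    ObservedTrajectories,
    ParamEntry,
    ParameterSpec,
    fit_multistart,
    fit_single,
)

__all__ = [
    "MetricReport",
    "LOOFold",
    "LOOReport",
    "SensitivityRow",
    "SensitivityReport",
    "basic_metrics",
    "dtw_distance",
    "trait_metrics",
    "loo_validate",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class MetricReport:
    """Goodness-of-fit metrics for one trait."""

    rmse: float
    r_squared: Optional[float]
    pearson_r: Optional[float]
    pearson_p: Optional[float]
    dtw_distance: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse, "r_squared": self.r_squared,
            "pearson_r": self.pearson_r, "pearson_p": self.pearson_p,
            "dtw_distance": self.dtw_distance,
        }


def basic_metrics(observed, predicted) -> MetricReport:
    """RMSE, R-squared and Pearson r (with two-sided p) of a prediction.

    The p-value is the two-sided t test on r with ``n - 2`` degrees of
    freedom.  A constant observed vector leaves r and R-squared
    undefined and raises :class:`UndefinedMetricError`; use
    :func:`rmse_only` if only the error is needed.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length vectors")
    if observed.size < 2:
        raise InvalidInputError("need at least 2 observations")
    resid = predicted - observed
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((observed - observed.mean()) ** 2))
    if sstot == 0.0:
        raise UndefinedMetricError(
            f"observed vector is constant; R^2 and Pearson r undefined "
            f"(rmse={rmse:.6g})"
        )
    r_squared = 1.0 - float(np.sum(resid**2)) / sstot
    if np.ptp(predicted) == 0.0:
        pearson_r, pearson_p = None, None
    else:
        r, p = stats.pearsonr(observed, predicted)
        pearson_r, pearson_p = float(r), float(p)
    return MetricReport(rmse, r_squared, pearson_r, pearson_p)


def rmse_only(observed, predicted) -> float:
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def dtw_distance(a, b) -> float:
    """Dynamic time warping distance between two sequences.

    Classic dynamic program with local cost ``|a_i - b_j|``, steps
    (i-1,j), (i,j-1), (i-1,j-1), matched boundaries and no window or
    normalization.  Symmetric in its arguments.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("dtw_distance requires nonempty sequences")
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((a.size + 1, b.size + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, a.size + 1):
        for j in range(1, b.size + 1):
            D[i, j] = cost[i - 1, j - 1] + min(
                D[i - 1, j], D[i, j - 1], D[i - 1, j - 1]
            )
    return float(D[a.size, b.size])


def trait_metrics(obs: ObservedTrajectories, fit: FitResult,
                  rtol: float = 1e-8, atol: float = 1e-10) -> dict:
    """Full metric reports (including DTW) for both traits of a fit."""
    traj = simulate(fit.params, fit.init, obs.wave_times, rtol=rtol, atol=atol)
    out = {}
    rep_n = basic_metrics(obs.n_observed, traj.N)
    out["N"] = MetricReport(
        rep_n.rmse, rep_n.r_squared, rep_n.pearson_r, rep_n.pearson_p,
        dtw_distance(obs.n_observed, traj.N),
    )
    if obs.p_observed is not None:
        rep_p = basic_metrics(obs.p_observed, traj.P)
        out["P"] = MetricReport(
            rep_p.rmse, rep_p.r_squared, rep_p.pearson_r, rep_p.pearson_p,
            dtw_distance(obs.p_observed, traj.P),
        )
    return out


# ---------------------------------------------------------------------------
# Leave-one-wave-out forecasting
# ---------------------------------------------------------------------------

@dataclass
class LOOFold:
    held_out_index: int
    wave_time: float
    observed_n: float
    predicted_n: float
    observed_p: Optional[float]
    predicted_p: Optional[float]
    converged: bool
    failed: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class LOOReport:
    """Leave-one-wave-out results: one fold per held-out wave plus the
    pooled held-out RMSE per trait (squared residuals pooled across
    folds before the root)."""

    folds: List[LOOFold]
    loo_rmse_n: float
    loo_rmse_p: Optional[float]
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "folds": [f.to_dict() for f in self.folds],
            "loo_rmse_n": self.loo_rmse_n,
            "loo_rmse_p": self.loo_rmse_p,
            "n_failed": self.n_failed,
        }


def _free_init_for_first_fold(spec: ParameterSpec, obs: ObservedTrajectories):
    """Holding out the first wave removes the data the initial condition
    is pinned to, so any data-pinned N0/P0 becomes a free, bounded
    parameter for that fold (started at the next wave's value)."""
    out = spec
    for name, vec in (("N0", obs.n_observed), ("P0", obs.p_observed)):
        if vec is None:
            continue
        entry = out.entries[name]
        if not entry.free:
            lo, hi = DEFAULT_BOUNDS[name]
            start = min(max(float(vec[1]), lo), hi)
            out = out.with_entry(name, ParamEntry(True, start, lo, hi, start))
    return out


def loo_validate(
    obs: ObservedTrajectories,
    spec: ParameterSpec,
    *,
    n_starts: int = 8,
    seed: int = 20260319,
    **fit_options,
) -> LOOReport:
    """Refit with each wave held out and predict it by forward simulation.

    Every fold keeps the original time origin; the refitted system is
    integrated over the full span and read off at the held-out wave.
    Folds whose refit raises are marked failed and excluded from the
    pooled RMSE (reported in ``n_failed``).
    """
    if obs.n_waves < 3:
        raise InvalidInputError("leave-one-wave-out needs at least 3 waves")
    folds: List[LOOFold] = []
    sq_n, sq_p = [], []
    for w in range(obs.n_waves):
        obs_train = obs.drop_wave(w)
        # holding out any later wave leaves the first wave (and thus any
        # data-pinned initial condition) in the training set untouched;
        # a fully fixed spec estimates nothing, so its initial condition
        # needs no freeing either
        spec_w = (
            _free_init_for_first_fold(spec, obs)
            if w == 0 and spec.n_free > 0
            else spec
        )
        try:
            t0 = float(obs.wave_times[0])
            fit = fit_multistart(spec_w, obs_train, n_starts=n_starts,
                                 seed=seed + w, t0=t0, **fit_options)
            init = fit.init
            if abs(init.t0 - t0) > 1e-12:
                raise InvalidInputError("fold time origin drifted")
            traj = simulate(fit.params, init, obs.wave_times)
        except Exception:  # noqa: BLE001 - fold failure is a reportable outcome
            folds.append(LOOFold(w, float(obs.wave_times[w]),
                                 float(obs.n_observed[w]), math.nan,
                                 None if obs.p_observed is None
                                 else float(obs.p_observed[w]),
                                 None, False, failed=True))
            continue
        pred_n = float(traj.N[w])
        obs_n = float(obs.n_observed[w])
        sq_n.append((pred_n - obs_n) ** 2)
        if obs.p_observed is not None:
            pred_p = float(traj.P[w])
            obs_p = float(obs.p_observed[w])
            sq_p.append((pred_p - obs_p) ** 2)
        else:
            pred_p, obs_p = None, None
        folds.append(LOOFold(w, float(obs.wave_times[w]), obs_n, pred_n,
                             obs_p, pred_p, fit.converged))
    n_failed = sum(f.failed for f in folds)
    if not sq_n:
        raise InvalidInputError("every leave-one-wave-out fold failed")
    loo_rmse_n = float(np.sqrt(np.mean(sq_n)))
    loo_rmse_p = float(np.sqrt(np.mean(sq_p))) if sq_p else None
    return LOOReport(folds, loo_rmse_n, loo_rmse_p, n_failed)


# ---------------------------------------------------------------------------
# Local parameter sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityRow:
    parameter: str
    direction: str  # "+10%" or "-10%"
    perturbed_value: float
    total_rmse: float
    percent_change: float
    clamped: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class SensitivityReport:
    baseline_rmse: float
    mode: str
    rows: List[SensitivityRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "baseline_rmse": self.baseline_rmse,
            "mode": self.mode,
            "rows": [r.to_dict() for r in self.rows],
        }

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame([r.to_dict() for r in self.rows])


def _total_rmse(params, init, obs) -> float:
    traj = simulate(params, init, obs.wave_times)
    res = [traj.N - obs.n_observed]
    if obs.p_observed is not None:
        res.append(traj.P - obs.p_observed)
    res = np.concatenate(res)
    return float(np.sqrt(np.mean(res**2)))


def sensitivity_scan(
    fit: FitResult,
    obs: ObservedTrajectories,
    spec: ParameterSpec,
    mode: str = "perturb_only",
    *,
    fractions=(0.9, 1.1),
    **fit_options,
) -> SensitivityReport:
    """Perturb each free parameter by +/-10% around its fitted value and
    record the change in total RMSE (both traits pooled).

    ``mode='perturb_only'`` evaluates the perturbed model directly;
    ``mode='perturb_refit_others'`` first re-optimizes the remaining
    free parameters with the perturbed one held fixed.  Perturbed values
    escaping their bounds are clamped and flagged.
    """
    if mode not in ("perturb_only", "perturb_refit_others"):
        raise InvalidInputError(f"unknown sensitivity mode {mode!r}")
    if not fit.converged:
        raise InvalidInputError("sensitivity_scan requires a converged fit")
    t0 = float(obs.wave_times[0])
    base_rmse = _total_rmse(fit.params, fit.init, obs)
    report = SensitivityReport(baseline_rmse=base_rmse, mode=mode)
    fitted = dict(zip(fit.free_names, fit.x))
    for name in fit.free_names:
        lo, hi = spec.entries[name].lower, spec.entries[name].upper
        for frac, label in zip(fractions, ("-10%", "+10%")):
            target = fitted[name] * frac
            clamped = not (lo <= target <= hi)
            value = min(max(target, lo), hi)
            if mode == "perturb_only":
                x = np.array([value if n == name else fitted[n]
                              for n in fit.free_names])
                params, init = spec.to_model(x, t0)
                rmse = _total_rmse(params, init, obs)
            else:
                spec_fixed = spec.with_entry(
                    name, ParamEntry(False, value, lo, hi)
                )
                start = np.array([fitted[n] for n in fit.free_names if n != name])
                refit = fit_single(spec_fixed, obs, start, **fit_options)
                rmse = _total_rmse(refit.params, refit.init, obs)
            pct = 100.0 * (rmse - base_rmse) / base_rmse if base_rmse > 0 else 0.0
            report.rows.append(
                SensitivityRow(name, label, value, rmse, pct, clamped)
            )
    return report
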
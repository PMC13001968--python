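"""Basic trajectory and fit figures (matplotlib)."""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory, simulate
from .estimation import FitResult, ObservedTrajectories

__all__ = ["plot_trajectory", "plot_fit"]


def plot_trajectory(traj: Trajectory, ax=None):
    """All three state variables against time on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.times, traj.N, label="N")
    ax.plot(traj.times, traj.P, label="P")
    ax.plot(traj.times, traj.E_stress, label="E_stress", linestyle="--")
    ax.set_xlabel("time (years)")
    ax.set_ylabel("state")
    ax.legend()
    return ax


def plot_fit(fit: FitResult, obs: ObservedTrajectories, ax=None, n_grid=200):
    """Fitted N/P curves over a dense grid with the observed waves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(obs.wave_times[0], obs.wave_times[-1], n_grid)
    traj = simulate(fit.params, fit.init, grid)
    ax.plot(grid, traj.N, label="N (model)")
    ax.plot(grid, traj.P, label="P (model)")
    ax.plot(obs.wave_times, obs.n_observed, "o", label="N (observed)")
    if obs.p_observed is not None:
        ax.plot(obs.wave_times, obs.p_observed, "s", label="P (observed)")
    ax.set_xlabel("time (years)")
    ax.set_ylabel("normalized entropy")
    ax.legend()
    return ax
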
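"""Generate a synthetic cohort and recover known dynamics.

First: multinomial Likert counts whose per-item entropies follow a
prescribed declining path, run back through the entropy module.
Second: noisy observations of a known ODE model, refit to check that
the strongly identifiable coefficients (alpha, beta, gamma) are
recovered.
"""

import numpy as np

from entrodyn import (
    CohortSimSpec,
    CoupledTraitParams,
    InitialCondition,
    TrajectorySimSpec,
    entropy_series,
    fit_multistart,
    generate_likert_waves,
    generate_trajectory_data,
)
from entrodyn.estimation import ParamEntry, ParameterSpec

# --- cohort counts -> entropies ------------------------------------------
spec = CohortSimSpec(n_items=2, wave_times=[0.0, 3.0, 9.0, 19.0, 23.0],
                     n_respondents=1700, total_attrition=0.66, seed=11)
tables = generate_likert_waves(spec)
by_item = {}
for t in tables:
    by_item.setdefault(t.item_id, []).append(t)
for item, rows in sorted(by_item.items()):
    s = entropy_series(rows)
    print(f"{item}: H(t) =", np.round(s.entropy_bits, 3),
          f"(n per wave {[r.n_respondents for r in rows]})")

# --- trajectory observations -> parameter recovery -----------------------
truth = CoupledTraitParams(mu=0.05, alpha=0.3, beta=0.4, gamma=0.15,
                           c1=1.0, c2=0.2, c3=1.0, K=0.5)
init = InitialCondition(0.0, 0.8, 0.85, 0.05)
obs = generate_trajectory_data(
    TrajectorySimSpec(truth, init, [0.0, 3.0, 9.0, 13.0, 19.0, 23.0],
                      noise_sd=0.005, seed=42)
)
entries = {
    "alpha": ParamEntry(True, 0.5, 0.0, 5.0),
    "beta": ParamEntry(True, 0.2, -2.0, 2.0),
    "gamma": ParamEntry(True, 0.1, 0.0, 1.0),
    "mu": ParamEntry(False, truth.mu, 0.0, 1.0),
    "c1": ParamEntry(False, truth.c1, 0.0, 20.0),
    "c2": ParamEntry(False, truth.c2, 0.0, 20.0),
    "c3": ParamEntry(False, truth.c3, 0.0, 20.0),
    "K": ParamEntry(False, truth.K, 1e-3, 10.0),
    "N0": ParamEntry(False, init.N0, 0.0, 1.0),
    "P0": ParamEntry(False, init.P0, 1e-4, 1.0),
    "E0": ParamEntry(False, init.E0, 1e-4, 1.0),
}
fit = fit_multistart(ParameterSpec(entries), obs, n_starts=4, seed=7)
for name, est, true in zip(("alpha", "beta", "gamma"), fit.x,
                           (truth.alpha, truth.beta, truth.gamma)):
    print(f"{name}: true={true:.3f} estimated={est:.3f} "
          f"({100 * abs(est - true) / true:.1f}% off)")
print("\nThe declining entropy paths mimic a shrinking aging cohort; the")
print("refit shows the six-wave design carries enough information to pin")
print("down the self-limitation, coupling and stress-growth coefficients.")
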
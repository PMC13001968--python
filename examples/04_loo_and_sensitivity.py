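"""Out-of-sample and robustness diagnostics on the dental fixture.

Leave-one-wave-out refits the model with each wave excluded and
predicts the held-out wave by forward simulation; the +/-10%
sensitivity scan perturbs each fitted coefficient and reports the
change in total RMSE.
"""

from entrodyn import (
    ParameterSpec,
    dental_observed,
    fit_multistart,
    loo_validate,
    sensitivity_scan,
)

obs = dental_observed(scale="norm")
spec = ParameterSpec.reduced(obs)

loo = loo_validate(obs, spec, n_starts=8, seed=20260319)
print("held-out predictions (normalized scale):")
for f in loo.folds:
    print(f"  wave t={f.wave_time:.0f}: supp obs={f.observed_n:.4f} "
          f"pred={f.predicted_n:.4f} | time obs={f.observed_p:.4f} "
          f"pred={f.predicted_p:.4f}")
print(f"LOO RMSE: supp={loo.loo_rmse_n:.4f} time={loo.loo_rmse_p:.4f}")

fit = fit_multistart(spec, obs, n_starts=32, seed=20260319)
sens = sensitivity_scan(fit, obs, spec, mode="perturb_only")
print(f"\nbaseline total RMSE: {sens.baseline_rmse:.5f}")
print("parameter  direction  RMSE change")
for row in sens.rows:
    print(f"  {row.parameter:6s}  {row.direction:5s}  {row.percent_change:+9.1f}%")
print("\nLarge RMSE changes mark coefficients the four waves actually")
print("constrain; near-zero changes mark weakly identified ones.")
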
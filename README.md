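# entrodyn

Entropy-initialized coupled-trait ODE modelling of longitudinal Likert
cohort data.

Longitudinal surveys (aging cohorts, student panels) measure ordered
categorical (Likert) items at a handful of waves. `entrodyn` compresses
each item's response distribution at each wave into a normalized
Shannon entropy — a scale-free summary of how dispersed the cohort's
answers are — and models the resulting low-dimensional trajectories
with a small autonomous system of coupled ordinary differential
equations. It is aimed at quantitative researchers who want an
interpretable continuous-time description of cohort-level change
without latent-variable machinery, plus the validation tooling
(out-of-sample forecasting, null-model contrasts, sensitivity scans)
needed to judge whether such a description is earning its keep.

## The model

For item $j$ with category counts $x_1,\dots,x_n$ at wave $t$:

$$p_i = \frac{x_i}{\sum_k x_k}, \qquad
H_j(t) = -\sum_i p_i \log_2 p_i, \qquad
H_{j,\mathrm{norm}}(t) = \frac{H_j(t)}{\log_2 n} \in [0,1],$$

and the pooled cohort index is the unweighted mean
$H^*(t) = \tfrac1J \sum_j H_{j,\mathrm{norm}}(t)$.

Two normalized entropy trajectories are mapped onto the states $N$
(primary trait) and $P$ (coupled trait); a third latent state
$E_\mathrm{stress}$ carries slowly accumulating context. With
$s(N) = \alpha N + \beta^2 P$ and
$E_\mathrm{met} = c_1 P + c_2 N + c_3 E_\mathrm{stress}$:

$$\frac{dN}{dt} = \mu N - s(N)\,N, \qquad
\frac{dP}{dt} = \mu P - \beta P\,\frac{E_\mathrm{met}}{G}, \qquad
\frac{dE_\mathrm{stress}}{dt} = \gamma E_\mathrm{stress}\frac{N}{N+K}.$$

The system is initialized from the first observed wave
($N(t_0)$ = first value of the N-mapped trait) and then evolves
autonomously. Coefficients are estimated by bounded multistart least
squares (L-BFGS-B) against the observed waves; an optional sinusoid
$A\sin(\omega(t-t_0))$ can be injected into the cost term, and an
uncoupled null model ($\beta = c_2 = c_3 = 0$) serves as the
structural baseline. Fits are evaluated with RMSE, $R^2$, Pearson $r$,
dynamic-time-warping distance, leave-one-wave-out forecasting and
±10% parameter-sensitivity scans.

## Worked example

The package bundles a four-wave dental-student fixture: entropies of a
perceived-support item (`supp`, mapped to N) and a perceived
time-pressure item (`time`, mapped to P) over academic years D1–D4.

```python
from entrodyn import ParameterSpec, dental_observed, fit_multistart

obs = dental_observed(scale="norm")          # entropies / log2(5)
spec = ParameterSpec.reduced(obs)            # free: mu, alpha, gamma, E0, beta, c1
fit = fit_multistart(spec, obs, n_starts=32, seed=20260319)
print(f"SSE={fit.sse:.6f}  supp RMSE={fit.rmse_n:.4f} R2={fit.r2_n:.4f}"
      f"  time RMSE={fit.rmse_p:.4f} R2={fit.r2_p:.4f}")
```

prints

```
SSE=0.002116  supp RMSE=0.0115 R2=0.4924  time RMSE=0.0199 R2=0.8845
```

i.e. on the normalized scale the integrated model passes within about
0.01–0.02 entropy units of the eight observations; the multistart SSE
spread (`fit.start_stats`) shows whether independent random
initializations agree on that optimum. `examples/` contains one short
script per capability (entropy compression, forward simulation, the
dental fits, LOO + sensitivity, synthetic-cohort recovery), and the
same stages are scriptable from the shell:

```bash
entrodyn synth dental --out dental.csv
entrodyn fit --data dental.csv --item-n supp --item-p time --out fit.json
entrodyn pipeline --data counts.csv --out-dir run/ --loo --sensitivity
```

## Layout

- `src/entrodyn/entropy.py` — Likert counts → entropies → pooled index
- `src/entrodyn/dynamics.py` — the ODE system and its integrator
- `src/entrodyn/estimation.py` — parameter specs, bounded multistart fitting
- `src/entrodyn/validation.py` — metrics, DTW, LOO, sensitivity scans
- `src/entrodyn/synthetic.py` — cohort/trajectory generators, dental fixture
- `src/entrodyn/io.py`, `cli.py` — file formats, pipeline, `entrodyn` CLI
- `docs/methods.md` — modelling assumptions, defaults and limitations
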
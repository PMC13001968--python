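# Methods

This note records the modelling choices behind `entrodyn`: what the
model assumes, what the defaults mean, what the synthetic generators do
and do not emulate, and where the numerics have been deliberately
pinned down.

## Entropy compression

Each (item, wave) cell of a Likert table is reduced to the Shannon
entropy of its category proportions, in bits, with zero-probability
categories contributing nothing. Entropy is then normalized by its
theoretical maximum `log2(n_categories)` so items with different
category counts are comparable, and normalized item entropies are
averaged (unweighted) into the pooled index H*(t).

Assumptions and consequences:

- Entropy is a *cross-sectional* dispersion summary. It says nothing
  about within-person change, and two very different response
  distributions can share an entropy value.
- The category count is taken per item from the data, never hard-coded;
  the dental fixture carries it as explicit metadata (default 5)
  because the underlying instrument's count is not part of the record.
- No respondent-count weighting is applied when pooling; waves with few
  respondents count as much as full waves. Attrition therefore shows up
  as sampling noise in the entropy, not as a weight.
- Probability vectors must sum to 1 within 1e-9. Counts-derived inputs
  satisfy this exactly; the tolerance only absorbs float round-trips.

## The dynamical system

States: N (primary trait, initialized from the N-mapped trait's first
wave), P (secondary coupled trait), E_stress (latent context). Time is
in years relative to the first observed wave; all states are
dimensionless, on the normalized-entropy scale when fit to data.

- dN/dt = mu*N − (alpha*N + beta²*P)·N. `mu` (per year) is a shared
  baseline persistence rate; `alpha` self-limits N; `beta` couples P
  into N's damping, squared so either sign of beta damps.
- dP/dt = mu*P − beta·P·(c1*P + c2*N + c3*E_stress)/G. The cost
  aggregate weighted by `c1..c3` (dimensionless) damps P, scaled by the
  capacity constant `G > 0`. G defaults to 1.0 — no principled value
  exists, it simply sets the scale against which the cost term is
  measured, so it is fixed by convention and may be freed in fitting.
- dE/dt = gamma·E_stress·N/(N+K). Stress self-amplifies at rate
  `gamma` (per year) through a saturating kernel with scale `K > 0`
  (default 0.5), so stress cannot explode at small N.

Optional sinusoidal forcing A·sin(omega·(t−t0)) is added to E_stress
*inside the cost term only*, scaled by c3; the stress ODE itself stays
unforced. Defaults A=1, omega=1 rad/year. The uncoupled null model
zeroes every N↔P pathway (beta, c2, c3), reducing N to logistic decay
and P to exponential persistence while keeping the same initialization
and functional class.

The origin (0,0,0) is a fixed point, nonnegative parameters preserve
nonnegative states, and E_stress is nondecreasing whenever gamma ≥ 0
and N ≥ 0 — all asserted as property tests.

## Integration

Forward simulation uses adaptive explicit Runge–Kutta (RK45) with
rtol 1e-8, atol 1e-10, evaluated densely at the requested times; a
state exceeding 1e12 in magnitude aborts with a structured error
rather than propagating NaNs. The fitting objective instead defaults
to LSODA at the same tolerances: multistart draws trial points
uniformly in the bounds, and corners such as G ≈ 1e-3 with large c1·β
make the P equation stiff enough that an explicit method spends ~1e5
steps per evaluation. LSODA switches to a stiff method there and
agrees with RK45 within integration tolerance on benign points (tested
directly). The explicit path is itself verified against closed forms
(exponential, hyperbolic-decay and exponential-stress limits, 1e-7)
and an independent fixed-step classical RK4 oracle at step 1e-3 over
25 years (1e-6).

## Estimation

The objective is the pooled sum of squared errors of N and P against
the two observed trajectories at the wave times. Trial points whose
simulation blows up receive a finite penalty (1e6) so the optimizer
can continue. Minimization is bounded L-BFGS-B with forward-difference
gradients (scipy's default relative step, ~1.5e-8); multistart repeats
the descent from seeded uniform-in-bounds starts, drawn sequentially
from one generator so extending `n_starts` under a seed only appends
starts. Default n_starts=32, seed=20260319.

Default box bounds: mu∈[0,1], alpha∈[0,5], beta∈[−2,2], gamma∈[0,1],
c1..c3∈[0,20], K,G∈[1e-3,10], A∈[0,5], omega∈[0,2π], P0,E0∈[1e-4,1],
N0∈[0,1]. These bracket every illustrative parameter regime with ample
margin; they are conventions, not estimates.

Initialization policy: N0 is pinned to the N-trait's first observed
value, P0 likewise by default (both traits are observed, so both
starts come from data; a `p0_policy` of `free` or a constant is
available), and E0 — unobservable — is free by default. The reduced
parameterization frees (mu, alpha, gamma, E0, beta, c1) and fixes
c2=0.21, c3=0, K=0.5, G=1: the weakly-coupled illustrative regime.
Fitting happens on the normalized scale by default (`scale="bits"` is
available) — the in-package reference RMSEs for the dental fixture are
treated as upper bounds rather than values to match, because the
scale on which they were originally computed cannot be reconstructed
from the printed entropies (the printed RMSE/R² pairs are not mutually
consistent under any single scaling of those values).

## Validation

- R² is 1 − SSE/SStot about the observed mean (may be negative);
  Pearson's p-value is the two-sided t test with n−2 df.
- DTW is the minimal textbook dialect: |a_i − b_j| local cost, full
  window, boundary-matched, unnormalized; verified against exhaustive
  path enumeration for short sequences.
- Leave-one-wave-out refits with each wave excluded (seed offset per
  fold) and predicts the held-out wave by forward simulation over the
  full span. When the *first* wave is held out, any data-pinned N0 and
  P0 become free bounded parameters for that fold, since the values
  they would be pinned to are unseen; a fully fixed specification
  estimates nothing and skips the freeing. Fold failures are reported
  and excluded from the pooled RMSE (squared residuals pooled across
  folds before the root).
- The sensitivity scan evaluates total RMSE at 0.9× and 1.1× each
  fitted coefficient, either directly (`perturb_only`) or after
  re-optimizing the other free parameters (`perturb_refit_others`) —
  both are provided because "refit as needed" is ambiguous; perturbed
  values escaping bounds are clamped and flagged.

## Synthetic data

The cohort generator draws multinomial counts from categorical
distributions matched exactly (±1e-6 bits) to target entropies via a
one-parameter exponential tilt over linear category scores — entropy
is strictly monotone in the tilt, so bisection always converges.
Default entropy paths start uniformly in [1.9, 2.25] bits on a
5-category scale and decline linearly by 0.05–0.15 bits over the study
span, emulating the gently declining, 1.7–2.3-bit trajectories of a
multi-wave aging survey; default cohort size 1700 with geometric
attrition (0.66 total leaves roughly one third responding by the final
wave). What this does *not* emulate: item covariance, twin/family
structure, nonrandom dropout, response styles, or instrument changes
across waves — so passing tests show the pipeline recovers structure
under clean missing-completely-at-random sampling, not that real
cohorts are this well behaved.

The trajectory generator observes the ODE model itself plus i.i.d.
Gaussian noise (default sd 0.005 on the normalized scale, the order of
multinomial entropy noise at n≈1700). The parameter-recovery
experiments free (alpha, beta, gamma) — the strongly identifiable
trio — with other coefficients at truth; the truth used has c3 > 0
because with c3 = 0 the stress state influences nothing and gamma is
structurally unidentifiable. The coupled-vs-uncoupled contrast gives
both fits the same nominal free list; the uncoupled variant simply
evaluates with its coupling entries forced to zero, so its effective
dimension is smaller by construction — that asymmetry is the point of
the null model.

## Problem sizes

The dental fits run 32 starts over 4 waves; recovery and contrast
experiments use 20 replicates of 6 waves (4 and 3 starts), and the LOO
degradation check 10 replicates × 6 folds (4 starts each). These sizes
give stable pass/fail behaviour for the statistical assertions while
keeping a full run in the minutes range on one core.

## Known limitations

- Local optimization only: multistart probes, but does not certify,
  global optimality.
- No uncertainty quantification (no posterior, no profile likelihood);
  the sensitivity scan is a local, empirical probe.
- Identifiability at 4–6 waves is genuinely weak for several
  coefficients (mu/c1 trade off through the cost term; E0 and gamma
  only enter via c3). The multistart spread and sensitivity reports
  surface this rather than hide it.
- The wave spacing of the dental fixture (one year per academic stage)
  is a convention, overridable in `dental_fixture`.
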
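# Methods

This note documents the model, the simulator, the estimation machinery and
the validation design of `weevilmove`, including the numerical choices and
the limitations a user should know before trusting results on real data.

## 1. The movement model

The unit of analysis is the (individual × Δt-window) record. With y = 1 if
the individual completed at least one patch-to-patch crossing during the
window,

    logit P(y = 1) = α + x'β + b_ind + c_rep,
    b_ind ~ N(0, σ²_ind),   c_rep ~ N(0, σ²_rep)  (crossed),

with covariates: time of night (window start, minutes since darkness
onset) and its square; local and neighboring patch densities (individuals,
including the focal animal); local and neighboring sex ratios
(males/total, with an empty patch assigned the configurable convention
value 0.5); sex (female = 0, male = 1); bulb age (days, 0–9 cycling across
replicates); and up to seven pairwise interactions. The coefficients are
defined *per reference window* of `dt_ref_min` minutes (default 30): the
intercept is the baseline log-odds of moving at least once within such a
window. `ModelCoefficients.fitted()` carries the published estimates for
*C. sordidus* and is the package's default generating truth;
`REFERENCE_INTERVALS` carries the published 95% intervals used by the
recovery harness.

## 2. The simulator

`simulate_replicate` is *window-synchronous*. At the start of each
reference window the patch states (densities, sex ratios) are read off the
current membership, the linear predictor is evaluated per in-patch agent,
and a Bernoulli movement indicator is drawn with that window probability.
For a mover, the within-window completion time comes from the equivalent
constant per-tick hazard q = 1 − (1 − p)^(tick/Δt_ref) (default tick 60 s)
conditioned on at least one event in the window — a truncated-geometric
tick plus a uniform second — so that with constant covariates the
probability of at least one crossing in a window equals p exactly.
Corridor transit time is gamma distributed with mean 5.29 and SD 2.45 min
(the published spread is labelled a standard error, but with N = 882
crossings that is implausible, so it is treated as an SD); the initiation
time is completion minus duration, clamped to darkness onset, to the
agent's previous read plus the 60-s reader dead time, and to at least 1 s
after darkness onset. A crossing emits a near-antenna read at initiation
and a far-antenna read at completion; membership — and therefore every
density and sex ratio — flips at completion.

Design choices worth flagging:

* **Why window-synchronous rather than a free-running tick hazard.** The
  coefficients are defined on window-level probabilities. A generator whose
  states drift within the window while the estimator measures something
  else produces data whose conditional law is *not* the stated model; we
  verified cell-by-cell that the window-synchronous generator's decision
  covariates equal the reconstructed window-start covariates exactly, which
  makes parameter recovery a well-posed check of the inference machinery.
* **Last-known-patch accounting.** Between its near and far reads an
  animal's position is unobservable in the real detection record, so
  occupancy assigns every individual to a patch at all times, switching at
  the read that completes the crossing (x₁ + x₂ = N throughout).
* **Behavioural refractory period.** An agent does not initiate a new
  crossing within 60 s of its previous read. This mirrors the reader's
  dead time and guarantees that, at abort rate 0, every true crossing is
  observable — the reconstruction round-trip is then exact by design, and
  the hardware-suppression pass is a no-op.
* **Hierarchical seeding.** One experiment seed spawns independent
  per-replicate streams (roster and dynamics), so extending the design
  never perturbs earlier replicates.
* **Aborted corridor entries** (same-antenna read pairs) are off by
  default; when enabled, the dwell time is drawn at ≥ 61 s so the paired
  return read always clears the dead time.

## 3. Windowing and the two covariate conventions

`windowize` cuts the night into Δt-windows (5–60 min supported; a final
partial window is dropped with a log record) and attaches covariates under
one of two conventions:

* `window_start` (default): step-function values at the window opening —
  the state of the system when the decision window begins. These are
  measurable strictly before the indicator's interval.
* `interval_mean`: time-weighted means of the step functions over the same
  interval as the indicator — the measurement procedure of the original
  analysis, kept for replicating it on field data.

The default matters for two reasons, both discovered and quantified during
validation:

1. **Simultaneity.** With same-interval means, a mover's own membership
   flip shifts the mean covariates of its own y = 1 window (for example, a
   male's departure lowers its origin patch's mean sex ratio for the rest
   of the window). Fitting simulated data measured this way produces
   systematic coefficient distortions up to ~20 standard errors on the
   sex × sex-ratio terms. Decision-time covariates cannot be contaminated
   by the outcome.
2. **Exact aliasing.** For coherent snapshot covariates, density ×
   sex-ratio = patch male count, so LD·LSR + ND·NSR = (LD + ND)/2 holds
   *exactly* in every record and the quartet {LD, ND, LD·LSR, ND·NSR} is
   rank-deficient. Interval means break the identity only through
   within-window churn — that is, partly through the simultaneity
   contamination itself. Consequently, fits on snapshot covariates anchor
   one quartet member at a known value (an offset); the package anchors
   ND × neighboring-SR, the member with the weakest support in the
   original analysis. The anchored direction is structurally unidentifiable
   and is not validated; all other coefficients are estimated from data.

## 4. Estimation

`fit_glmm` maximizes a Laplace approximation to the marginal likelihood of
the Bernoulli-logit model with up to two crossed Gaussian intercepts,
exploiting the structure: the individual block of the penalized Hessian is
diagonal, the replicate block is small, and a Schur complement reduces
every Newton solve to a dense system of size (n_fixed + n_replicates).
Two stages:

1. **Profile stage.** Nelder–Mead over (σ_ind, σ_rep) with (β, u) jointly
   mode-optimized by damped penalized Newton (inner gradient tolerance
   1e-8, outer xatol 1e-5 / fatol 1e-8).
2. **Polish stage** (`refine_beta=True`, default). Quasi-Newton (BFGS,
   finite differences in standard-error-scaled coordinates) on the full
   Laplace objective over (β, σ) jointly, so the fixed effects maximize
   the approximate marginal likelihood *including* the log-determinant's
   dependence on β. This matches the reference Laplace implementations for
   this model class: on a 2160-row crossed fixture the fit agrees with
   lme4's `glmer` to <5e-4 on fixed effects and ~0.002 on the
   log-likelihood (a permanent cross-check test runs `glmer` through
   Rscript). Inside large selection loops `refine_beta=False` keeps the
   profile optimum; likelihood *differences* are insensitive to the
   variant.

Wald 95% intervals come from the σ-conditional Hessian at the optimum.
Degenerate inputs (constant response) raise immediately; suspected
separation (|β| > 40) or optimizer failure flags the fit non-converged
rather than failing silently. `fix_sigma` pins variance components (the
σ = 0 pin reproduces ordinary logistic regression exactly, which the test
suite checks against statsmodels GLM).

**Selection.** `backward_select` removes interactions and then main
effects by likelihood-ratio tests at α = 0.05, always removing the
highest-p candidate first (ties break toward the later term), refitting
the random effects at each step, and never removing a main effect that
participates in a retained (or anchored) interaction. **Variance-component
tests** halve the p-value by default (boundary-at-zero 50:50 χ² mixture).
**Dispersion** is reported as sqrt[(Σ Pearson residuals² + |û|²)/n], with
the random-effect penalty evaluated at the spherical modes; it is a
diagnostic only, as the exact composition of the original penalized
residual sum of squares is not documented. **VIF** screening is
report-only (warning above 3): with a 1:1 release design the sex-ratio
covariates hover near 0.5 and several columns are strongly collinear by
construction, so automatic dropping would be destructive.

**Approximate Bayesian intervals.** `mcmc_fit` runs random-walk Metropolis
over (β, σ) against the Laplace-integrated marginal posterior under
weakly informative priors (β ~ N(0, 10²), σ ~ half-N(0, 5²)), with
split-R̂ flagging above 1.05. It provides credible intervals in the spirit
of the original analysis's MCMC fit; it is not a full joint sampler over
the random effects.

## 5. Validation design and what it does (not) show

The recovery harness (`run_recovery`, also driving
`scripts/acceptance.py`) simulates the complete published design — initial
counts {4, 6, 10} × 10 replicates and {16, 20, 24, 30, 40, 50} × 4, 1:1
sex ratio, one 720-min night, 920 individuals — from the fitted
coefficients, reconstructs, windowizes at Δt = 30, fits the final model
(ND × neighboring-SR anchored) and averages estimates over five seeds
(~22,080 records and ~450–550 crossings per seed; the whole harness runs
in about half a minute).

Observed behaviour of this pipeline, measured over seeds 1–5:

* Most coefficients are recovered within the published 95% intervals,
  including the steep sex × local-sex-ratio interaction, both sex-ratio
  main effects, the density–density interaction and both variance
  components.
* The **intercept** recovers ~0.27 high and **local density** rides a
  weakly identified direction (within a replicate LD + ND equals the
  release count, which the replicate intercept absorbs; the sex-ratio
  covariates barely leave 0.5). These deviations appear *only* under the
  closed-loop dynamics — redrawing the response exogenously on the same
  covariate tables recovers everything without bias — i.e. they are the
  dynamic-panel feedback effect (random effects correlated with the
  covariate histories they helped create), which the original experiment
  shares but which no conditional-likelihood fit removes.
* Simulating the fitted model forward yields ~0.65 (F) / 0.54 (M)
  crossings per individual per night, roughly half the originally
  observed 1.24 / 1.1. A conditional model fitted to realized covariate
  trajectories does not, run as a causal engine from the release initial
  condition (everyone in one patch, strong local-density repulsion),
  reproduce the marginal activity of the real animals — a useful caution
  against using such coefficient tables as forward simulators. The
  information content of the simulated data is correspondingly lower,
  which is also why backward selection drops the LD × local-SR interaction
  (LRT χ² ≈ 3.8 here vs ≈ 24.5 in the original data) even though the
  published removals (bulb age, LD × neighboring-SR,
  sex × neighboring-SR) are reproduced.

The LRT null-calibration check uses directly simulated covariate tables
(10 replicates × 15 individuals × 24 windows) and tests an
observation-level truly-zero covariate: rejection ≈ 0.04–0.05. A caveat
surfaced during calibration: testing a *replicate-level* covariate (such
as bulb age) against χ²₁ with only ~10 replicates is anticonservative
(empirically ~0.09–0.10), because the effective sample size for such terms
is the number of replicates. Field analyses of replicate-level covariates
should rely on many replicates or on replicate-level resampling.

What passing these checks shows: the event processing is exact, the
windowing is correct, and the estimator recovers the generating model on
identified directions at realistic scale. What it does not show: that real
weevil data are free of the simultaneity and aliasing issues above (they
are not — any two-patch analysis with same-interval means inherits them),
nor that the simulator reproduces every feature of real trajectories (no
within-patch movement, no detection failure, perfect 1:1 antenna
geometry, activity calibrated to the fitted model rather than to the
observed rates).

## 6. Numerical details and defaults

| quantity | default | notes |
|---|---|---|
| reference window Δt_ref | 30 min | scale on which coefficients are defined; which Δt produced the published table is unstated, 30 is the package convention |
| analysis Δt | 30 min | 5–60 supported; signs are stable across 10/30/60 on the same data |
| tick | 60 s | within-window hazard discretisation |
| crossing duration | Gamma(mean 5.29, SD 2.45 min) | rounded to seconds, floor 1 s |
| empty-patch sex ratio | 0.5 | configurable convention |
| reader dead time / refractory | 60 s | same-antenna suppression window |
| night | 720 min, one night per replicate | bulb age cycles 0–9 d across replicates |
| inner / outer tolerances | 1e-8 / (xatol 1e-5, fatol 1e-8) | polish gtol 3e-5 in scaled units |
| α (selection) | 0.05 | fixed by the original analysis |
| anchor term | ND × neighboring-SR | weakest-evidence member of the aliased quartet |

Ties and degenerate cases: removal ties break toward the later term in the
spec order; exactly collinear design columns yield VIF = ∞ with a warning;
a Δt that does not divide the night drops the final partial window with a
log entry; an agent's trailing unpaired read is an unresolved corridor
entry and never a crossing.
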
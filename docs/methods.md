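# Methods

`gswitch` estimates per-protocol effects of sustained treatment strategies
on overall survival in a two-arm randomized trial with one-sided treatment
switching, using inverse-probability-of-censoring weighting (IPCW) and the
noniterative-conditional-expectation parametric g-formula in discrete time.
This note records the models, the conventions, the synthetic-data design
used for validation, and the open design choices made along the way.

## Data model and discrete-time conventions

Follow-up is discretized into 30-day intervals indexed `k = 0, 1, ...`.
Each person-time row carries the randomized arm `Z`, the current treatment
`A_k`, the time-varying covariates `L_k` (disease progression `dp`,
intracranial progression `icp`, performance state `ecog_tv`, target-lesion
size `tls`, months since progression `tdp`), and the event indicators
`Y_{k+1}` (death by the end of interval `k+1`) and `C_{k+1}` (loss to
follow-up), both attached to the row with index `k`.

Conventions the data model fixes:

- progression indicators are absorbing; `tdp` is 0 before progression, with
  `dp = 0` marking the pre-progression state;
- the hazard of death is structurally 0 before progression (death is gated
  by progression) — all estimators and the generator share this rule;
- when death and censoring would fall in the same interval, death wins;
- switching is recorded at the start of the interval of the first
  experimental dose; censoring-at-switch removes the switch interval itself;
- rows are emitted for complete intervals only;
- administrative censoring is handled by the common 48-month horizon, so the
  stochastic component of "LTFU/AC" in the generated data is LTFU alone.

The discrete hazard at month `m` is `h_m = Pr[death in m | alive at m-1]`;
survival is the product-limit `S_m = prod_{j<=m}(1 - h_j)`; risk is
`1 - S_m`. Effect measures at the horizon (48 months by default):

- `RR = risk_exp(48) / risk_ctrl(48)`;
- `cHR = ln S_exp(48) / ln S_ctrl(48)` (cumulative-hazard ratio). The
  discrete alternative `sum(h)` ratio is available via
  `chr_method="sum_hazard"`; the two coincide for small hazards and every
  output records which was used;
- `dHR = exp(arm coefficient)` of the pooled logistic outcome model.

Pooled logistic hazard models use quadratic time by default (saturated time
and 5-knot natural cubic splines are available). Spline knots sit at the
5/27.5/50/72.5/95th percentiles of the fitting data — a conventional
boundary-percentile placement, recorded in the design metadata.

## Estimators

**ITT.** Unadjusted (arm + quadratic time), strata-adjusted,
baseline-adjusted, and a marginal variant that standardizes over two cloned
copies of the baseline cohort with the arm forced to 0 and 1. Standardized
risks are means of per-subject model-implied risks, never means of hazards.
Supplying an LTFU/AC weight specification relaxes non-informative
censoring.

**Naive per-protocol.** Excluding ever-switchers, or censoring switchers at
the switch interval. Both are deliberately biased comparators when
switching is driven by prognostic time-varying covariates; censoring at
switch is biased *even when switching is independent of every covariate*,
because only progressed (hence high-risk) person-time can be censored.

**IPCW per-protocol.** Switching and LTFU/AC are treated as censoring
events with separate weight models per arm: a denominator pooled logistic
model on baseline plus time-varying covariates and a time-only numerator.
Switching models are fitted on control-arm post-progression person-time up
to and including the switch interval; the experimental arm and
pre-progression control person-time carry a deterministic switching weight
of 1. The weighted outcome model contains the randomized arm and linear and
quadratic time, never the confounders (enforced structurally); a weighted
life-table estimator is computed alongside. Percentile truncation of the
weights is available; truncating to the (50, 50) window makes every weight
the median, which reproduces the unadjusted censored analysis exactly.

### Stabilized versus unstabilized weights

Both variants are always computed. The stabilized weights — cumulative
products of (numerator event-free) / (denominator event-free) probabilities
starting at progression, exactly 1 under the deterministic rules — feed the
weight diagnostics (mean, SD, min, max and the extreme-weight alarms).

For *estimation*, the default is the unstabilized weights. The reason is
structural: switching-weight accrual begins at the subject-specific
progression time, so the cumulative time-only numerator is not a common
factor within an analysis month — it varies across subjects with their
progression time, which is a post-baseline prognostic variable that the
arm+time outcome model cannot absorb. On generated data with widely
dispersed progression times the stabilized-weighted curve is severely
biased toward the censor-at-switch curve while the unstabilized-weighted
curve recovers the counterfactual truth. When switching is generated
independently of covariates the two variants agree, and that equivalence is
tested. `AnalysisRequest(weight_type="stabilized")` restores the stabilized
analysis for sensitivity purposes.

### Extreme-weight alarms

Diagnostics flag a weight set when the mean drifts from 1 by more than 0.1
or the maximum exceeds 20 times the mean. The multiple is anchored on the
published range of this family of analyses: well-behaved specifications
show max/mean around 5–11, destabilized ones around 24–27.

### Covariate screening

`screen_covariates` retains a candidate when its univariate pooled-logistic
p-value is ≤ 0.20 or its odds ratio falls outside [0.75, 1.33], reporting
AIC alongside; multi-column terms use a likelihood-ratio p-value and the
most extreme column-wise OR.

## Parametric g-formula

Each arm is analysed as a separate observational study. Pooled-over-time
models are fitted for each time-varying covariate in the order `dp, icp,
ecog_tv, tls` (progression first so same-interval models may condition on
it): logistic for binary, multinomial for >2-level categorical, linear-
Gaussian for continuous (residual SD from the residual mean square).
History depth is one lag of each covariate plus the current interval's
earlier covariates; deeper history is excluded by default. Absorbing
covariates are fitted only where the lagged value is 0 and stick at 1 in
simulation; the outcome model is fitted on post-progression person-time
only. Terms that are constant on the fitting data (e.g. treatment in the
experimental arm, where everyone is always treated) are dropped and
recorded.

Simulation resamples observed baseline rows with replacement (preserving
the joint baseline distribution), rolls covariates forward from the fitted
models with treatment forced to the strategy value, applies the absorbing
and death-gating restrictions, and never simulates censoring. Default
10,000 histories per strategy per arm; Monte-Carlo standard errors are
reported. A post-hoc audit on every simulated dataset verifies
monotone risk, monotone progression means, the forced treatment and the
absence of censoring.

The natural-course mode simulates treatment from a fitted switching-hazard
model (control arm) instead of intervening, and compares simulated
covariate means and cumulative risk against the observed data month by
month, with a pass band of 3 combined (sampling + simulation) standard
errors. While the observed risk is still exactly 0 its Greenwood SE
degenerates to 0; the comparison floors it with the binomial SE implied by
the simulated risk. A p-value screening helper regenerates reduced model
ladders (p < 0.2 / 0.1 / 0.05) while always retaining each covariate's own
lag.

## Bootstrap inference

Nonparametric bootstrap over *subjects* (all person-time moves together),
stratified by randomized arm so arm sizes are preserved. The entire
procedure — weight estimation plus outcome fitting, or g-formula fitting
plus simulation — is re-run per replicate. Replicates that fail (non-
convergence, separation, empty category) are dropped and counted, never
retried; more than 50% failures flags the result unreliable. Intervals are
percentile-based; defaults are 1000 resamples for ITT/IPCW paths and 500
for the g-formula path. The g-formula procedure fixes its internal
Monte-Carlo seed so each replicate is a deterministic function of the
resampled data.

## The synthetic trial generator

The generator emulates the structure of an open-label oncology trial with
one-sided crossover: 138 control / 137 experimental subjects by default, a
48-month horizon, monthly visits. Every transition is discrete-time
logistic (or linear-Gaussian for lesion size) in the lagged state, so the
weighting and g-formula nuisance models can be specified *correctly* on
generated data — that is what makes the generator an oracle rather than
just a fixture. Counterfactual truths are computed by direct intervention:
`simulate_truth` re-runs the mechanism with switching and censoring forced
off and treatment fixed, giving the true risk curve of each sustained
strategy up to Monte-Carlo error.

Structure per month (fixed update order: time-varying covariates →
progression → intracranial progression → switching → censoring → death):

- performance state worsens with probability logistic in its lag, the
  lagged treatment and lagged progression;
- lesion size drifts linearly (growth slowed by treatment, accelerated by
  progression) with Gaussian noise;
- progression is an absorbing logistic hazard in lagged treatment, lesion
  size, performance state and age;
- switching (control arm, post-progression, at most once) is logistic in
  the *current* visit's lesion size, performance state, months since
  progression and age — the informative-censoring channel;
- LTFU is a small time-only hazard (~0.4%/month);
- death (post-progression only) is logistic in current treatment, lesion
  size, performance state and intracranial progression.

Treatment-confounder feedback runs through the lesion-size and
performance-state channels: prior treatment shapes them, and they drive
both later switching and death.

The default configuration was calibrated once, before any estimator
validation, to loose study-scale targets: ~47% of control subjects ever
crossing over (measured 47.0–48.2% at n = 10,000 across seeds), a control
never-switch counterfactual risk at month 48 of ≈ 0.55 against ≈ 0.37 under
sustained experimental treatment (truth RR ≈ 0.67), and an ITT risk ratio
of ≈ 0.7. Switching selection was deliberately kept moderate: with stronger
lesion-size/performance coefficients the probability of a high-risk control
subject remaining unswitched for years becomes so small that the weighted
analysis faces a *practical positivity violation* — even weights computed
from the true generator probabilities no longer recover the truth at
realistic sample sizes. The shipped strength leaves the censor-at-switch
bias large (≈ −0.12 at month 48, about 5 standard errors at 1,000 subjects
per arm) while keeping recovery feasible.

Two companion configurations ship alongside:

- `null_config` removes treatment from every hazard and transition;
  crossover and LTFU still occur, so the null exercise is non-trivial.
  Note that censoring-at-switch does **not** converge to RR = 1 even here —
  its selection on progression persists — which is exactly why it is the
  cautionary comparator.
- `weight_instability_config` concentrates crossover in the months right
  after progression (steep negative time-since-progression slope) and
  makes lesion size prognostic of switching mainly through its baseline
  value. Under the full weight model the stabilized weights are clean
  (mean ≈ 0.99, no alarms); dropping the time-since-progression terms
  leaves the model systematically over-predicting switching for
  long-unswitched large-lesion survivors, whose cumulative weights then
  destabilize (SD inflation ≥ 2×, typically far more, verified across
  many generator seeds before freezing). The default configuration's
  crossover is not concentrated enough after progression for this
  fragility to appear reliably, which is why the demonstration has its own
  configuration.

Randomness: one stream per subject keyed by `(seed, arm, index)`, so
cohorts are byte-reproducible and stable under changes in cohort size.

### What the generator does not emulate

Real trial features outside the generator: staggered accrual and therefore
heterogeneous administrative censoring times; visit-level missingness and
measurement error; more than two ECOG states; non-logistic hazard shapes;
unmeasured confounding (the generator's switching depends only on measured
covariates, so exchangeability holds by construction). Passing validation
on generated data therefore demonstrates that the estimators are correct
*under their stated assumptions*; it cannot certify those assumptions in
real data.

## Validation problem sizes

The shipped validation suite uses: 1,000 subjects per arm for the
confounded-recovery check (bootstrap SEs from 40–60 resamples), 400 per arm
for the null check, 20,000 intervened histories per oracle truth, 20,000
natural-course histories, 10,000 control subjects for the crossover
calibration check, and 2,500 control subjects for the weight-instability
demonstration. These sizes put Monte-Carlo error well below the effects
being demonstrated while keeping the whole battery runnable on a laptop in
a few minutes.

## Known limitations

- The cHR definition (log-survival ratio versus summed-hazard ratio) is a
  convention; both are exposed and labelled, and they diverge for large
  monthly hazards.
- Stabilized-weight estimation is offered but known to be biased under
  heterogeneous progression times (see above); diagnostics always use the
  stabilized weights, estimation defaults to unstabilized.
- The g-formula's categorical-logistic pathway (multinomial) is exercised
  only lightly, as the generator's performance state is binary.
- Weighted model fits use weighted maximum pseudo-likelihood; model-based
  covariances are not corrected for weight estimation — inference goes
  through the bootstrap, which re-runs weight estimation per replicate.
- LTFU/AC weight models are fitted on each arm's full person-time, not on
  the switch-censored view; with the light, time-only LTFU mechanism this
  distinction is immaterial, but it is a convention.
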
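# Methods

This note documents the models, defaults and numerical choices behind
`habitdecay`, and what the synthetic-data tests do and do not show
about real diary data.

## Data model and preprocessing

The unit of analysis is one participant's daily habit-strength series:
SRBAI scores (mean of four 0–4 Likert items, hence a 0–4 scale in steps
of 0.25) on an occasion grid `t = 0 … 83`, one unit = one day of the
84-day decay phase. Under the default indexing, occasion 0 is study
Day 8 (`day_offset = 8`); the Day-7 measurement taken before the decay
phase begins is kept aside as a baseline, not modelled. Both the offset
and the decision to exclude the baseline from the modelled series are
configurable.

Cleaning rules, in order:

* **Day recoding.** A response stamped in the half-open interval
  [00:00, 12:00) is an after-midnight submission and refers to the
  previous day; 12:00 noon itself belongs to the same day.
* **Scoring.** SRBAI = mean of the four items; rows with a partial
  item set are rejected with a warning (complete scales are the norm
  for this instrument, so a partial row signals a data error).
* **Duplicates.** Multiple responses on one participant-day are
  collapsed to their arithmetic mean.
* **Imputation.** Only *isolated* missing days — interior occasions
  whose immediate left and right neighbors are both observed — are
  filled, with the neighbor mean. For a singleton gap this equals
  linear interpolation, so the choice coincides with any linear scheme
  on the gaps it touches. Runs of two or more missing days, and edge
  singletons (no two neighbors), stay missing. The operation is
  idempotent and never alters an observed value.
* **Retention.** A participant enters analysis with ≥ 6 *observed*
  (non-imputed) measurements and a last observed occasion at or past
  the decay-phase midpoint (`midpoint_occasion = 41` by default; the
  day-to-occasion mapping makes the exact midpoint convention a
  one-unit judgement call, so the threshold is a config parameter).
  Exclusions are logged with the first failed rule.

Missing gaps are defined as runs of consecutive missing occasions
*including* edge runs: a dropout tail is as much a gap in observations
as an interior block, and the gap-based validity check should not treat
a participant missing the entire second half more leniently than one
with a mid-series block.

## Person-specific trajectory families

Six mean structures, with mean-parameter counts 1, 2, 3, 4, 3, 4:

| family | f(t) | parameters |
|---|---|---|
| constant | β₀ | β₀ |
| linear | β₀ + β₁t | β₀, β₁ |
| quadratic | + β₂t² | … |
| cubic | + β₃t³ | … |
| asymptotic | A + (R₀ − A)·exp(−e^λ·t) | lower asymptote A, initial value R₀, log rate λ |
| logistic | L + (U − L)/(1 + e^{(t−m)/s}) | asymptotes L, U, midpoint m, scale s > 0 |

The logistic carries a free lower asymptote (4 parameters) because the
stabilization criterion below needs "95 % of the *lower* asymptote";
with s > 0 and U > L the curve decays from U toward L, and U < L
represents habits that regain strength. The asymptotic rate is
parameterized on the log scale so it stays positive; the fit is
invariant under the reparameterization rate = e^λ.

**Estimation.** Polynomials: exact OLS via the Vandermonde normal
equations. Curves: bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobians, ftol = xtol = 1e−13). Bounds: level parameters in [−1, 5]
(slightly beyond the 0–4 scale, tolerating boundary-flat fits);
λ ∈ [ln 1e−4, ln 2]; m ∈ [−30, 120]; s ∈ [0.25, 60]. Initialization is
deterministic: level starts from the mean of the first/last five
usable values, plus a 9-point start grid (rates
0.003 … 1.6/day for the asymptotic; a 3 × 3 grid over m at the window
quartiles × s ∈ {2, 8, 25} for the logistic). Best SSE wins; ties go
to the earliest start. Observed and imputed occasions both enter the
fit; missing occasions are simply absent (never zero-filled). A family
is unfittable for a participant with fewer than k_mean + 2 usable
occasions. No autoregressive term is included: the aim is a univocal
description of the trajectory's shape.

**Model selection.** Gaussian BIC
`n ln(max(SSE, 1e−10)/n) + (k_mean + 1) ln n`, with n = occasions in
the fit and the error variance counted as a parameter. The 1e−10 floor
keeps perfect (noise-free) fits finite and comparable — among perfect
fits the penalty term alone decides, which is the intended parsimony
behavior. Ties within 1e−9 break by smaller k_mean, then by the fixed
family order (constant, linear, quadratic, cubic, asymptotic,
logistic).

## The four-step validity gate

1. **Decreasing**: fitted value at the first usable occasion minus the
   fitted value at the last exceeds 0 (strict). Fitted values, not raw
   data, because the gate judges the model's description.
2. **Leave-one-out selection stability**: delete each usable occasion
   in turn, refit all six families, recompute the BIC winner; the
   check passes only if every replicate selects the original family
   (unanimity). A ≥ 95 %-agreement variant is available
   (`loo_min_agreement`). A replicate with no converged fit counts as
   disagreement. Unanimity is the strictest reading of "selection not
   impacted by individual observations" and is the default.
3. **RMSE ≤ 0.33**, inclusive (RMSE = √(SSE/n)).
4. **Longest missing gap ≤ 21 days**, inclusive, computed on
   post-imputation missing runs (imputation fills only singletons, so
   runs ≥ 2 are unaffected).

A constant best fit cannot satisfy step 1; steps 2–4 alone decide the
separate `stable_habit_valid` verdict ("the habit stayed put" is a
valid description, but not a decay trajectory, so `overall_valid`
remains false for it).

## Stabilization estimates

All three estimators refuse to extrapolate: a solution beyond the last
usable occasion is reported as null with `within_window = False`.
Reported days are ceilings of continuous solutions ("reached by day
d"), floored at 0.

* **asymptote95** (asymptotic/logistic best fits): solve
  f(t*) = f(0) − 0.95·(f(0) − lower asymptote). Closed forms:
  asymptotic t* = ln 20 · e^(−λ); logistic
  t* = m + s·ln(20(1 + e^(−m/s)) − 1). For the asymptotic family
  f(0) = R₀, so measuring the drop from f(0) coincides exactly with
  "95 % of the asymptote reached". For the logistic it is a choice:
  the default measures from f(0); `drop_from_f0=False` measures from
  the upper asymptote U (then t* = m + s·ln 19).
* **window7** (primary for linear/quadratic/cubic; emitted for all
  families for comparison): first occasion t with
  |f(t + 6) − f(t)| < threshold and t + 6 inside the observed span.
  The change is measured between the window's endpoints, not max−min
  within it. Two thresholds circulate for this criterion — 0.1 and
  0.01 — and the package computes both every run (`window_threshold`,
  `window_threshold_alt`), reporting the 0.1 variant in the main
  summary; neither is asserted as the canonical setting.
* **midpoint_cross**: first occasion with f(t) < 2.0, flagged as
  before/after the method-specific stabilization day.

The summary table (median, min, max per method × family) is restricted
to participants whose fitted values are overall-valid *and* cross the
scale midpoint, mirroring how such estimates are conventionally
tabulated.

## Group-level models

* **ICC**: random-intercept-only model by ML
  (`statsmodels MixedLM`); ICC = σ²_b/(σ²_b + σ²_w). Degenerate
  cohorts are resolved analytically before the optimizer sees them
  (zero within-variance → ICC 1 with a warning; no between-person
  spread → ICC 0, flagged).
* **Cubic LMM**: fixed cubic polynomial in rescaled time
  t′ = t · (1.72 / t_max) ∈ [0, 1.72]; random effects added
  iteratively (intercept → +linear → +quadratic → +cubic); optional
  group contrast: a 0/1 dummy for one focal group versus the combined
  average of the others, as a main effect and optionally interacted
  with t′, t′², t′³ — one focal group per model. ML throughout so the
  BIC ladder is coherent across fixed-effect structures;
  BIC = −2ℓ + (p_fixed + q(q+1)/2 + 1)·ln N with N = observations.
  Rescaling is affine and order-preserving, so fitted values are
  invariant to the scale constant (verified by test); 1.72/t_max is
  the fixed default. A singular random-effects covariance is flagged
  in diagnostics but the fit is retained, so estimation trouble is
  visible rather than silently discarded. Lag-1 autocorrelation of
  within-person residuals is a known feature of such data; it is left
  unmodelled here (the cubic LMM is a marginal trend model, not a
  forecasting model).
* **Asymptotic mixed model, two-stage**: full-likelihood nonlinear
  mixed models for this curve are fragile in practice, so the package
  deliberately uses a deterministic two-stage estimator. Stage 1:
  per-person bounded NLS for (Aᵢ, R₀ᵢ, λᵢ) with sampling covariances
  σ̂²(JᵀJ)⁻¹ from the analytic Jacobian. Stage 2: between-person
  covariance D = sample covariance of the estimates minus the mean
  sampling covariance, floored to positive semidefinite by eigenvalue
  clipping; fixed effects are precision-weighted means with weights
  1/(sampling variance + between-person variance), i.e. a
  random-effects pooling per coordinate. The reported BIC is a
  *conditional pseudo-BIC* from stage-1 residuals (flagged
  `bic_kind: two_stage_pseudo` in diagnostics) and must not be ranked
  against the marginal BICs of the linear mixed models. The model is
  declared non-estimable when more than half the stage-1 fits fail. A
  full NLMM can be plugged in behind the same result type later.

## Synthetic cohort generator

The generator emulates the structure of a four-group diary study:
groups SB/US/AC/TS sized 46/57/52/39 (N = 194), 84 daily occasions,
plus a Day-7 baseline response. Per participant it draws a family from
a mix dominated by the curve families (6 % constant, 7 % linear, 14 %
quadratic, 17 % cubic, 29 % asymptotic, 27 % logistic), parameters from
uniform priors rejection-sampled so the latent curve stays on the 0–4
scale, residual SD from U(0.2, 0.5), and group-specific intercept
shifts (+0.5 SB, −0.3 US, −0.6 AC, +0.3 TS — group differences in
level only, not shape, with the strongest initial habits in the
sedentary-behavior and smoking groups). The observed value is
latent + Gaussian noise, clamped to [0, 4] and decomposed into four
integer items whose mean is the 0.25-grid score. Missingness combines
isolated Bernoulli missingness (p = 0.12/day) with 0–3 long gap blocks
per participant of geometric length (minimum 2, mean ≈ 14 days),
starting in the second half of the series with probability 0.7; these
defaults realize ≈ 28–29 % total missingness with ≈ 1,150–1,200
singleton-imputable days per 194-participant cohort and late-series gap
clustering. Duplicates (p = 0.02/day) and after-midnight timestamps
(p = 0.08/response) exercise the cleaning rules. Everything is driven
by one `numpy` Generator seed; equal configs give byte-identical
tables.

Ground truth records each participant's family, parameters, noise SD
and — for decaying curve families — the noiseless 95 %-asymptote day,
so recovery tests have exact targets.

**What the generator does not emulate:** response-style drift,
floor/ceiling censoring beyond clamping, time-varying noise,
autocorrelated residuals, informative missingness (gaps are independent
of the latent trajectory), or cue-encounter/behavior streams. Passing
recovery tests on this cohort therefore shows the estimators are
correct under the stated data model, not that real diary data satisfy
that model; in particular the generator's between-person dispersion
yields a lower ICC (≈ 0.5–0.6) than strongly person-separated real
cohorts can show.

## Problem sizes and determinism

The package's own evaluation runs at the following sizes, chosen to
exercise each estimator at meaningful scale: exact recovery at 84
occasions per family; stabilization-day recovery over 100 noisy
replicates; a 1,000-point closed-form sweep; ICC recovery over 100
replicates of 200 × 84; cubic-LMM recovery at 200 participants; and a
quarter-scale cohort (49 participants) through the complete pipeline
including leave-one-out refits, which dominate runtime (~6 × n_occasions
refits per participant). All randomness flows from explicit seeds;
there are no stochastic restarts anywhere in estimation, so identical
inputs give identical outputs.

## Known limitations

* The leave-one-out operationalization (single deletions, unanimity)
  and the singleton imputation rule are documented package choices;
  other reasonable operationalizations (small-subset deletion,
  model-based imputation) are out of scope.
* The two-stage asymptotic mixed estimator is not a full NLMM; its
  fixed effects are consistent under the stated model but its
  pseudo-BIC is not comparable across model classes.
* Stabilization-day estimates inherit the fitted model's bias: under
  heavy noise the BIC occasionally prefers a polynomial to the true
  curve family, and those replicates contribute no asymptote95
  estimate.
* The multilevel logistic model is intentionally absent.
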
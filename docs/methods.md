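# Methods

## Model overview

The package estimates the association of non-HDL cholesterol with
atherosclerotic cardiovascular disease (CVD) and turns it into an absolute
lifetime-risk tool. All survival modelling uses **age as the timescale**: a
subject enters the risk set at their baseline age and leaves at the age of
event or censoring (left truncation / delayed entry). Non-CVD death is a
**competing risk** throughout — a subject who dies of another cause can no
longer have a CVD event, so naive Kaplan–Meier-based risks would be inflated.

Two layers of analysis share this structure:

* **Nonparametric**: the Aalen–Johansen estimator of the cause-specific
  cumulative incidence F₁(t), with the counting-process (delta-method)
  variance, and Gray's K-sample test (ρ = 0 weights) comparing
  subdistribution hazards across exposure groups.
* **Semiparametric**: cause-specific Cox models (CVD; non-CVD death),
  stratified by sex and cohort, with Efron tie handling. For absolute risk,
  each stratum's baseline hazard is given a parametric Weibull form
  h(a) = (k/λ)(a/λ)^(k−1), estimated by maximising the left-truncated
  likelihood with the subject-level Cox linear predictor as a fixed
  multiplicative offset. The probability of CVD by 75 for a subject aged
  a₀ ∈ [35, 70] is F₁(75|a₀) = ∫ S(u|a₀) h₁(u) du with the all-cause survival
  S available in closed form (Weibull cumulative hazards) and the outer
  integral by the trapezoid rule on a per-subject uniform grid of 801 nodes
  (step ≤ 0.05 y; halving the step moves results by < 1e−5).

## Exposure handling

Non-HDL cholesterol = total − HDL cholesterol (mmol/L; 38.67 mg/dL per
mmol/L). Recorded values of subjects on lipid-lowering therapy are inflated
by 30% to approximate untreated concentrations. Categories use bounds
2.6 / 3.7 / 4.8 / 5.7 mmol/L; intervals are half-open [lower, upper), so a
value exactly on a bound joins the higher category (forced by the "<" upper
bounds; adopted symmetrically at the lower edge). The 3.7 bound is the
adapted low-risk treatment-goal cutoff (145 mg/dL) rather than the 3.4 mmol/L
guideline threshold. The category grid is overridable.

Continuous exposure effects use natural cubic splines. The display-oriented
association model places 3 interior knots at the exposure quartiles with
boundary knots at the winsorisation bounds (1.6, 8.5 mmol/L); HR curves are
reported relative to 2.6 mmol/L (HR ≡ 1 there) with delta-method CIs, inputs
clamped to the bounds. The *predictive* cause-specific models use restricted
cubic splines with 5 knots at the 5/27.5/50/72.5/95th percentiles (Harrell's
default) for non-HDL, BMI and systolic blood pressure: placing the outer
knots inside the data keeps the linear tails supported and the sparse-tail
predictions stable. The predictive model includes a sex × non-HDL
interaction (sex-specific spline coefficients; sex main effects live in the
strata).

## Synthetic cohort generator

Subject-level data from the pooled multinational cohorts are not public, so every stage runs on a
generator that emulates the pooled cohort's statistical structure:

* **Marginals** (defaults): baseline age truncated-normal (51, 13.5²) on
  [35, 75] (median ≈ 51–52, IQR ≈ 45–60); 48.7% women; non-HDL lognormal with
  median 4.3 and IQR ≈ 3.5–5.2 mmol/L; HDL lognormal median 1.3 (IQR
  1.1–1.6); the two joined by a Gaussian copula with correlation −0.2 (total
  cholesterol = non-HDL + HDL by construction); BMI ~ N(25.8, 4.2²); SBP ~
  N(132, 18²); prevalences: smoking 33.3%, diabetes 4.8%, hypertension 40.1%
  (anchored to SBP ≥ 140 and topped up at random), antihypertensive use 15%,
  lipid-lowering therapy 4.9%.
* **Events**: cause-specific Weibull hazards on the age scale with log-linear
  covariate effects; CVD shape 6, scale 110, per-mmol/L log-HR 0.20 (so the
  top-vs-bottom category adjusted HR is ≈ 2–2.3); non-CVD death shape 9,
  scale 94 (mortality accelerates faster with age than CVD). Covariates are
  centred at reference values (non-HDL 4.3, BMI 25.7, SBP 130). Event ages
  are drawn by inverse-transform sampling of the conditional two-cause
  survival given alive at the baseline age (vectorised bisection), and the
  cause is assigned with probability proportional to the cause-specific
  hazards at the event age.
* **Cohorts**: 8 cohorts with a shared normal log-hazard frailty
  (sd 0.2) on both causes — this is what justifies cohort-stratified fitting
  downstream.
* **Censoring**: administrative, uniform 3–38 years of follow-up. The
  resulting observed median follow-up is ≈ 15 years with ≈ 14% of subjects
  experiencing a CVD event; the window extends well past 30 years so that
  30-year cumulative incidences are estimated away from the censoring
  boundary.
* **Treatment bookkeeping**: treated subjects' hazards use their *true*
  non-HDL; their recorded value is deflated by exactly 1/1.3, so the
  downstream 30% inflation recovers the hazard-relevant concentration — this
  makes the inflation rule testable end to end.

What the generator deliberately does **not** emulate: country-specific rates
across dozens of real cohorts, case-cohort sampling designs, covariate
correlations with lipids (age, smoking etc. are independent of non-HDL), and
confounding-induced divergence between unadjusted incidence spreads and
adjusted hazard ratios. Consequently the unadjusted incidence ratio between
top and bottom category (~2–3×) is smaller than in real pooled cohorts
(~4×) even though the adjusted HRs match; passing tests demonstrate the
correctness of the estimators and the internal consistency of the pipeline,
not the real-world magnitudes.

## Risk cells and treatment benefit

Predicted probabilities of CVD by 75 are averaged within the 60 cells of
sex × baseline age group (<45, 45–59, ≥60, restricted to 35–70) × non-HDL
category × risk-factor burden. The burden counts daily smoking, hypertension
(the flag, not measured SBP), diabetes and obesity (BMI ≥ 30 kg/m²), split
0–1 vs ≥2. Cell CIs are percentile bootstrap over subjects (cohort-stratified
resampling, 500 replicates by default, seeded); predictions are held fixed
during the bootstrap, so the CI reflects cell-composition uncertainty.

The benefit model uses the duration-dependent expected proportional risk
reduction per mmol/L of cholesterol lowered,
r(t) = 1 − exp(−0.249 + (t − 5)(−0.0152)) (≈ 22% at 5 years, ≈ 51% at 35
years), with treatment assumed to run from baseline age to the age-75 horizon
(t = 75 − a₀). Per-mmol/L effects compound multiplicatively on the
probability scale: RR = (1 − r(t))^Δ with Δ = fraction × baseline non-HDL,
and p₁ = p₀·RR. The compounding (rather than additive, 1 − rΔ) form is
required for coherent behaviour at large Δ — additive scaling turns negative
for Δ ≳ 2 mmol/L at long durations — and makes the relative risk reduction
independent of p₀ given age, non-HDL and fraction, which matches the
near-constant RRR across sexes within a cell. From percent-scale cell
averages: RD = p₀ − p₁, NNT = 100/RD (∞ when RD = 0), RRR = RD/p₀; NNT is
reported to one decimal, RRR to two. Treated cumulative-incidence curves
apply RR(u − a₀) pointwise and are replaced by their running maximum, since
the growing r(t) can otherwise produce a decreasing — hence invalid — CIF.

## Validation

The derivation/validation split halves each cohort at random (seeded;
singleton cohorts go to derivation with a warning), so every cohort
contributes to both halves. The full model pipeline is rerun independently
per half and agreement is the RMSE over the shared non-empty cells of the
two 60-cell tables, in percentage points. A leave-one-group-out variant
generalises this to country/cohort-specific RMSEs and degenerates to the
plain split for a single group.

Discrimination: Harrell's concordance of the predicted cause-1 CIF at
baseline age + timeframe, with competing events treated as non-events
censored at their event time and pairs truncated at the timeframe; ten-fold
cross-validation with per-fold refitting, folds seeded; default timeframes
10/20/30 years (a package choice, not an external constraint).

Calibration: jackknife pseudo-values PVᵢ = n·F̂(t) − (n−1)·F̂₍₋ᵢ₎(t) of the
Aalen–Johansen CIF (exact leave-one-out, grouped by identical (time, cause)
pairs; their mean equals F̂(t) to machine precision, and without censoring or
competing events they reduce to 0/1 event indicators) are regressed on
predicted risk with a lowess smoother, span 0.75, evaluated on a 100-point
grid. Robustness iterations are disabled: pseudo-values are two-point-like
and robust reweighting would treat the event cluster as outliers, flattening
the curve. Pseudo-values require n ≥ 50.

## Numerical and convention choices

* Ties between an event and a censoring at the same time: the event comes
  first (censored subjects remain in that risk set).
* Gray's test uses the subdistribution risk set
  R_k(t) = Y_k(t)(1 − F̂₁k(t⁻))/Ŝ_k(t⁻) per group with a log-rank-type
  covariance (multiplicity-corrected); the statistic is referred to
  χ²(K − 1). The variance estimator is simpler than the full asymptotic
  form; simulation shows nominal type-I error, and the statistic agrees with
  the reference R implementation within a few percent on test fixtures.
* Weibull baseline fits: Nelder–Mead on (log k, log λ), initialised at
  k = 5 and λ = 1.3 × mean exit age; strata with fewer than 25 events of a
  cause fall back to a pooled-sex baseline within the cohort.
* Cox fits: lifelines `CoxPHFitter` with `entry_col` (left truncation),
  strata = (sex, cohort), Efron ties; strata with zero events are dropped
  with a warning.
* Probabilities are carried as proportions internally and formatted as
  percent only in the cell tables and reports.

## Problem sizes in tests

The acceptance-style checks run the split-agreement pipeline at n = 100 000
(the scaled-down stand-in for the pooled multi-cohort study), parameter recovery at
n = 100 000 × 10 seeds, Gray's test calibration at n = 2 000 × 50 replicates,
and Monte-Carlo oracles at 10⁶ draws — sizes chosen to keep the whole suite
in the tens of minutes on one CPU while leaving Monte-Carlo error well below
the asserted tolerances. At these sizes the split RMSE fluctuates around
0.7–1.0 percentage points across seeds; at the full pooled-study scale
(~200 000 per half) the same model halves that noise, which is what the
sub-1% agreement claim reflects.

## Known limitations

* Generator covariates are mutually independent (except hypertension/SBP and
  the lipid copula); real confounding structures are not represented.
* The benefit equation extrapolates a meta-analytic LDL relation to non-HDL
  and to multi-decade durations; adherence and real-world attenuation are
  out of scope.
* The alternative reading of the benefit computation — re-plugging the
  reduced non-HDL into the Cox model rather than scaling probabilities by
  the compounded RR — is not implemented; the RR-scaling form is the one
  consistent with the published worked cells.
* LDL cholesterol is carried through the tables and the category grid is
  configurable, but no LDL-specific outputs are produced.
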
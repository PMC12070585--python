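# Methods

This note documents the models implemented in `portfoliodiet`, the default
parameters and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that affect results.

## Portfolio Diet Score

The score grades adherence to the Portfolio dietary pattern from the
within-sample distribution of six component intakes: sources of plant
protein, viscous fibre, nuts, phytosterols and MUFAs (favourable), and
saturated fat/cholesterol sources (unfavourable). Intakes are servings/day,
except phytosterols in mg/day. Each component is binned by population
quintile — the 20/40/60/80th sample percentiles — earning 1–5 points,
reversed (6 − q) for the unfavourable component; the six points sum to a
total in [6, 30].

Numerical conventions, each of which can change individual scores:

* **Quantile definition.** Type-7 (linear interpolation), the numpy/R
  default, fixed for reproducibility since quintile boundaries from finite
  samples differ across definitions.
* **Boundary ties.** Intervals are half-open, `(b_{k-1}, b_k]`: an intake
  exactly at a boundary falls in the *lower* quintile. An "upper" mode is
  available (`ties="upper"`).
* **Zero inflation.** Many participants consume no nuts, soy or added MUFA
  sources. When ≥20% of intakes are zero, two or more quintile boundaries
  coincide at 0 and all such consumers receive 1 point (5 for the reverse
  component); upper quintiles may then hold more or fewer than n/5. This is
  the deliberate consequence of half-open binning and is exercised heavily in
  the tests.
* **Tertiles.** T1/T2/T3 boundaries are the 33.3/66.7th percentiles of the
  realised integer scores (same tie rule), not fixed cuts; per-tertile median
  scores feed the trend test.

Cutpoints serialise to a JSON sidecar so scores are exactly reproducible on
new data ("frozen cutpoints" mode) or re-estimated from the analysis sample
("population mode", the default).

## Derived biomarkers and exclusions

LDL-C is estimated from the fasting panel (TC, HDL-C, TG, all mmol/L) with
three equations, each evaluated on its native mg/dL scale (factors 38.67 for
cholesterol, 88.57 for TG, 18.018 for glucose) and reported in mmol/L:

* **Sampson–NIH** (primary):
  `LDL = TC/0.948 − HDL/0.971 − (TG/8.56 + TG·nonHDL/2140 − TG²/16100) − 9.44`.
* **Martin/Hopkins**: `LDL = nonHDL − TG/f`, with `f` looked up in the
  packaged 180-cell table stratified by TG (30 rows) and non-HDL (6 columns);
  TG outside the tabulated range clamps to the boundary stratum with a
  warning.
* **Vujovic**: `LDL = TC − HDL − TG/6.85`.

Negative estimates are replaced by the minimum positive value computed in the
sample — applied per equation, since the replacement rule's scope across
sensitivity equations is otherwise ambiguous; the choice is logged. Body fat
% uses the Deurenberg adult form `1.20·BMI + 0.23·age − 10.8·male − 5.4`,
and FMI = fat mass / height², which is ≤ BMI by construction.

Exclusions run in a fixed cascade — implausible energy (strictly >3500
kcal/day for females, >4500 for males, <800 for either; boundary values
retained), incomplete diet data, missing covariates, then per-outcome missing
data — and each record is counted once, under the first reason that applies.
The ledger conserves counts (retained + excluded = input) and the order is
documented because the per-reason counts depend on it. Outcome-specific
missingness does not remove a record from the retained table; models are
complete-case per outcome.

## Association models

All fits are ordinary least squares (statsmodels/patsy behind the module
surface; every fixture is cross-checked against a direct normal-equations
solve in the tests). The standard covariate set is sex, age, education
(4 levels), ethnicity (4 groups), BMI, family history of CVD and of diabetes,
hypertension and hypercholesterolemia status, energy intake, smoking,
physical activity and alcohol — with BMI dropped whenever the outcome is
itself an adiposity marker, and alcohol entered square-root transformed
(zero-heavy, so log is undefined). Triglycerides, CRP and the adiposity
outcomes are log-transformed before fitting; which variables transform is
configurable per model.

* **Continuous effects** are reported per 1 point, with the per-8-point
  effect an exact ×8 rescaling of the slope and CI (8 points ≈ the
  inter-tertile span of the score).
* **Marginal means** at each tertile are population-averaged: the tertile
  indicator model's prediction for every analysis-sample row with tertile
  forced to T, averaged; CIs are delta-method on the linear predictor. This
  averages over the observed covariate distribution rather than fixing
  covariates at their means; the alternative is noted in output metadata.
  Whether these CIs should also carry covariate-estimation uncertainty is an
  open modelling question; the delta-method default is recorded with results.
* **Trend tests** assign each participant their tertile's median score as a
  continuous regressor; the trend p-value is that coefficient's two-sided
  t-test, taken from the transformed-outcome fit.
* **Back-transformation** for log outcomes reports `(e^β − 1) × mean` — the
  proportional difference anchored at the untransformed sample mean — with
  marginal means computed on the raw scale; sqrt outcomes use the
  delta-method analogue `2·√mean·β`.
* **Interactions** (sex, ethnicity, BMI <25 / ≥25) are joint F-tests of the
  exposure × subgroup product terms against the additive model, with
  per-stratum slopes from stratified fits.
* **Component models** regress each outcome on one component's servings/day
  (phytosterols: mg/day ÷ 25) with the same covariates. No multiple-testing
  adjustment anywhere (significance at p < 0.05), and no multicollinearity
  handling for the composite score, by design.

Rank-deficient designs raise an error naming the aliased columns (QR with
column pivoting) rather than silently dropping them.

## Cumulative LDL-C exposure model

Absolute adherence divides each pillar's gram/day intake by its
recommendation (50 g plant protein, 20 g viscous fibre, 45 g nuts, 2 g
phytosterols, 45 g MUFAs); overall adherence is the unrounded mean of the
five fractions, reported as a whole percent, and the clinical score is
c-PDS = round(25 × overall fraction), clamped to [0, 25]. Rounding is half
away from zero throughout. Per-pillar adherence is not capped at 100% by
default (young cohorts rarely exceed recommendations); a cap is available.

LDL-C at an arbitrary adherence level is a straight line through two
(adherence %, LDL-C) anchors — by convention the lowest and highest score
tertiles' overall adherence and unadjusted marginal mean LDL-C — extrapolated
beyond them. The two-anchor endpoint fit is the default; a least-squares fit
through all three tertiles is nearly identical at interpolated levels but
differs in the second decimal at 100% adherence. Note the extrapolation is
sensitive to the anchor spread: anchors only a few percentage points apart
(as in a low-adherence cohort scored on its own distribution) produce steep,
unreliable projections at 50–100% adherence.

Cumulative exposure assumes the LDL-C level is constant over life, so
exposure at age a is `LDL × a` (mmol/L·years, linear through the origin), and
risk onset is the age where exposure crosses a plaque-burden threshold,
rounded to the nearest year. The default threshold is **5,000 mg/dL·years =
129.30 mmol/L·years** (the cumulative-exposure framework's native figure),
not the commonly quoted round 125 mmol/L·years: a brute check shows
nearest-year onset ages for LDL-C 2.34/2.29/2.24/2.13/1.89 mmol/L are
55/56/58/61/68 under 5,000 mg/dL·years but 53/55/56/59/66 under a literal
125. Both are available (`threshold=`); floor rounding is not used because it
is inconsistent with the nearest-year convention at 2.29 mmol/L. The model
deliberately excludes age-varying LDL-C trajectories and any plaque biology
beyond the linear proxy.

## Synthetic cohort generator

The generator emulates the marginal structure of a young, ethnoculturally
diverse cohort: default n=1,507; age ~ N(23, 3²) truncated at 18; 68% female;
ethnicity Caucasian/East Asian/South Asian/other at 0.48/0.34/0.11/0.07
(normalised from printed percentages that sum to 101); education, smoking
(5% current), PAL ~ U[1.2, 2.2], alcohol (30% abstainers, log-normal
otherwise) and comorbidity prevalences (hypertension 1%, high cholesterol 3%,
family CVD 2%, family diabetes 13%) as plausible fillers at typical cohort
frequencies.

Component intakes are zero-inflated log-normal — medians 0.25/1.0/0.4
servings/day for plant protein/viscous fibre/nuts with 25/2/30% zero
consumers, 250 mg/day phytosterols, 0.25 servings MUFAs (30% zeros), 2.0
servings saturated-fat sources — calibrated so that pillar gram intakes give
overall absolute adherence in the single-digit-to-low-tens percent range
characteristic of free-living young adults, and so that quintile scoring is
stressed by heavy ties at zero. Within-person component independence is the
default (an explicit correlation structure was considered and left out: no
empirical target exists for it); note this understates the between-component
clustering real FFQ data show.

Outcomes are generated **two-pass**: intakes are drawn, the cohort is scored,
and each outcome is then `baseline + slope·(PDS − mean PDS) + covariate
effects + N(0, σ)` on its analysis scale (log for TG, CRP, BMI), with the
female indicator and age centred so configured baselines stay the marginal
means. The true score-outcome slope is therefore exactly the configured
value; defaults plant slopes of the magnitude reported for this design
(LDL-C −0.009 mmol/L per point with residual SD 0.7, SBP −0.150, DBP −0.133
mmHg, etc.). Because LDL-C is derived, not stored, the generator draws the
target LDL-C and inverts the Sampson–NIH equation (linear in TC given HDL and
TG) for total cholesterol — so the planted LDL slope is recovered exactly
when LDL-C is re-derived, while TC and non-HDL slopes are induced by the
construction. Energy intake is positively linked to the score (60 kcal/day
per point) to mimic the confounding structure of diet-quality scores.

What passing tests on this cohort do **not** show: robustness to FFQ
measurement error, non-Gaussian residuals, outcome-dependent missingness,
within-person intake correlation, or selection effects — none of which the
generator produces. Parameter-recovery results show only that the estimators
are unbiased under the generator's assumptions.

## Problem sizes and reproducibility

Tests use cohorts of 250–6,000 rows; the headline checks run 200 replicates
at n=1,490 for slope recovery and 2,000 permutation replicates (n=300–400)
for the 5% type-I-error calibration of the trend and interaction tests,
judged against ±3 binomial standard errors. All randomness flows from
explicit seeds; the pipeline derives per-stage substreams from one root seed
(SHA-256 of the stage name into a `SeedSequence`), so a rerun with the same
config and seed is byte-identical, and any stage can be replayed from its
serialized inputs.
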
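# Methods

## The problem

In annual low-dose CT (LDCT) lung screening, roughly a quarter of screens show
a nodule that turns out not to be cancer within the year ("abnormal presumed
nonmalignant" screens). Many of these people are at low enough risk that a
2-year screening interval would be safe, cheaper, and less harmful. This
package implements the analysis chain needed to evaluate such a policy at the
level of individual screens:

1. **Recalibration.** A nodule malignancy score from an image model (a
   probability of *current* malignancy) is recalibrated into 1-year
   screen-detected cancer risk by logistic regression.
2. **Validation.** Discrimination (Mann-Whitney AUC, with bootstrap optimism
   adjustment for models refit to the data; DeLong's test for comparing
   correlated AUCs) and mean calibration (expected/observed case ratio with a
   lognormal CI).
3. **Decision analysis.** Screens below a risk threshold are assigned a
   biennial interval; the harms are counted as cancers whose diagnosis would
   have been delayed one year, summarized as an absolute risk among the
   assigned and as a tradeoff curve, with the Lung-RADS guideline categories
   as comparator.

The unit of analysis is the *screen* (a person can contribute a baseline T0
and a year-1 T1 screen); the outcome is the binary flag "cancer detected as a
result of the next annual screen". The image score of a screen is the maximum
over its nodules; both facts are properties of the input data, not of this
package.

## Recalibration model

Let `s` be the image malignancy score of a screen. The default model is

    logit P(Y = 1 | s) = alpha + logit(s),

an intercept-only ("single parameter") logistic shift on the log-odds scale:
the image score ranks screens well but overstates 1-year risk, so only its
level is moved. A free-slope variant `alpha + beta*logit(s)` is available,
and a combined model enters both the prescreening 1-year risk `r` and the
score as log-odds:

    logit P(Y = 1 | r, s) = c0 + c1*logit(r) + c2*logit(s).

All fits are maximum likelihood via iteratively reweighted least squares
(statsmodels GLM, binomial family; the fixed slope is imposed through an
offset). We require the score equations to hold to 1e-8 (scaled by n) at the
reported optimum; a useful consequence of the intercept's score equation is
that the training-data sum of predicted risks equals the observed case count
exactly, so the apparent E/O ratio of a fitted model is 1 by construction —
honest calibration assessment therefore uses *out-of-fold* risks.

Probabilities exactly 0 or 1 are rejected at the data boundary rather than
clipped, since the model operates on log-odds. Complete separation (possible
with a free slope on small data) raises an error advising the fixed-slope
model; it cannot occur with the slope fixed.

### Cross-validation

Out-of-fold risks use k-fold cross-validation (default k = 8): each screen is
scored by the model fitted with its fold held out. Folds are balanced (sizes
differ by at most one unit) and are assigned on a canonical ordering — records
sorted by (person id, round), then permuted by a seeded RNG — so the
assignment is a function of the records, not of their order in the file. The
default unit is the screen; a person-level unit is available for those who
want to keep a person's two screens in the same fold.

## Validation metrics

* **AUC** is the Mann-Whitney statistic (ties counted half), the probability
  that a random case outranks a random noncase.
* **Optimism adjustment** follows Harrell's bootstrap: for each resample with
  replacement at the screen level, refit, and record the difference between
  the refit model's AUC on the resample and on the original cohort; the
  adjusted AUC subtracts the mean difference from the apparent AUC. Default
  200 resamples; one-class resamples are redrawn and logged. For the one- and
  three-parameter models here the optimism is tiny (measured below 0.005 at
  n = 10,000 in the tests) — the adjustment matters in principle because the
  models are refit to the analysis data.
* **AUC comparison** uses DeLong's variance estimate for two correlated ROC
  curves (implemented here with midrank structural components; cross-checked
  against pROC's `roc.test` in the test suite). When two risk vectors are
  monotone transforms of each other the variance of the difference is zero
  and the p-value is defined as 1.
* **Calibration** is E/O = (sum of predicted risks)/(observed cases), with
  95% CI `ratio * exp(+-1.96/sqrt(O))` — a lognormal interval with Poisson
  variance on the observed count. This formula reproduces all published
  intervals of the study this analysis follows, given their printed E and O.

## Decision analysis

Given risks and outcomes for n screens:

* `assign_by_fraction(f)` assigns the `round(f*n)` lowest-risk screens
  (nearest-integer, half away from zero — this rounding uniquely reproduces
  the published 7,148/8,665/9,748 assigned of 10,831 at 66/80/90%). Ties in
  risk break by stable input order; with continuous model risks ties have
  measure zero.
* `fraction_assigned_at_delay(d)` finds the largest rank threshold that
  delays at most a fraction `d` of cancers.
* `tradeoff_curve` sweeps all n+1 rank thresholds and reports, per threshold,
  the percent of *noncases* assigned biennial against the percent of cancers
  delayed. Noncases as denominator matches the published figure convention
  (66.1% = 7,026/10,636); the count of all screens assigned is carried
  alongside.
* `assign_by_lungrads` is the guideline comparator: nested thresholds
  "category <= X" over the seven Lung-RADS labels, with grouped labels
  (e.g. "3 or 4A") kept atomic and ordered 2 < 3 < 3|4A < 3|4A|4B < 4A <
  4A|4B < 4B. This nested order exactly reproduces the published cumulative
  counts.
* `stratify` applies the *overall* cohort threshold within nodule-size (or
  Lung-RADS) strata — deliberately not a per-stratum threshold — so stratum
  counts sum to the overall counts.
* Sensitivity restrictions: one randomly chosen screen per person
  (seeded), and screens with Lung-RADS exactly 2.

Report formatting follows the published tables: percentages to 1 decimal,
absolute risks to 2.

## Synthetic cohort generator

Real screen-level data with image-model scores are access-restricted, so the
package carries a generator that reproduces the statistical structure the
analysis relies on, plus one exact fixture.

**Binormal latent model.** Outcomes are Bernoulli(prevalence), default 0.018.
Given the outcome, the log-odds of each score are normal with unit variance;
the case-noncase mean separation is `delta = sigma*sqrt(2)*PhiInv(AUC)`, which
gives closed-form control of the AUC (`AUC = Phi(delta/(sigma*sqrt(2)))`) and
hence an analytic oracle for every discrimination test. Defaults: image score
AUC 0.87, comparator risk 0.79, prescreening risk 0.70. The three latents
share pairwise correlation rho (default 0.3; the true joint distribution of
prescreening risk and image score is not published, so this is a documented
free choice). Baselines: the image score's noncase median is ~0.10 (a
malignancy probability), the prescreening risk's ~0.005 (deliberately *not*
calibrated to the 1.8% outcome prevalence — risk after an abnormal screen
runs several-fold above prescreening risk); the comparator's baseline is
solved at generation time (Gauss-Hermite quadrature + root finding) so its
mean risk equals the prevalence, emulating an externally calibrated model.

Size class and Lung-RADS category are drawn from outcome-conditional
categorical distributions whose defaults are the published cohort's marginal
proportions. By default they are *not* coupled to the scores (only the
outcome-conditional marginals are published); an option reassigns categories
within each outcome arm by sorting on the latent image score when a coupled
structure is wanted. Person structure: each person contributes both T0 and T1
with probability 0.445 (matching 10,831 screens from 7,495 people), else one
screen with a random round.

**What the generator does not emulate:** nodule growth or any longitudinal
dependence between a person's two screens (scores and outcomes are drawn
independently per screen); the empirical, non-normal shape of real score
distributions (particularly their spikes near 0); informative missingness;
Lung-RADS/score coupling by default. Consequently, tests passing on synthetic
cohorts demonstrate the *correctness of the machinery* (fits, metrics,
assignment logic) under known truth — not the clinical performance of any
model on real screens. Tradeoff-curve shapes in particular are smoother than
the published ones.

**Exact fixture.** `table1_fixture()` expands the published Lung-RADS x
outcome counts into 10,831 records (195 cancers) with placeholder mid-range
scores. Every quantity of the guideline-comparator analysis is a deterministic
function of these counts, and the package reproduces the published table to
its printed precision (one cell, 95.5% vs a printed 95.6%, differs because
10,162/10,636 = 95.54%).

**Parameter recovery.** `generate_shifted_score_cohort` draws scores with
log-odds Normal(-2, 1.5^2) and outcomes truly following an injected intercept
shift, so the recalibration's estimand is known exactly; the test suite
checks 95% CI coverage of the shift across 100 replicates at n = 20,000.

## Numerical choices

* GLM convergence: IRLS with tolerance 1e-12, score equations verified to
  1e-8 (scaled); divergent or separated fits raise rather than return.
* The E/O interval uses the conventional 1.96 normal quantile, matching the
  published intervals.
* Bootstrap resampling is at the screen level, ignoring within-person
  clustering, matching the screen-level analysis; duplicated records in a
  resample receive fresh ids so each resample is a valid cohort.
* Half-up rounding for assignment counts (see above); numpy stable argsort
  for all rank operations.
* Empty strata and empty assignments produce flagged zero/NaN rows, not
  errors; an empty cohort is only permitted as the (flagged) output of the
  Lung-RADS-2 restriction.

## Problem sizes

The shipped analyses use cohorts of 10,831 screens (the published cohort
size) for the drivers, 100,000 screens for empirical-AUC and
goodness-of-fit checks (binomial/Mann-Whitney noise well inside the +-0.02
assertions), 20,000 x 100 replicates for CI coverage, and 200 bootstrap
resamples for optimism. These sizes were chosen so each check's Monte-Carlo
error is small relative to its tolerance.

## Known limitations

* The recalibration transfers only the score's level; if the image score's
  slope on the log-odds scale is wrong, the fixed-slope model cannot correct
  it (the free-slope option can, at the cost of one more parameter).
* The generator's equal-variance binormal latents make every ROC curve
  "proper"; real image scores need not behave this way.
* P-values for differences in absolute delayed-diagnosis risk between
  policies are not implemented; the published analysis does not state its
  test, and a paired bootstrap over screens (sketched in the tests'
  machinery) is not claimed to match it.
* The calibration z statistic is reported, but the package does not attempt
  to reproduce the published "all P > .77" calibration p-values, whose test
  statistic is not derivable from the published numbers.
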
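# Methods

## The validation problem

The EPOS independent-gait model is a pair of frozen logistic equations
predicting, from two dichotomized bedside tests early after stroke, whether
a patient will walk independently (FAC ≥ 4) three months later.  External
validation evaluates those equations — coefficients untouched — on an
independent cohort and reports discrimination, classification and
calibration.  This package implements that protocol end to end, plus a
synthetic-cohort generator so the pipeline can be exercised and tested
without access to patient-level data.

## Pipeline

1. **Eligibility.** Patients who died before the day-90 visit are excluded,
   as are patients already walking independently at the baseline visit
   (baseline FAC ≥ 4).  The baseline FAC used for eligibility is the visit-1
   measurement.  Every exclusion is logged with its reason.
2. **Imputation.** Missing raw scores are multiply imputed by chained
   equations (below).  After imputation, rows whose *outcome* was missing in
   the raw data are dropped from every completed dataset: imputed outcomes
   stabilize the conditional models during the sweep but carry no
   information for validation.
3. **Prediction.** The day-2 model is scored from visit-1 measurements, the
   day-9 model from visit 2.  Raw scores are dichotomized (TCT-s = 25;
   MI-LE ≥ 25) *after* completion, because the imputation operates on the
   raw scales.  Classification uses a configurable threshold, default 0.5 —
   the convention of the standard confusion-matrix report; no alternative
   operating point is published for this score.
4. **Metrics** per completed dataset (below), then **pooling** across the m
   datasets.

## Chained-equations imputation

* Variables and sweep order: raw TCT-s (visits 1, 2), raw MI-LE (visits 1,
  2), 90-day FAC, NIHSS total; complete auxiliaries in every conditional
  model: age, sex, affected side, NIHSS consciousness and hemianopia items.
* Numeric scores use predictive mean matching (PMM): an OLS fit on the
  observed rows, then each missing cell borrows the observed value of one of
  the k = 5 donors whose predicted means are nearest the missing row's
  predicted mean (uniform draw among donors; ties broken by row order for
  determinism).  k = 5 is the de-facto standard donor pool.  PMM guarantees
  imputed values live on the observed support — integer scale scores stay
  integer scale scores.
* Binary variables (none in the default protocol, available for foreign
  tables) use a logistic draw from the fitted conditional probability.
* Initial fill: a seeded random draw from each variable's observed values.
  Constant predictors are dropped from a conditional model with a logged
  warning.  A 100%-missing variable is an error (no donors).
* Defaults m = 100 imputations, 5 iterations — the protocol's stated values.
  A per-variable/iteration trace of imputed-value means supports convergence
  inspection; with 1–4 missing cells per variable convergence is immediate.
* Reproducibility: one seed spawns independent child generators per
  imputation, so results are identical for identical (table, spec, seed) and
  independent of m ordering.

## Metrics

* **Confusion-matrix report.** Accuracy with exact Clopper–Pearson 95% CI;
  sensitivity, specificity, PPV, NPV as plain ratios, reported as undefined
  (rendered "N/R") when a denominator is zero — never coerced to 0.  The
  no-information rate (NIR) is the majority-class prevalence; accuracy > NIR
  is tested with the exact upper binomial tail P(X ≥ tp+tn | n, NIR).  The
  NIR enters the tail at full precision, not at its printed rounding — at
  these sample sizes the third decimal of the p-value is sensitive to that.
* **Discrimination.** AUC as the Mann–Whitney two-sample statistic with half
  credit for ties — with at most four distinct predicted probabilities, tied
  pairs dominate and trapezoidal shortcuts that ignore ties are wrong.  The
  95% CI uses DeLong's variance estimator with a normal approximation,
  clipped to [0, 1].  The ROC staircase is built over the distinct predicted
  probabilities with thresholds descending from above the maximum (nobody
  positive, the (0,0) corner) to the minimum (everybody positive, (1,1));
  its trapezoidal area equals the Mann–Whitney AUC exactly, which the tests
  assert to 1e−12.
* **Calibration.** One point per distinct predicted probability: the group's
  observed event fraction with a 95% Wilson score interval.  Wilson is the
  standard choice for small groups (the exact interval over-covers; the Wald
  interval degenerates at 0/1).  Calibration is exported as point data
  rather than a rendered figure so it can be tested bit-stably.

## Pooling across imputations

Proportion-scale point estimates (accuracy, sensitivity, specificity, PPV,
NPV, AUC) are pooled as means on the logit scale and back-transformed, with
estimates clipped to [0.5/n, 1 − 0.5/n] before the transform.  Interval
estimates for accuracy and AUC use Rubin's rules on the logit scale: total
variance T = mean within-imputation variance + (1 + 1/m) × between-imputation
variance, where the within components come from the binomial delta method
(accuracy) and the DeLong variance (AUC).  With a single dataset (complete
data, or raw mode) the exact single-dataset intervals are kept.  A plain
averaging rule is switchable to bound the influence of this choice; with the
cohorts' tiny missingness the two agree to about 1e−3.  Metrics undefined in
some imputations are pooled over the imputations where they are defined,
with the contributing count recorded.  The pooled NIR-test p-value is the
exact tail at the pooled correct count; the pooled ROC curve averages the
per-imputation staircases at the shared thresholds (the attainable
probabilities are fixed by the model), and pooled calibration uses mean
group compositions.

## Synthetic cohorts

The generator emulates the two validation cohorts' published case-mix; its
defaults are those published summaries, not tuning knobs.

* The visit-1 (tct, mi) pattern is drawn from a joint Bernoulli pair with
  the published marginal prevalences (cohort 1: 43.6% / 71.8%; cohort 2:
  60.3% / 76.9%) coupled by a Plackett odds ratio, default 4 — the joint
  dependence is unpublished; sitting balance and leg strength are clearly
  positively associated, and none of the acceptance checks depend on the
  value.
* Visit-2 patterns allow upward transitions only (early neurological
  improvement); each absent component recovers with probability 0.30,
  chosen so roughly 27–30% of initially gait-dependent patients reach the
  strongly gait-predictive patterns by the second visit, matching the
  published early-change description.
* Outcomes are *model-faithful* by default: the event probability is the
  day-9 equation evaluated on the visit-2 pattern, making that model
  perfectly calibrated by construction and landing the simulated outcome
  prevalence near the published 71.8% / 74.4%.  Custom per-pattern
  probabilities are supported for miscalibration experiments.
* Raw scores are drawn consistently with the pattern (TCT-s = 25 exactly
  when balance is present, else uniform 0–24; MI-LE uniform 25–100 when
  strength is present, else uniform 0–24), so dichotomization recovers the
  sampled pattern exactly.
* Age and NIHSS come from log-normal distributions moment-matched to the
  published median and quartiles (strictly positive, right-skewed; the true
  family is unpublished and immaterial to any check).  The NIHSS
  consciousness and hemianopia items are drawn with severity-linked rates;
  they act only as imputation-model covariates.
* Missingness is MCAR with the *exact published cell counts* (cohort 1:
  2, 1, 3 cells in TCT-s v1, MI-LE v1, MI-LE v2; cohort 2: 4 + 4 at
  visit 2), masked among analyzable patients.  Deaths and
  baseline-independent patients default to 0 in the presets — the published
  analysis sets already exclude them — and are generated only to exercise
  the eligibility filter.
* A truth table (latent pattern assignments and event probabilities) rides
  along with every generated cohort, enabling closed-form expectations: the
  population AUC of either model under a config is computed by enumerating
  the finitely many pattern states, and the empirical AUC at n = 10,000
  matches it within 0.01 in the tests.

**What the generator does not emulate:** within-patient correlation beyond
the pattern level (raw scores are uniform within their stratum), real
measurement error and retest effects, informative missingness, deaths
correlated with severity, and the true joint distribution of predictors with
age/NIHSS.  Passing tests therefore demonstrate the pipeline's correctness
and its behavior under the published case-mix — not the clinical performance
of the model on new patients.

## Numerical and design choices

* Quartiles use the median-unbiased estimator; the published summaries do
  not state an estimator, so the choice is documented rather than assumed.
* Probabilities are carried at full floating precision and rounded only at
  rendering (3 decimals; whole percents where percentages are quoted —
  which is why the both-present day-2 pattern computes as 0.978 yet is
  commonly quoted, truncated, as 97%).
* Classification ties (probability exactly at threshold) go to the positive
  class.
* Model coefficients live in a plain-text JSON file and are echoed
  bit-exactly in reports; any two-predictor logit score in the same format
  can be validated with the same pipeline.
* Test and acceptance runs use scaled problem sizes — m = 5–10 imputations
  and 20-seed Monte-Carlo averages — which is ample for the 1–4 missing
  cells per variable these protocols encounter; the library defaults remain
  m = 100 × 5 iterations.

## Known limitations

* The day-5 model cannot be validated (its coefficients are not bundled);
  requesting it is an explicit error.
* DeLong's normal-approximation CI is anticonservative when the AUC is near
  1 at small n; the interval is clipped to [0, 1] rather than transformed.
* The chained-equations implementation targets this protocol: no passive
  imputation, no custom predictor matrices beyond the include/exclude lists.
* Published AUCs of the real cohorts are not reproducible from synthetic
  data — the generator matches the case-mix, not the patients — so AUC
  checks are property-based (closed-form enumeration, brute-force pair
  counting) rather than numeric targets.
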
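# eposgait

External validation pipeline for the **EPOS** (Early Prediction of functional
Outcome after Stroke) model for independent gait — a frozen two-predictor
logistic risk score used at the bedside in the first days after stroke to
predict whether a patient will walk independently again.

## Who this is for

Clinical researchers validating (or re-validating) the EPOS gait model — or
any other fixed-coefficient two-predictor logit score — on a new cohort, and
methodologists who need a tested reference pipeline for external validation
of a binary clinical prediction model: multiple imputation, discrimination,
classification, calibration, and pooling across imputations.

## The model

A patient is scored on two dichotomized bedside tests:

* **TCT-s** — sitting-balance item of the Trunk Control Test (0–25);
  coded `1` iff the score is exactly 25 (able to sit unsupported for 30 s);
* **MI-LE** — Motricity Index lower-extremity subscale (0–100);
  coded `1` iff the score is ≥ 25 (some strength in the paretic leg).

The probability of independent gait (Functional Ambulation Categories,
FAC ≥ 4) three months post-stroke is

```
day-2 model:  P = 1 / (1 + exp(−(−0.982 + 2.691·TCT + 2.083·MI)))
day-9 model:  P = 1 / (1 + exp(−(−2.226 + 3.629·TCT + 1.854·MI)))
```

The coefficients are frozen — external validation never re-estimates them.
Each model emits at most four distinct probabilities, one per predictor
pattern, which shapes every metric downstream (heavy ties in the ROC, exact
groups in the calibration plot).

The pipeline reproduces the full validation protocol: eligibility filtering
(deaths before day 90; independent gait already at baseline), chained-equations
multiple imputation of missing raw scores (predictive mean matching, m = 100
imputations × 5 iterations by default), prediction and classification,
discrimination (Mann–Whitney AUC with a DeLong 95% CI), the confusion-matrix
report (accuracy with exact Clopper–Pearson CI, sensitivity, specificity,
PPV, NPV, no-information rate and its exact binomial test), calibration
points with Wilson CIs, and pooling across imputations with Rubin's rules on
the logit scale.

Because the validation cohorts' patient-level data are not public, the
package ships a synthetic-cohort generator (`eposgait.synthetic`) that
emulates the published case-mix of both cohorts (pattern prevalences,
outcome prevalence, age/NIHSS summaries, the exact missing-cell counts), so
the entire pipeline is testable end to end.

## Worked example

```bash
eposgait simulate --preset cohort2 --seed 7 --out cohort2.csv
eposgait validate --cohort cohort2.csv --model day9 --m 100 --seed 7 --out val
```

prints (and writes to `val/table.txt`):

```
Cohort: cohort2.csv   Model: day9   N = 78   m = 100   threshold = 0.5
------------------------------------------------------------------------
Accuracy (95% CI)           0.896 (0.804, 0.948)
Sensitivity                 0.899
Specificity                 0.889
Positive predictive value   0.964
Negative predictive value   0.725
No information rate         0.769
P-Value (Acc > NIR)         0.003
AUC (95% CI)                0.925 (0.815, 0.972)
```

Reading the rows: accuracy 0.896 is the pooled fraction of correct
classifications at the 0.5 threshold, with a Rubin-pooled 95% CI; it beats
the no-information rate 0.769 (the accuracy of always predicting the
majority class — here "walks independently") with exact binomial p = 0.003;
the AUC of 0.925 means a randomly chosen walker is ranked above a randomly
chosen non-walker 93% of the time (ties counted half).  `val/` also contains
`report.json` (machine-readable), `roc.csv`, `calibration.csv`,
`exclusions.csv` and a provenance `config.yaml`.

The same analysis is available as a library:

```python
import eposgait as eg

records = eg.read_cohort("cohort2.csv")
analysis, excluded = eg.apply_eligibility(records)
report = eg.run_validation(eg.records_to_frame(analysis), "day9",
                           eg.ImputationSpec(m=100, seed=7))
print(eg.render_report(report))
```

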
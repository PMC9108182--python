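"""Discrimination, classification and calibration of a binary risk score.

Given predicted probabilities of independent gait and the observed 3-month
outcome, this module computes the standard external-validation report:

* a 2x2 confusion table and the classification metrics derived from it
  (accuracy with exact Clopper-Pearson CI, sensitivity, specificity, PPV,
  NPV), together with the no-information rate (NIR, the accuracy of always
  predicting the majority observed class) and the exact one-sided binomial
  test of accuracy > NIR;
* the ROC curve and its area (AUC) computed as the Mann-Whitney two-sample
  statistic with half credit for tied pairs — essential here, because an
  EPOS model emits at most four distinct probabilities — with the DeLong
  variance estimator for the 95% CI;
* calibration points: one per distinct predicted probability, pairing the
  prediction with the observed event fraction of its group and a Wilson
  score CI.

Ratios with a zero denominator are reported as ``None`` (undefined), never
coerced to 0; the report renderer prints them as "N/R".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "ClassificationReport",
    "RocResult",
    "CalibrationPoint",
    "confusion_table",
    "classification_report",
    "roc_auc",
    "calibration_points",
    "binomial_tail_exact",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Cross-classification of predicted vs observed gait independence."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def events(self) -> int:
        return self.tp + self.fn

    @property
    def nonevents(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassificationReport:
    """Table-style classification metrics for one confusion table.

    ``None`` marks an undefined ratio (zero denominator).
    """

    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    nir: float
    p_acc_gt_nir: float
    n: int


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong standard error, normal-approximation CI and curve."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame  # columns: threshold, fpr, tpr


@dataclass(frozen=True)
class CalibrationPoint:
    """Observed event fraction for one predicted-probability group."""

    predicted: float
    observed: float
    ci_low: float
    ci_high: float
    n_group: int


def confusion_table(
    predicted_classes: Sequence[int], observed_labels: Sequence[int]
) -> ConfusionTable:
    """Cross-tabulate predictions against outcomes (event = label 1)."""
    pred = np.asarray(predicted_classes, dtype=int)
    obs = np.asarray(observed_labels, dtype=int)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    if pred.size == 0:
        raise ValueError("cannot tabulate an empty cohort")
    if not (np.isin(pred, (0, 1)).all() and np.isin(obs, (0, 1)).all()):
        raise ValueError("entries must be binary 0/1")
    return ConfusionTable(
        tp=int(np.sum((pred == 1) & (obs == 1))),
        fp=int(np.sum((pred == 1) & (obs == 0))),
        fn=int(np.sum((pred == 0) & (obs == 1))),
        tn=int(np.sum((pred == 0) & (obs == 0))),
    )


def binomial_tail_exact(successes: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= successes) for X ~ Binomial(n, p0)."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(successes - 1, n, p0))


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def classification_report(ct: ConfusionTable) -> ClassificationReport:
    """Accuracy (with exact 95% CI), sens/spec/PPV/NPV, NIR and its test.

    The no-information rate is the prevalence of the majority observed
    class; the reported p-value is the exact one-sided binomial tail
    P(X >= tp+tn | n, NIR).
    """
    n = ct.n
    correct = ct.tp + ct.tn
    accuracy = correct / n
    ci_low, ci_high = proportion_confint(correct, n, alpha=0.05, method="beta")
    nir = max(ct.events, ct.nonevents) / n
    return ClassificationReport(
        accuracy=accuracy,
        accuracy_ci=(float(ci_low), float(ci_high)),
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn),
        specificity=_ratio(ct.tn, ct.tn + ct.fp),
        ppv=_ratio(ct.tp, ct.tp + ct.fp),
        npv=_ratio(ct.tn, ct.tn + ct.fn),
        nir=nir,
        p_acc_gt_nir=binomial_tail_exact(correct, n, nir),
        n=n,
    )


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # midrank formulation: ties between an event and a non-event count 1/2
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    n1, n0 = len(pos), len(neg)
    rank_sum_pos = ranks[:n1].sum()
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong's covariance estimator for a single AUC."""
    n1, n0 = len(pos), len(neg)
    # placement of each event among non-events and vice versa
    v10 = np.empty(n1)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n0
    v01 = np.empty(n0)
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / n1
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def _roc_points(
    probabilities: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """ROC staircase over the distinct predicted probabilities.

    Thresholds descend from above max(prob) (classifying nobody positive,
    the (0,0) corner) down to the smallest probability (everybody positive,
    the (1,1) corner).
    """
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    distinct = np.unique(probabilities)[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    tp = fp = 0
    for thr in distinct:
        at = probabilities == thr
        tp += int((labels[at] == 1).sum())
        fp += int((labels[at] == 0).sum())
        rows.append({"threshold": float(thr), "fpr": fp / n0, "tpr": tp / n1})
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def roc_auc(
    probabilities: Sequence[float], observed_labels: Sequence[int]
) -> RocResult:
    """AUC (Mann-Whitney, ties = 1/2) with DeLong 95% CI and the ROC curve.

    Requires at least one event and one non-event; otherwise the AUC is
    undefined and a ``ValueError`` is raised.
    """
    prob = np.asarray(probabilities, dtype=float)
    obs = np.asarray(observed_labels, dtype=int)
    if prob.shape != obs.shape or prob.size == 0:
        raise ValueError("probabilities and labels must be equal-length, nonempty")
    pos = prob[obs == 1]
    neg = prob[obs == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: need at least one event and one non-event")
    auc = _mann_whitney_auc(pos, neg)
    var = _delong_variance(pos, neg)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    return RocResult(
        auc=float(auc),
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        curve=_roc_points(prob, obs),
    )


def calibration_points(
    probabilities: Sequence[float], observed_labels: Sequence[int]
) -> list[CalibrationPoint]:
    """One calibration point per distinct predicted probability.

    Groups are the subjects sharing one predicted probability (at most four
    per EPOS model); ``observed`` is the group's event fraction with a 95%
    Wilson score interval.  Points are ordered by predicted probability.
    """
    prob = np.asarray(probabilities, dtype=float)
    obs = np.asarray(observed_labels, dtype=int)
    if prob.size == 0:
        raise ValueError("cannot calibrate an empty cohort")
    points = []
    for value in np.unique(prob):
        group = obs[prob == value]
        events = int(group.sum())
        n_group = int(len(group))
        ci_low, ci_high = proportion_confint(
            events, n_group, alpha=0.05, method="wilson"
        )
        points.append(
            CalibrationPoint(
                predicted=float(value),
                observed=events / n_group,
                ci_low=float(ci_low),
                ci_high=float(ci_high),
                n_group=n_group,
            )
        )
    return points
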
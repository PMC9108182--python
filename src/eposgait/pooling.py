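"""Run the whole validation per imputed dataset, pool, and render the report.

The primary analysis imputes missing raw scores (m completed datasets),
evaluates the frozen EPOS equation on each dataset, and pools the
per-imputation metrics.  Proportions (accuracy, sensitivity, ..., AUC) are
pooled as means on the logit scale and back-transformed; the accuracy and AUC
interval estimates combine within- and between-imputation variance with
Rubin's rules, also on the logit scale.  A plain-average pooling rule is
available as a cross-check — with the cohorts' tiny missingness the two agree
to about 1e-3.

A raw-data mode (complete cases, no imputation) mirrors the secondary
analysis; on a complete table the two modes coincide exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .imputation import (
    ImputationSpec,
    ImputedDatasetSet,
    default_spec,
    exclude_missing_outcome,
    impute,
)
from .metrics import (
    CalibrationPoint,
    ClassificationReport,
    ConfusionTable,
    RocResult,
    binomial_tail_exact,
    calibration_points,
    classification_report,
    confusion_table,
    roc_auc,
)
from .model import EposModelParams, load_model, predict_probabilities

__all__ = [
    "ValidationReport",
    "run_validation",
    "pool_metrics",
    "render_report",
    "render_json",
    "report_to_json",
]

_MODEL_VISIT_COLUMNS = {
    "day2": ("tct_s_v1", "mi_le_v1"),
    "day9": ("tct_s_v2", "mi_le_v2"),
}

_Z975 = 1.959963984540054


@dataclass
class ValidationReport:
    """Pooled validation results for one cohort x one model."""

    cohort_label: str
    model_label: str
    threshold: float
    n: int
    m_used: int
    pooling_rule: str
    classification: ClassificationReport
    roc: RocResult
    calibration: list[CalibrationPoint]
    undefined_counts: dict[str, int]
    spread: dict[str, float]
    per_imputation: pd.DataFrame


def _evaluate_dataset(
    frame: pd.DataFrame, params: EposModelParams, threshold: float
) -> dict:
    tct_col, mi_col = _MODEL_VISIT_COLUMNS[params.label]
    tct = (frame[tct_col].to_numpy(dtype=float) == 25).astype(int)
    mi = (frame[mi_col].to_numpy(dtype=float) >= 25).astype(int)
    outcome = (frame["fac_90"].to_numpy(dtype=float) >= 4).astype(int)
    prob = predict_probabilities(params, tct, mi)
    pred = (prob >= threshold).astype(int)
    ct = confusion_table(pred, outcome)
    return {
        "confusion": ct,
        "report": classification_report(ct),
        "roc": roc_auc(prob, outcome),
        "calibration": calibration_points(prob, outcome),
        "probabilities": prob,
        "outcome": outcome,
    }


def _clipped_logit(p: float, n: int) -> float:
    eps = 0.5 / n
    return float(logit(min(max(p, eps), 1.0 - eps)))


def _pool_proportion(values: list[Optional[float]], n: int, rule: str):
    """Logit-scale (or plain) mean over the imputations where defined."""
    defined = [v for v in values if v is not None]
    if not defined:
        return None, 0
    if rule == "mean":
        return float(np.mean(defined)), len(defined)
    return float(expit(np.mean([_clipped_logit(v, n) for v in defined]))), len(defined)


def _rubin_logit_ci(
    estimates: Sequence[float], within_var: Sequence[float], n: int, rule: str
) -> tuple[float, float, float, float]:
    """Rubin's rules on the logit scale: point, (lo, hi), total SE.

    ``within_var`` are the per-imputation sampling variances on the logit
    scale; the between-imputation component is the sample variance of the
    logit point estimates.
    """
    logits = np.array([_clipped_logit(e, n) for e in estimates])
    m = len(logits)
    w_bar = float(np.mean(within_var))
    b = float(np.var(logits, ddof=1)) if m > 1 else 0.0
    t = w_bar + (1.0 + 1.0 / m) * b
    center = float(np.mean(logits))
    if rule == "mean":
        point = float(np.mean(estimates))
    else:
        point = float(expit(center))
    half = _Z975 * math.sqrt(t)
    return point, float(expit(center - half)), float(expit(center + half)), math.sqrt(t)


def pool_metrics(
    per_dataset: list[dict], rule: str = "rubin"
) -> tuple[ClassificationReport, RocResult, dict[str, int], pd.DataFrame]:
    """Pool per-imputation classification and ROC results.

    Point estimates are means across imputations on the logit scale
    (back-transformed); accuracy and AUC intervals apply Rubin's rules
    combining the within-imputation variance (delta method on the logit
    scale) with the between-imputation variance of the logit estimates.
    Metrics undefined in some imputations are pooled over the imputations
    where they are defined, with the contributing count recorded.
    """
    if not per_dataset:
        raise ValueError("need at least one per-imputation result")
    if rule not in ("rubin", "mean"):
        raise ValueError(f"unknown pooling rule {rule!r}")
    reports = [d["report"] for d in per_dataset]
    rocs = [d["roc"] for d in per_dataset]
    n = reports[0].n
    m = len(reports)

    accs = [r.accuracy for r in reports]
    acc_within = [
        1.0 / (n * min(max(a, 0.5 / n), 1 - 0.5 / n)
               * (1.0 - min(max(a, 0.5 / n), 1 - 0.5 / n)))
        for a in accs
    ]
    acc_point, acc_lo, acc_hi, _ = _rubin_logit_ci(accs, acc_within, n, rule)
    if m == 1:
        # single dataset: keep the exact Clopper-Pearson interval
        acc_point = reports[0].accuracy
        acc_lo, acc_hi = reports[0].accuracy_ci

    undefined: dict[str, int] = {}
    pooled_simple: dict[str, Optional[float]] = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        values = [getattr(r, name) for r in reports]
        pooled, n_def = _pool_proportion(values, n, rule)
        pooled_simple[name] = pooled
        if n_def < m:
            undefined[name] = m - n_def

    nir = float(np.mean([r.nir for r in reports]))  # outcomes observed: constant
    correct_pooled = int(round(acc_point * n))
    p_acc = binomial_tail_exact(correct_pooled, n, nir)

    aucs = [r.auc for r in rocs]
    auc_within = [
        (r.se / (min(max(r.auc, 0.5 / n), 1 - 0.5 / n)
                 * (1 - min(max(r.auc, 0.5 / n), 1 - 0.5 / n)))) ** 2
        for r in rocs
    ]
    auc_point, auc_lo, auc_hi, auc_se = _rubin_logit_ci(aucs, auc_within, n, rule)
    if m == 1:
        auc_point, auc_lo, auc_hi = rocs[0].auc, rocs[0].ci_low, rocs[0].ci_high
        auc_se = rocs[0].se

    pooled_curve = _pool_curves([r.curve for r in rocs])
    pooled_roc = RocResult(
        auc=auc_point, se=auc_se, ci_low=max(0.0, auc_lo),
        ci_high=min(1.0, auc_hi), curve=pooled_curve,
    )
    pooled_report = ClassificationReport(
        accuracy=acc_point,
        accuracy_ci=(max(0.0, acc_lo), min(1.0, acc_hi)),
        sensitivity=pooled_simple["sensitivity"],
        specificity=pooled_simple["specificity"],
        ppv=pooled_simple["ppv"],
        npv=pooled_simple["npv"],
        nir=nir,
        p_acc_gt_nir=p_acc,
        n=n,
    )
    per_imp = pd.DataFrame({"accuracy": accs, "auc": aucs})
    return pooled_report, pooled_roc, undefined, per_imp


def _pool_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Average the ROC staircases over imputations at shared thresholds.

    The attainable predicted probabilities are fixed by the model's four
    patterns, so curves share thresholds; only group compositions vary.
    """
    thresholds = sorted(
        {float(t) for c in curves for t in c["threshold"]}, reverse=True
    )
    rows = []
    for thr in thresholds:
        fprs, tprs = [], []
        for c in curves:
            # staircase value at this threshold: last point with threshold >= thr
            at = c[c["threshold"] >= thr]
            fprs.append(float(at["fpr"].iloc[-1]))
            tprs.append(float(at["tpr"].iloc[-1]))
        rows.append(
            {"threshold": thr, "fpr": float(np.mean(fprs)),
             "tpr": float(np.mean(tprs))}
        )
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def _pool_calibration(per_dataset: list[dict]) -> list[CalibrationPoint]:
    """Pool calibration groups: mean composition per predicted probability."""
    from statsmodels.stats.proportion import proportion_confint

    m = len(per_dataset)
    by_value: dict[float, list[tuple[int, float]]] = {}
    for d in per_dataset:
        for pt in d["calibration"]:
            by_value.setdefault(round(pt.predicted, 12), []).append(
                (pt.n_group, pt.observed * pt.n_group)
            )
    points = []
    for value in sorted(by_value):
        entries = by_value[value]
        n_mean = sum(n for n, _ in entries) / m
        events_mean = sum(e for _, e in entries) / m
        if n_mean == 0:
            continue
        lo, hi = proportion_confint(events_mean, n_mean, alpha=0.05, method="wilson")
        points.append(
            CalibrationPoint(
                predicted=float(value),
                observed=events_mean / n_mean,
                ci_low=float(lo),
                ci_high=float(hi),
                n_group=int(round(n_mean)),
            )
        )
    return points


def run_validation(
    table: pd.DataFrame,
    model_label: str,
    imputation_spec: Optional[ImputationSpec] = None,
    threshold: float = 0.5,
    mode: str = "impute",
    cohort_label: str = "",
    pooling: str = "rubin",
) -> ValidationReport:
    """Validate one EPOS model on one analysis table.

    Parameters
    ----------
    table
        Analysis table (post-eligibility) as produced by
        :func:`eposgait.cohort.records_to_frame`.
    model_label
        ``day2`` (scored from visit-1 measurements) or ``day9`` (visit 2).
    imputation_spec
        Chained-equations protocol; defaults to m=100, 5 iterations.
    mode
        ``impute`` for the primary analysis, ``raw`` for the complete-case
        secondary analysis.
    """
    if mode not in ("impute", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    params = load_model(model_label)
    tct_col, mi_col = _MODEL_VISIT_COLUMNS[model_label]
    spec = imputation_spec if imputation_spec is not None else default_spec()

    if mode == "raw":
        complete = table.dropna(subset=[tct_col, mi_col, "fac_90"])
        if complete.empty:
            raise ValueError("no complete cases for raw-data analysis")
        datasets = [complete.reset_index(drop=True)]
    else:
        var_names = [name for name, _ in spec.variables]
        if not table[var_names].isna().any().any():
            datasets = [table.reset_index(drop=True)]  # nothing to impute
        else:
            imputed = impute(table, spec)
            imputed = exclude_missing_outcome(imputed, table["fac_90"])
            datasets = imputed.datasets
        if not len(datasets[0]):
            raise ValueError("analysis set empty after outcome exclusion")

    per_dataset = [_evaluate_dataset(ds, params, threshold) for ds in datasets]
    pooled_report, pooled_roc, undefined, per_imp = pool_metrics(
        per_dataset, rule=pooling
    )
    calibration = _pool_calibration(per_dataset)
    spread = {
        "accuracy_min": float(per_imp["accuracy"].min()),
        "accuracy_max": float(per_imp["accuracy"].max()),
        "auc_min": float(per_imp["auc"].min()),
        "auc_max": float(per_imp["auc"].max()),
    }
    return ValidationReport(
        cohort_label=cohort_label,
        model_label=model_label,
        threshold=threshold,
        n=pooled_report.n,
        m_used=len(datasets),
        pooling_rule=pooling,
        classification=pooled_report,
        roc=pooled_roc,
        calibration=calibration,
        undefined_counts=undefined,
        spread=spread,
        per_imputation=per_imp,
    )


def _fmt(value: Optional[float], decimals: int = 3) -> str:
    return "N/R" if value is None else f"{value:.{decimals}f}"


def render_json(payload: dict) -> str:
    """Human-readable table (published-metrics-table layout) from report JSON."""
    lines = [
        f"Cohort: {payload.get('cohort') or 'unnamed'}   Model: {payload['model']}"
        f"   N = {payload['n']}   m = {payload['m']}"
        f"   threshold = {payload['threshold']}",
        "-" * 72,
        f"{'Accuracy (95% CI)':<28}"
        f"{_fmt(payload['accuracy'])} ({_fmt(payload['accuracy_ci'][0])}, "
        f"{_fmt(payload['accuracy_ci'][1])})",
        f"{'Sensitivity':<28}{_fmt(payload['sensitivity'])}",
        f"{'Specificity':<28}{_fmt(payload['specificity'])}",
        f"{'Positive predictive value':<28}{_fmt(payload['ppv'])}",
        f"{'Negative predictive value':<28}{_fmt(payload['npv'])}",
        f"{'No information rate':<28}{_fmt(payload['nir'])}",
        f"{'P-Value (Acc > NIR)':<28}{_fmt(payload['p_acc_gt_nir'])}",
        f"{'AUC (95% CI)':<28}"
        f"{_fmt(payload['auc'])} ({_fmt(payload['auc_ci'][0])}, "
        f"{_fmt(payload['auc_ci'][1])})",
    ]
    return "\n".join(lines)


def render_report(report: ValidationReport) -> str:
    """Human-readable table for an in-memory :class:`ValidationReport`."""
    return render_json(report_to_json(report))


def report_to_json(report: ValidationReport) -> dict:
    """Machine-readable report with stable keys."""
    c = report.classification
    return {
        "cohort": report.cohort_label,
        "model": report.model_label,
        "threshold": report.threshold,
        "n": report.n,
        "m": report.m_used,
        "pooling_rule": report.pooling_rule,
        "accuracy": c.accuracy,
        "accuracy_ci": list(c.accuracy_ci),
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "ppv": c.ppv,
        "npv": c.npv,
        "nir": c.nir,
        "p_acc_gt_nir": c.p_acc_gt_nir,
        "auc": report.roc.auc,
        "auc_ci": [report.roc.ci_low, report.roc.ci_high],
        "calibration": [dataclasses.asdict(p) for p in report.calibration],
        "spread": report.spread,
        "undefined_counts": report.undefined_counts,
    }
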
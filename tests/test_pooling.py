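"""Pooling across imputations (Rubin's rules) and report rendering."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit, logit

from eposgait import (
    ImputationSpec,
    apply_eligibility,
    generate_cohort,
    pool_metrics,
    preset,
    records_to_frame,
    render_json,
    render_report,
    report_to_json,
    run_validation,
)
from eposgait.metrics import (
    calibration_points,
    classification_report,
    confusion_table,
    roc_auc,
)
from eposgait.pooling import _rubin_logit_ci


def evaluate(pred, obs, prob):
    ct = confusion_table(pred, obs)
    return {
        "confusion": ct,
        "report": classification_report(ct),
        "roc": roc_auc(prob, obs),
        "calibration": calibration_points(prob, obs),
    }


def sample_eval(seed=0, n=60):
    rng = np.random.default_rng(seed)
    prob = rng.choice([0.1, 0.4, 0.8, 0.97], size=n)
    obs = (rng.random(n) < prob).astype(int)
    pred = (prob >= 0.5).astype(int)
    return evaluate(pred, obs, prob)


def test_identical_imputations_pool_to_the_single_report():
    single = sample_eval()
    pooled_report, pooled_roc, undefined, _ = pool_metrics([single] * 7)
    assert pooled_report.accuracy == pytest.approx(single["report"].accuracy, abs=1e-12)
    assert pooled_report.sensitivity == pytest.approx(
        single["report"].sensitivity, abs=1e-12
    )
    assert pooled_roc.auc == pytest.approx(single["roc"].auc, abs=1e-12)
    assert undefined == {}
    # between-imputation variance is 0, so the pooled AUC CI equals the
    # within-only (DeLong) interval up to the logit-scale transform
    assert pooled_roc.ci_low <= pooled_roc.auc <= pooled_roc.ci_high


def test_pooled_point_estimate_lies_between_two_imputations():
    a = sample_eval(seed=1)
    b = sample_eval(seed=2)
    pooled_report, pooled_roc, _, per_imp = pool_metrics([a, b])
    lo, hi = sorted([a["report"].accuracy, b["report"].accuracy])
    assert lo <= pooled_report.accuracy <= hi
    lo, hi = sorted([a["roc"].auc, b["roc"].auc])
    assert lo <= pooled_roc.auc <= hi
    assert per_imp.shape == (2, 2)


def test_rubin_total_variance_hand_computation():
    """T = mean within-variance + (1 + 1/m) * between-variance, logit scale."""
    n = 50
    estimates = [0.6, 0.64, 0.7, 0.66, 0.62]
    within = [1.0 / (n * p * (1 - p)) for p in estimates]
    point, lo, hi, se = _rubin_logit_ci(estimates, within, n, rule="rubin")
    logits = [logit(p) for p in estimates]
    w_bar = float(np.mean(within))
    between = float(np.var(logits, ddof=1))
    t_expected = w_bar + (1 + 1 / 5) * between
    assert se**2 == pytest.approx(t_expected, rel=1e-12)
    assert point == pytest.approx(expit(np.mean(logits)), rel=1e-12)
    half = 1.959963984540054 * math.sqrt(t_expected)
    assert lo == pytest.approx(expit(np.mean(logits) - half), rel=1e-12)
    assert hi == pytest.approx(expit(np.mean(logits) + half), rel=1e-12)


def test_pooling_is_permutation_invariant():
    evals = [sample_eval(seed=s) for s in range(5)]
    fwd_report, fwd_roc, _, _ = pool_metrics(evals)
    rev_report, rev_roc, _, _ = pool_metrics(evals[::-1])
    assert fwd_report == rev_report
    assert fwd_roc.auc == rev_roc.auc
    assert (fwd_roc.ci_low, fwd_roc.ci_high) == (rev_roc.ci_low, rev_roc.ci_high)


def test_undefined_metric_flagged_with_contributing_count():
    degenerate = evaluate([1, 1, 1], [1, 1, 0], [0.9, 0.9, 0.6])  # no negatives
    fine = sample_eval()
    pooled_report, _, undefined, _ = pool_metrics([degenerate, fine])
    assert undefined.get("npv") == 1
    assert pooled_report.npv == pytest.approx(fine["report"].npv)


def test_plain_average_pooling_rule_close_to_logit_rule():
    evals = [sample_eval(seed=s) for s in range(5)]
    rubin_rep, rubin_roc, _, _ = pool_metrics(evals, rule="rubin")
    mean_rep, mean_roc, _, _ = pool_metrics(evals, rule="mean")
    assert rubin_rep.accuracy == pytest.approx(mean_rep.accuracy, abs=0.01)
    assert rubin_roc.auc == pytest.approx(mean_roc.auc, abs=0.01)


def analysis_table(label, seed):
    cohort = generate_cohort(dataclasses.replace(preset(label), seed=seed))
    return records_to_frame(apply_eligibility(cohort.records)[0])


def test_complete_table_report_identical_between_raw_and_imputed_modes():
    table = analysis_table("cohort1", seed=21)
    complete = table.dropna()
    spec = ImputationSpec(m=6, iterations=3, seed=21)
    imputed = run_validation(complete, "day9", spec, mode="impute")
    raw = run_validation(complete, "day9", spec, mode="raw")
    assert report_to_json(imputed) == report_to_json(raw)
    assert imputed.m_used == 1  # nothing to impute: m collapses trivially


def test_pooled_values_lie_within_per_imputation_envelope():
    table = analysis_table("cohort2", seed=3)
    report = run_validation(
        table, "day9", ImputationSpec(m=8, iterations=3, seed=3)
    )
    assert report.m_used == 8
    s = report.spread
    assert s["accuracy_min"] - 1e-12 <= report.classification.accuracy
    assert report.classification.accuracy <= s["accuracy_max"] + 1e-12
    assert s["auc_min"] - 1e-12 <= report.roc.auc <= s["auc_max"] + 1e-12


def test_pooled_report_converges_to_complete_data_as_missingness_vanishes():
    rng = np.random.default_rng(77)
    spec = ImputationSpec(m=5, iterations=3, seed=77)
    config = dataclasses.replace(
        preset("cohort2"), n=120, missing_counts={}, seed=55
    )
    table = records_to_frame(apply_eligibility(generate_cohort(config).records)[0])
    reference = run_validation(table, "day9", spec).classification.accuracy
    gaps = {}
    for frac in (0.0, 0.01, 0.05):
        holey = table.copy()
        k = int(round(frac * len(holey)))
        for col in ("tct_s_v2", "mi_le_v2"):
            rows = rng.choice(len(holey), size=k, replace=False)
            holey.loc[rows, col] = np.nan
        acc = run_validation(holey, "day9", spec).classification.accuracy
        gaps[frac] = abs(acc - reference)
    assert gaps[0.0] == 0.0
    assert max(gaps.values()) < 0.05


def test_render_report_layout_and_json_schema():
    table = analysis_table("cohort1", seed=9)
    report = run_validation(table, "day2", ImputationSpec(m=4, iterations=2, seed=9))
    payload = report_to_json(report)
    for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                "nir", "p_acc_gt_nir", "auc"):
        assert key in payload
    text = render_report(report)
    rows = [
        "Accuracy (95% CI)", "Sensitivity", "Specificity",
        "Positive predictive value", "Negative predictive value",
        "No information rate", "P-Value (Acc > NIR)", "AUC (95% CI)",
    ]
    positions = [text.index(row) for row in rows]
    assert positions == sorted(positions)  # rendered in the published order
    assert render_json(payload) == text


def test_undefined_cells_render_as_nr():
    # degenerate cohort where everyone is predicted positive: NPV undefined
    table = analysis_table("cohort1", seed=9).dropna()
    table["tct_s_v2"] = 25.0
    table["mi_le_v2"] = 80.0
    report = run_validation(table, "day9", mode="raw")
    assert report.classification.npv is None
    assert "N/R" in render_report(report)
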
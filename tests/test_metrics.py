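"""Discrimination, classification and calibration metrics.

The published classification cells are checked through confusion tables
reconstructed from the printed margins (sensitivity x events, specificity x
non-events); the AUC implementation is checked against brute-force
Mann-Whitney pair counting and an independent library routine.
"""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from eposgait import (
    ConfusionTable,
    binomial_tail_exact,
    calibration_points,
    classification_report,
    confusion_table,
    roc_auc,
)


def brute_force_auc(prob, labels):
    """Independent oracle: count event/non-event pairs, ties worth 1/2."""
    pos = [p for p, y in zip(prob, labels) if y == 1]
    neg = [p for p, y in zip(prob, labels) if y == 0]
    wins = sum(1.0 for a in pos for b in neg if a > b)
    ties = sum(0.5 for a in pos for b in neg if a == b)
    return (wins + ties) / (len(pos) * len(neg))


# --- confusion tables -------------------------------------------------------

def test_confusion_table_perfect_prediction():
    ct = confusion_table([1, 1, 0], [1, 1, 0])
    assert (ct.tp, ct.tn, ct.fp, ct.fn) == (2, 1, 0, 0)


def test_confusion_table_all_positive_rule():
    pred = [1] * 39
    obs = [1] * 28 + [0] * 11
    ct = confusion_table(pred, obs)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (28, 11, 0, 0)


def test_confusion_table_empty_errors():
    with pytest.raises(ValueError):
        confusion_table([], [])


def test_confusion_counts_always_sum_to_n():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(1, 50))
        pred = rng.integers(0, 2, n)
        obs = rng.integers(0, 2, n)
        ct = confusion_table(pred, obs)
        assert ct.n == n


# --- classification reports: the four published cohort x model cells --------

# counts reconstructed from printed sensitivity/specificity and margins
# (cohort I: 39 patients, 28 events; cohort II: 78 patients, 58 events)
PUBLISHED_CELLS = [
    # (ct, accuracy, sensitivity, specificity, ppv, npv, nir, p_acc_gt_nir)
    (ConfusionTable(tp=22, fp=8, fn=6, tn=3),
     0.641, 0.786, 0.273, 0.733, 0.333, 0.718, 0.892),
    (ConfusionTable(tp=27, fp=3, fn=1, tn=8),
     0.897, 0.964, 0.727, 0.900, 0.889, 0.718, 0.007),
    (ConfusionTable(tp=54, fp=9, fn=4, tn=11),
     0.833, 0.931, 0.550, 0.857, 0.733, 0.744, 0.041),
    (ConfusionTable(tp=54, fp=7, fn=4, tn=13),
     0.859, 0.931, 0.650, 0.885, 0.765, 0.744, 0.010),
]


@pytest.mark.parametrize("ct, acc, sens, spec, ppv, npv, nir, p", PUBLISHED_CELLS)
def test_classification_report_reproduces_published_cells(
    ct, acc, sens, spec, ppv, npv, nir, p
):
    rep = classification_report(ct)
    assert rep.accuracy == pytest.approx(acc, abs=5e-4)
    assert rep.sensitivity == pytest.approx(sens, abs=5e-4)
    assert rep.specificity == pytest.approx(spec, abs=5e-4)
    assert rep.ppv == pytest.approx(ppv, abs=5e-4)
    assert rep.npv == pytest.approx(npv, abs=5e-4)
    assert rep.nir == pytest.approx(nir, abs=5e-4)
    assert rep.p_acc_gt_nir == pytest.approx(p, abs=1e-3)


@pytest.mark.parametrize("ct", [c[0] for c in PUBLISHED_CELLS])
def test_report_is_a_fixed_point_of_reconstruction(ct):
    """Rebuilding the table from its own reported margins returns the table."""
    rep = classification_report(ct)
    events, nonevents = ct.events, ct.nonevents
    tp = round(rep.sensitivity * events)
    tn = round(rep.specificity * nonevents)
    again = ConfusionTable(tp=tp, fp=nonevents - tn, fn=events - tp, tn=tn)
    assert again == ct
    assert classification_report(again) == rep


def test_perfect_two_patient_case():
    rep = classification_report(ConfusionTable(tp=1, fp=0, fn=0, tn=1))
    assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
    assert rep.ppv == rep.npv == 1.0
    assert rep.nir == 0.5


def test_undefined_ratios_reported_as_none_not_zero():
    rep = classification_report(ConfusionTable(tp=3, fp=1, fn=0, tn=0))
    assert rep.npv is None  # no predicted negatives
    assert rep.specificity == 0.0


def test_nir_is_majority_class_prevalence():
    rep = classification_report(ConfusionTable(tp=1, fp=9, fn=1, tn=1))
    assert rep.nir == pytest.approx(10 / 12)  # non-events are the majority


# --- exact binomial tail ----------------------------------------------------

def test_binomial_tail_closed_form_extremes():
    assert binomial_tail_exact(39, 39, 0.718) == pytest.approx(
        0.718**39, rel=1e-12
    )
    assert binomial_tail_exact(0, 10, 0.3) == 1.0


@pytest.mark.parametrize(
    "successes, n, p0, printed",
    # p0 is the exact no-information rate (28/39 and 58/78; printed rounded
    # as 0.718 and 0.744)
    [(25, 39, 28 / 39, 0.892), (35, 39, 28 / 39, 0.007),
     (65, 78, 58 / 78, 0.041), (67, 78, 58 / 78, 0.010)],
)
def test_binomial_tail_matches_published_nir_tests(successes, n, p0, printed):
    assert binomial_tail_exact(successes, n, p0) == pytest.approx(
        printed, abs=1e-3
    )


# --- ROC / AUC --------------------------------------------------------------

def test_auc_pure_ties_is_half():
    res = roc_auc([0.4] * 6, [1, 1, 1, 0, 0, 0])
    assert res.auc == 0.5


def test_auc_perfect_separation_is_one():
    res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert res.auc == 1.0


def test_auc_worked_pair_count():
    # events {0.8, 0.6} vs non-events {0.7, 0.4}: 3 wins of 4 pairs
    res = roc_auc([0.8, 0.6, 0.7, 0.4], [1, 1, 0, 0])
    assert res.auc == pytest.approx(0.75, abs=1e-12)


def test_auc_single_class_undefined():
    with pytest.raises(ValueError, match="undefined"):
        roc_auc([0.2, 0.8], [1, 1])


def test_auc_matches_brute_force_and_library_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 40))
        # few distinct values to force heavy ties, as with 4-pattern scores
        prob = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        res = roc_auc(prob, labels)
        assert res.auc == pytest.approx(brute_force_auc(prob, labels), abs=1e-12)
        assert res.auc == pytest.approx(roc_auc_score(labels, prob), abs=1e-10)
        assert res.ci_low <= res.auc <= res.ci_high


def test_trapezoidal_area_under_curve_equals_auc():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        prob = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        res = roc_auc(prob, labels)
        area = np.trapezoid(res.curve["tpr"], res.curve["fpr"])
        assert area == pytest.approx(res.auc, abs=1e-12)


def test_roc_curve_is_a_staircase_from_origin_to_corner():
    res = roc_auc([0.1, 0.3, 0.5, 0.9, 0.9, 0.3], [0, 0, 1, 1, 0, 1])
    curve = res.curve
    assert (curve.iloc[0]["fpr"], curve.iloc[0]["tpr"]) == (0.0, 0.0)
    assert (curve.iloc[-1]["fpr"], curve.iloc[-1]["tpr"]) == (1.0, 1.0)
    assert curve["fpr"].is_monotonic_increasing
    assert curve["tpr"].is_monotonic_increasing
    assert curve["threshold"].is_monotonic_decreasing


def test_delong_ci_narrows_with_sample_size():
    rng = np.random.default_rng(3)
    widths = {100: [], 1000: []}
    for n in widths:
        for _ in range(20):
            prob = rng.choice([0.1, 0.4, 0.8, 0.97], size=n)
            labels = (rng.random(n) < prob).astype(int)
            res = roc_auc(prob, labels)
            widths[n].append(res.ci_high - res.ci_low)
    assert np.mean(widths[1000]) < np.mean(widths[100])


# --- calibration ------------------------------------------------------------

def test_calibration_point_wilson_interval_worked_example():
    # one group of 10 sharing predicted 0.273 with 3 observed events
    points = calibration_points([0.273] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    assert len(points) == 1
    pt = points[0]
    assert pt.observed == pytest.approx(0.3)
    # Wilson closed form at x=3, n=10: (0.1078, 0.6032)
    assert pt.ci_low == pytest.approx(0.1078, abs=5e-4)
    assert pt.ci_high == pytest.approx(0.6032, abs=5e-4)
    assert 0.08 < pt.ci_low and pt.ci_high < 0.65


def test_calibration_groups_ordered_and_exhaustive():
    prob = [0.9, 0.1, 0.9, 0.5, 0.1]
    obs = [1, 0, 1, 1, 0]
    points = calibration_points(prob, obs)
    assert [p.predicted for p in points] == [0.1, 0.5, 0.9]
    assert sum(p.n_group for p in points) == len(prob)


def test_calibration_on_the_diagonal_when_observed_equals_predicted():
    prob = [0.25] * 4 + [0.75] * 4
    obs = [1, 0, 0, 0, 1, 1, 1, 0]
    for pt in calibration_points(prob, obs):
        assert pt.observed == pytest.approx(pt.predicted)


def test_calibration_singleton_group_is_uninformative():
    (pt,) = calibration_points([0.5], [1])
    assert pt.ci_high - pt.ci_low > 0.75
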
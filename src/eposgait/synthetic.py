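"""Synthetic stroke cohorts with the statistical structure the pipeline needs.

The validation cohorts' patient-level data are available on request only, so
the pipeline is exercised on generated cohorts that emulate the published
case-mix: the prevalence of the two binary EPOS predictor patterns at each
visit, the 3-month independent-gait prevalence, nonparametric summaries of
age and NIHSS, small MCAR missingness in raw predictor scores, and complete
outcomes.

Generation proceeds patient by patient:

1. the visit-1 (tct, mi) pattern is drawn from a joint Bernoulli pair with
   the configured marginal prevalences and a predictor odds ratio (default 4:
   sitting balance and leg strength are positively associated);
2. the visit-2 pattern allows upward transitions only (neurological
   improvement), each absent component recovering with its improvement
   probability;
3. the latent event probability is the configured outcome model — by default
   a named EPOS equation evaluated on the visit-2 pattern, which makes that
   model perfectly calibrated by construction — and the 90-day FAC is drawn
   >= 4 with that probability;
4. raw scores are drawn consistently with the pattern (TCT-s = 25 exactly
   when the pattern says balance is present, MI-LE uniform on 25-100 when
   strength is present, else uniform on 0-24), so dichotomization recovers
   the sampled pattern exactly;
5. age and NIHSS come from log-normal distributions moment-matched to the
   published median and quartiles; MCAR masks, deaths before day 90 and
   baseline-independent patients are applied last.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .model import load_model, predict_probability

__all__ = [
    "SyntheticCohortConfig",
    "GeneratedCohort",
    "generate_cohort",
    "preset",
    "expected_auc",
    "joint_pattern_probabilities",
]

_PATTERNS = [(0, 0), (0, 1), (1, 0), (1, 1)]
_IQR_Z = 1.3489795003921634  # z(0.75) - z(0.25)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters of one synthetic cohort."""

    label: str
    n: int
    tct_prev_v1: float
    mi_prev_v1: float
    predictor_odds_ratio: float = 4.0
    tct_improve: float = 0.30
    mi_improve: float = 0.30
    #: model label evaluated on the visit-2 pattern, or explicit per-pattern
    #: event probabilities keyed by the visit-2 (tct, mi) pattern
    outcome_model: Union[str, Mapping[tuple[int, int], float]] = "day9"
    age_median: float = 72.0
    age_q1: float = 63.0
    age_q3: float = 77.0
    nihss_median: float = 8.0
    nihss_q1: float = 5.0
    nihss_q3: float = 13.0
    pct_female: float = 35.0
    pct_left_side: float = 42.0
    pct_ischemic: float = 85.0
    missing_counts: Mapping[str, int] = field(default_factory=dict)
    n_died: int = 0
    n_baseline_independent: int = 0
    visit_days: tuple[int, int] = (1, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.tct_prev_v1, self.mi_prev_v1, self.tct_improve, self.mi_improve,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all prevalences/rates must lie in [0, 1]")
        if self.predictor_odds_ratio <= 0:
            raise ValueError("predictor odds ratio must be positive")
        if self.n < self.n_died + self.n_baseline_independent:
            raise ValueError("n must cover deaths and baseline-independent patients")
        if self.visit_days[0] >= self.visit_days[1]:
            raise ValueError("visit 1 must precede visit 2")
        for var, count in self.missing_counts.items():
            if count < 0 or count > self.n:
                raise ValueError(f"missing count for {var!r} outside [0, n]")
        # fail fast on an infeasible marginal/odds-ratio combination
        joint_pattern_probabilities(
            self.tct_prev_v1, self.mi_prev_v1, self.predictor_odds_ratio
        )

    def event_probability(self, pattern_v2: tuple[int, int]) -> float:
        if isinstance(self.outcome_model, str):
            params = load_model(self.outcome_model)
            return predict_probability(params, *pattern_v2)
        return float(self.outcome_model[pattern_v2])


@dataclass
class GeneratedCohort:
    """Generated records plus the per-patient latent truth table."""

    records: list[PatientRecord]
    truth: pd.DataFrame


def joint_pattern_probabilities(
    tct_prev: float, mi_prev: float, odds_ratio: float
) -> dict[tuple[int, int], float]:
    """Joint distribution of the (tct, mi) pattern from marginals + odds ratio.

    Uses the Plackett construction: p11 is the root of the odds-ratio
    quadratic that lies inside the Frechet bounds.
    """
    a, b, psi = tct_prev, mi_prev, odds_ratio
    if psi == 1.0:
        p11 = a * b
    else:
        s = 1.0 + (a + b) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * a * b
        p11 = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo, hi = max(0.0, a + b - 1.0), min(a, b)
    if not lo - 1e-12 <= p11 <= hi + 1e-12:
        raise ValueError("infeasible marginals/odds-ratio combination")
    p11 = min(max(p11, lo), hi)
    return {
        (1, 1): p11,
        (1, 0): a - p11,
        (0, 1): b - p11,
        (0, 0): 1.0 - a - b + p11,
    }


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    if not 0 < q1 <= median <= q3:
        raise ValueError("need 0 < Q1 <= median <= Q3")
    mu = math.log(median)
    sigma = math.log(q3 / q1) / _IQR_Z if q3 > q1 else 0.0
    return mu, sigma


def generate_cohort(config: SyntheticCohortConfig) -> GeneratedCohort:
    """Draw one cohort; same config (incl. seed) always yields the same cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    joint = joint_pattern_probabilities(
        config.tct_prev_v1, config.mi_prev_v1, config.predictor_odds_ratio
    )
    pattern_idx = rng.choice(
        len(_PATTERNS), size=n, p=[joint[p] for p in _PATTERNS]
    )
    age_mu, age_sigma = _lognormal_params(
        config.age_median, config.age_q1, config.age_q3
    )
    ni_mu, ni_sigma = _lognormal_params(
        config.nihss_median, config.nihss_q1, config.nihss_q3
    )

    # special roles: deaths first, then baseline-independent patients
    died = np.zeros(n, dtype=bool)
    baseline_independent = np.zeros(n, dtype=bool)
    roles = rng.permutation(n)
    died[roles[: config.n_died]] = True
    baseline_independent[
        roles[config.n_died: config.n_died + config.n_baseline_independent]
    ] = True

    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    raw: list[dict] = []
    for i in range(n):
        tct1, mi1 = _PATTERNS[pattern_idx[i]]
        tct2 = tct1 or int(rng.random() < config.tct_improve)
        mi2 = mi1 or int(rng.random() < config.mi_improve)
        event_prob = config.event_probability((tct2, mi2))
        event = int(rng.random() < event_prob)
        fac_90 = int(rng.integers(4, 6)) if event else int(rng.integers(0, 4))
        age = int(np.clip(round(rng.lognormal(age_mu, age_sigma)), 18, 120))
        nihss = int(np.clip(round(rng.lognormal(ni_mu, ni_sigma)), 0, 42))
        row = {
            "patient_id": f"{config.label or 'synthetic'}-{i:04d}",
            "age": age,
            "sex": "female" if rng.random() < config.pct_female / 100.0 else "male",
            "affected_side": (
                "left" if rng.random() < config.pct_left_side / 100.0 else "right"
            ),
            "stroke_type": (
                "ischemic" if rng.random() < config.pct_ischemic / 100.0
                else "hemorrhagic"
            ),
            "nihss_total": nihss,
            "nihss_loc": int(rng.binomial(3, min(0.9, nihss / 84.0))),
            "nihss_hemianopia": int(rng.binomial(3, min(0.9, nihss / 60.0))),
            "tct_s_v1": 25 if tct1 else int(rng.integers(0, 25)),
            "tct_s_v2": 25 if tct2 else int(rng.integers(0, 25)),
            "mi_le_v1": int(rng.integers(25, 101)) if mi1 else int(rng.integers(0, 25)),
            "mi_le_v2": int(rng.integers(25, 101)) if mi2 else int(rng.integers(0, 25)),
            "fac_baseline": int(rng.integers(0, 4)),
            "fac_90": fac_90,
            "died_before_90": False,
            "visit1_day": config.visit_days[0],
            "visit2_day": config.visit_days[1],
        }
        if died[i]:
            row["died_before_90"] = True
            row["fac_90"] = None
        if baseline_independent[i]:
            row["fac_baseline"] = int(rng.integers(4, 6))
        raw.append(row)
        truth_rows.append(
            {
                "patient_id": row["patient_id"],
                "tct_v1": tct1, "mi_v1": mi1, "tct_v2": tct2, "mi_v2": mi2,
                "event_prob": event_prob, "event": event,
                "died": bool(died[i]),
                "baseline_independent": bool(baseline_independent[i]),
            }
        )

    # MCAR masks: exactly the configured number of cells per variable,
    # drawn among the analyzable patients so analysis-set counts match
    eligible = np.flatnonzero(~died & ~baseline_independent)
    maskable = ("tct_s_v1", "tct_s_v2", "mi_le_v1", "mi_le_v2", "fac_90")
    for var, count in config.missing_counts.items():
        if var not in maskable:
            raise ValueError(f"cannot mask variable {var!r}")
        chosen = rng.choice(eligible, size=count, replace=False)
        for i in chosen:
            raw[i][var] = None

    records = [PatientRecord(**row) for row in raw]
    truth = pd.DataFrame(truth_rows)
    return GeneratedCohort(records=records, truth=truth)


def preset(label: str) -> SyntheticCohortConfig:
    """Documented emulation of the two validation cohorts' published summaries.

    ``cohort1``: N=39, visits on days 1 and 8; visit-1 prevalences 43.6%
    (TCT-s = 25) and 71.8% (MI-LE >= 25); missing cells 2/1/3 in TCT-s v1 /
    MI-LE v1 / MI-LE v2; age 74 (69-77); NIHSS 9 (5.5-13.5); all ischemic.

    ``cohort2``: N=78, visits on days 3 and 9; prevalences 60.3% / 76.9%;
    4 missing cells in each visit-2 score; age 69 (60-77); NIHSS 8 (5-12);
    76.9% ischemic.

    Outcomes are model-faithful (day-9 equation on the visit-2 pattern),
    which lands the 3-month independent-gait prevalence near the published
    71.8% / 74.4%.
    """
    if label == "cohort1":
        return SyntheticCohortConfig(
            label="cohort1",
            n=39,
            tct_prev_v1=0.436,
            mi_prev_v1=0.718,
            tct_improve=0.30,
            mi_improve=0.30,
            outcome_model="day9",
            age_median=74, age_q1=69, age_q3=77,
            nihss_median=9, nihss_q1=5.5, nihss_q3=13.5,
            pct_female=33.3, pct_left_side=33.3, pct_ischemic=100.0,
            missing_counts={"mi_le_v1": 1, "tct_s_v1": 2, "mi_le_v2": 3},
            visit_days=(1, 8),
        )
    if label == "cohort2":
        return SyntheticCohortConfig(
            label="cohort2",
            n=78,
            tct_prev_v1=0.603,
            mi_prev_v1=0.769,
            tct_improve=0.30,
            mi_improve=0.30,
            outcome_model="day9",
            age_median=69, age_q1=60, age_q3=77,
            nihss_median=8, nihss_q1=5, nihss_q3=12,
            pct_female=37.2, pct_left_side=47.4, pct_ischemic=76.9,
            missing_counts={"tct_s_v2": 4, "mi_le_v2": 4},
            visit_days=(3, 9),
        )
    raise KeyError(f"unknown preset {label!r}; available: cohort1, cohort2")


def _state_distribution(
    config: SyntheticCohortConfig,
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Enumerate (visit-1 pattern, visit-2 pattern, probability) states."""
    joint = joint_pattern_probabilities(
        config.tct_prev_v1, config.mi_prev_v1, config.predictor_odds_ratio
    )
    states = []
    for (tct1, mi1), w in joint.items():
        tct_moves = [(tct1, 1.0)] if tct1 else [
            (1, config.tct_improve), (0, 1.0 - config.tct_improve)
        ]
        mi_moves = [(mi1, 1.0)] if mi1 else [
            (1, config.mi_improve), (0, 1.0 - config.mi_improve)
        ]
        for tct2, pt in tct_moves:
            for mi2, pm in mi_moves:
                if w * pt * pm > 0:
                    states.append(((tct1, mi1), (tct2, mi2), w * pt * pm))
    return states


def expected_auc(config: SyntheticCohortConfig, model_label: str) -> float:
    """Closed-form population AUC of a model under the generative config.

    Enumerates the finitely many (visit-1, visit-2) pattern states; the
    model's predicted probability depends on the scored visit and the latent
    event probability on the visit-2 pattern.  AUC is the probability that a
    random event outranks a random non-event, ties counted half.
    """
    params = load_model(model_label)
    visit = 1 if model_label == "day2" else 2
    groups: list[tuple[float, float, float]] = []  # (predicted, event_prob, weight)
    for pattern1, pattern2, w in _state_distribution(config):
        scored = pattern1 if visit == 1 else pattern2
        groups.append(
            (predict_probability(params, *scored),
             config.event_probability(pattern2), w)
        )
    p_event = sum(w * e for _, e, w in groups)
    p_nonevent = sum(w * (1 - e) for _, e, w in groups)
    if p_event == 0 or p_nonevent == 0:
        raise ValueError("AUC undefined under this config")
    num = 0.0
    for pred_g, e_g, w_g in groups:
        for pred_h, e_h, w_h in groups:
            pair = w_g * e_g * w_h * (1.0 - e_h)
            if pred_g > pred_h:
                num += pair
            elif pred_g == pred_h:
                num += 0.5 * pair
    return num / (p_event * p_nonevent)
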
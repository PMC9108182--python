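"""Cohort tables: domain types, CSV I/O, dichotomization and eligibility.

One row of a cohort CSV is one patient: demographics, NIHSS scores at the
first study visit, raw TCT-s (Trunk Control Test, sitting-balance item, 0-25)
and MI-LE (Motricity Index lower extremity, 0-100) at two visits, FAC
(Functional Ambulation Categories, 0-5) at baseline and at 90 days, and
death/eligibility flags.  Missing measurements are empty cells.

The canonical header is :data:`CANONICAL_COLUMNS`; foreign tables can be read
by supplying a ``schema`` mapping from canonical names to the file's own
column names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "DichotomizedPredictors",
    "CohortSchemaError",
    "CohortParseError",
    "CANONICAL_COLUMNS",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "dichotomize_predictors",
    "dichotomize_outcome",
    "apply_eligibility",
    "summarize_cohort",
]

#: canonical CSV header, in column order
CANONICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "affected_side",
    "stroke_type",
    "nihss_total",
    "nihss_loc",
    "nihss_hemianopia",
    "tct_s_v1",
    "tct_s_v2",
    "mi_le_v1",
    "mi_le_v2",
    "fac_baseline",
    "fac_90",
    "died_before_90",
    "visit1_day",
    "visit2_day",
]

# per-column integer ranges for validation (scale bounds)
_RANGES = {
    "age": (18, 120),
    "nihss_total": (0, 42),
    "nihss_loc": (0, 3),
    "nihss_hemianopia": (0, 3),
    "tct_s_v1": (0, 25),
    "tct_s_v2": (0, 25),
    "mi_le_v1": (0, 100),
    "mi_le_v2": (0, 100),
    "fac_baseline": (0, 5),
    "fac_90": (0, 5),
}

_OPTIONAL_INT_COLUMNS = (
    "tct_s_v1",
    "tct_s_v2",
    "mi_le_v1",
    "mi_le_v2",
    "fac_baseline",
    "fac_90",
)

_CATEGORIES = {
    "sex": ("female", "male"),
    "affected_side": ("left", "right"),
    "stroke_type": ("ischemic", "hemorrhagic"),
}


class CohortSchemaError(ValueError):
    """The CSV is missing a required column."""


class CohortParseError(ValueError):
    """A cell could not be parsed or is out of range; names the row."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's raw measurements across visits, outcome and flags."""

    patient_id: str
    age: int
    sex: str
    affected_side: str
    stroke_type: str
    nihss_total: int
    nihss_loc: int
    nihss_hemianopia: int
    tct_s_v1: Optional[int]
    tct_s_v2: Optional[int]
    mi_le_v1: Optional[int]
    mi_le_v2: Optional[int]
    fac_baseline: Optional[int]
    fac_90: Optional[int]
    died_before_90: bool
    visit1_day: int
    visit2_day: int

    def __post_init__(self) -> None:
        for field, (lo, hi) in _RANGES.items():
            value = getattr(self, field)
            if value is not None and not lo <= value <= hi:
                raise ValueError(
                    f"patient {self.patient_id}: {field}={value} outside [{lo}, {hi}]"
                )
        for field, allowed in _CATEGORIES.items():
            if getattr(self, field) not in allowed:
                raise ValueError(
                    f"patient {self.patient_id}: {field}={getattr(self, field)!r} "
                    f"not in {allowed}"
                )
        if not self.visit1_day < self.visit2_day:
            raise ValueError(
                f"patient {self.patient_id}: visit1_day must precede visit2_day"
            )
        if self.died_before_90 and self.fac_90 is not None:
            raise ValueError(
                f"patient {self.patient_id}: died before day 90 but has a "
                "90-day FAC score"
            )


@dataclass(frozen=True)
class DichotomizedPredictors:
    """Binary EPOS predictors; ``None`` marks a missing raw score."""

    tct: Optional[int]
    mi: Optional[int]


def dichotomize_predictors(
    tct_raw: Optional[int], mi_raw: Optional[int]
) -> DichotomizedPredictors:
    """Dichotomize raw scores into the EPOS predictor coding.

    ``tct = 1`` iff the raw TCT-s equals 25/25 (able to sit unsupported for
    30 s); ``mi = 1`` iff the raw MI-LE is >= 25/100 (some strength in the
    paretic leg).  Missing raw scores propagate as missing.
    """
    if tct_raw is not None and not 0 <= tct_raw <= 25:
        raise ValueError(f"TCT-s score {tct_raw} outside [0, 25]")
    if mi_raw is not None and not 0 <= mi_raw <= 100:
        raise ValueError(f"MI-LE score {mi_raw} outside [0, 100]")
    tct = None if tct_raw is None else int(tct_raw == 25)
    mi = None if mi_raw is None else int(mi_raw >= 25)
    return DichotomizedPredictors(tct=tct, mi=mi)


def dichotomize_outcome(fac_90: Optional[int]) -> Optional[int]:
    """Independent gait at 3 months: 1 iff FAC >= 4, missing stays missing."""
    if fac_90 is None:
        return None
    if not 0 <= fac_90 <= 5:
        raise ValueError(f"FAC score {fac_90} outside [0, 5]")
    return int(fac_90 >= 4)


def _parse_optional_int(value, column: str, row: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise CohortParseError(
            f"row {row}: column {column!r} has non-numeric value {value!r}"
        ) from None
    if not float(as_float).is_integer():
        raise CohortParseError(
            f"row {row}: column {column!r} has non-integer value {value!r}"
        )
    return int(as_float)


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no", ""):
        return False
    raise CohortParseError(f"row {row}: column {column!r} has non-boolean {value!r}")


def read_cohort(
    path: str | Path, schema: Optional[Mapping[str, str]] = None
) -> list[PatientRecord]:
    """Read a patient cohort CSV into validated records.

    Parameters
    ----------
    path
        CSV file with a header row; empty cells denote missing values.
    schema
        Optional mapping from canonical column names to the file's column
        names, for tables that do not use the canonical header.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = {c: c for c in CANONICAL_COLUMNS}
    if schema:
        mapping.update(schema)
    for canonical, actual in mapping.items():
        if actual not in frame.columns:
            raise CohortSchemaError(
                f"required column {actual!r} (for {canonical!r}) missing from {path}"
            )
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        cells = {c: getattr(row, mapping[c]) for c in CANONICAL_COLUMNS}
        kwargs = {}
        kwargs["patient_id"] = str(cells["patient_id"])
        for col in ("age", "nihss_total", "nihss_loc", "nihss_hemianopia",
                    "visit1_day", "visit2_day"):
            value = _parse_optional_int(cells[col], col, i)
            if value is None:
                raise CohortParseError(f"row {i}: column {col!r} must not be empty")
            kwargs[col] = value
        for col in _OPTIONAL_INT_COLUMNS:
            kwargs[col] = _parse_optional_int(cells[col], col, i)
        for col in _CATEGORIES:
            kwargs[col] = str(cells[col]).strip()
        kwargs["died_before_90"] = _parse_bool(cells["died_before_90"],
                                               "died_before_90", i)
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            raise CohortParseError(f"row {i}: {exc}") from None
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV with the canonical header; missing cells empty."""
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        row["died_before_90"] = int(row["died_before_90"])
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    frame.to_csv(path, index=False, na_rep="")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Analysis table: numeric encoding of the imputation-model variables.

    Binary encodings: sex female=1, affected side left=1, stroke ischemic=1.
    Raw scores stay raw (the imputation operates on undichotomized scores).
    """
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "female": [int(r.sex == "female") for r in records],
            "left_side": [int(r.affected_side == "left") for r in records],
            "ischemic": [int(r.stroke_type == "ischemic") for r in records],
            "nihss_total": [r.nihss_total for r in records],
            "nihss_loc": [r.nihss_loc for r in records],
            "nihss_hemianopia": [r.nihss_hemianopia for r in records],
            "tct_s_v1": [r.tct_s_v1 for r in records],
            "tct_s_v2": [r.tct_s_v2 for r in records],
            "mi_le_v1": [r.mi_le_v1 for r in records],
            "mi_le_v2": [r.mi_le_v2 for r in records],
            "fac_90": [r.fac_90 for r in records],
        }
    )
    for col in ("tct_s_v1", "tct_s_v2", "mi_le_v1", "mi_le_v2", "fac_90"):
        frame[col] = frame[col].astype("float64")
    return frame


def apply_eligibility(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], list[dict]]:
    """Split records into the analysis set and an exclusion log.

    Excluded: patients who died before the day-90 visit, and patients already
    walking independently at the baseline visit (FAC >= 4).
    """
    kept: list[PatientRecord] = []
    excluded: list[dict] = []
    for rec in records:
        if rec.died_before_90:
            excluded.append(
                {"patient_id": rec.patient_id, "reason": "died before day-90 visit"}
            )
        elif rec.fac_baseline is not None and rec.fac_baseline >= 4:
            excluded.append(
                {"patient_id": rec.patient_id, "reason": "independent gait at baseline"}
            )
        else:
            kept.append(rec)
    return kept, excluded


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="median_unbiased")
    return float(q1), float(med), float(q3)


def summarize_cohort(records: Sequence[PatientRecord]) -> dict:
    """Nonparametric cohort description (median/Q1/Q3, prevalences).

    Prevalences are fractions of non-missing values.  Quartiles use the
    median-unbiased estimator.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n = len(records)
    age_q1, age_med, age_q3 = _quartiles([r.age for r in records])
    ni_q1, ni_med, ni_q3 = _quartiles([r.nihss_total for r in records])

    def _prevalence(flags: list[Optional[int]]) -> Optional[float]:
        present = [f for f in flags if f is not None]
        return sum(present) / len(present) if present else None

    tct_v1 = [dichotomize_predictors(r.tct_s_v1, r.mi_le_v1).tct for r in records]
    mi_v1 = [dichotomize_predictors(r.tct_s_v1, r.mi_le_v1).mi for r in records]
    tct_v2 = [dichotomize_predictors(r.tct_s_v2, r.mi_le_v2).tct for r in records]
    mi_v2 = [dichotomize_predictors(r.tct_s_v2, r.mi_le_v2).mi for r in records]
    outcome = [dichotomize_outcome(r.fac_90) for r in records]
    return {
        "n": n,
        "age_median": age_med,
        "age_q1": age_q1,
        "age_q3": age_q3,
        "nihss_median": ni_med,
        "nihss_q1": ni_q1,
        "nihss_q3": ni_q3,
        "pct_female": 100.0 * sum(r.sex == "female" for r in records) / n,
        "pct_ischemic": 100.0 * sum(r.stroke_type == "ischemic" for r in records) / n,
        "pct_left_side": 100.0 * sum(r.affected_side == "left" for r in records) / n,
        "tct_v1_prevalence": _prevalence(tct_v1),
        "mi_v1_prevalence": _prevalence(mi_v1),
        "tct_v2_prevalence": _prevalence(tct_v2),
        "mi_v2_prevalence": _prevalence(mi_v2),
        "outcome_prevalence": _prevalence(outcome),
    }
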
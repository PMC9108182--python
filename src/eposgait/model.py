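"""EPOS logistic prediction equations for independent gait after stroke.

The EPOS (Early Prediction of functional Outcome after Stroke) model for
independent gait is a two-predictor logistic risk score.  Its inputs are the
dichotomized sitting-balance item of the Trunk Control Test (``tct``: 1 if the
raw TCT-s equals 25/25, else 0) and the dichotomized Motricity Index lower
extremity subscale (``mi``: 1 if the raw MI-LE is >= 25/100, else 0).  Two
fixed-coefficient equations exist, one for an assessment around day 2
post-stroke and one for day 9:

    P = 1 / (1 + exp(-(intercept + beta_tct * tct + beta_mi * mi)))

Coefficients are shipped in a plain-text JSON file so that other two-predictor
logit scores can be validated with the same pipeline; they are never
re-estimated here (external validation keeps the model frozen).
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EposModelParams",
    "Prediction",
    "load_model",
    "list_models",
    "predict_probability",
    "predict_probabilities",
    "classify",
    "pattern_probabilities",
]

_MODEL_RESOURCE = "models.json"


@dataclass(frozen=True)
class EposModelParams:
    """Intercept and coefficients of one EPOS prediction time point."""

    label: str
    intercept: float
    beta_tct: float
    beta_mi: float

    def linear_predictor(self, tct: int, mi: int) -> float:
        return self.intercept + self.beta_tct * tct + self.beta_mi * mi


@dataclass(frozen=True)
class Prediction:
    """A predicted probability with its thresholded class."""

    probability: float
    predicted_class: int
    threshold: float


class UnknownModelError(KeyError):
    """Requested model label is not among the bundled equations."""


@functools.lru_cache(maxsize=1)
def _read_model_file() -> dict:
    text = resources.files("eposgait.data").joinpath(_MODEL_RESOURCE).read_text()
    return json.loads(text)


def list_models() -> list[str]:
    """Labels of the bundled prediction equations (``day2``, ``day9``)."""
    return [entry["label"] for entry in _read_model_file()["models"]]


def load_model(label: str) -> EposModelParams:
    """Load one bundled equation by label.

    Raises
    ------
    UnknownModelError
        If ``label`` is not bundled (e.g. the day-5 model, whose coefficients
        were never published for this validation and which therefore cannot be
        validated here).  The error message lists the available labels.
    """
    data = _read_model_file()
    for entry in data["models"]:
        if entry["label"] == label:
            coefs = {t["name"]: float(t["coef"]) for t in entry["terms"]}
            return EposModelParams(
                label=label,
                intercept=float(entry["intercept"]),
                beta_tct=coefs["tct"],
                beta_mi=coefs["mi"],
            )
    available = ", ".join(e["label"] for e in data["models"])
    raise UnknownModelError(
        f"model {label!r} is not available; bundled models: {available}"
    )


def predict_probability(params: EposModelParams, tct: int, mi: int) -> float:
    """Probability of independent gait at 3 months for one predictor pattern.

    Both predictor components must be present (0 or 1); imputation of missing
    raw scores happens upstream of prediction.
    """
    if tct is None or mi is None:
        raise ValueError(
            "missing predictor component; impute raw scores before prediction"
        )
    if tct not in (0, 1) or mi not in (0, 1):
        raise ValueError(f"predictors must be binary 0/1, got tct={tct}, mi={mi}")
    return 1.0 / (1.0 + math.exp(-params.linear_predictor(tct, mi)))


def predict_probabilities(
    params: EposModelParams, tct: Sequence[int], mi: Sequence[int]
) -> np.ndarray:
    """Vectorized :func:`predict_probability` over aligned binary arrays."""
    tct_arr = np.asarray(tct, dtype=float)
    mi_arr = np.asarray(mi, dtype=float)
    if np.isnan(tct_arr).any() or np.isnan(mi_arr).any():
        raise ValueError(
            "missing predictor component; impute raw scores before prediction"
        )
    if not (np.isin(tct_arr, (0, 1)).all() and np.isin(mi_arr, (0, 1)).all()):
        raise ValueError("predictors must be binary 0/1")
    eta = params.intercept + params.beta_tct * tct_arr + params.beta_mi * mi_arr
    return 1.0 / (1.0 + np.exp(-eta))


def classify(probability: float, threshold: float = 0.5) -> int:
    """Binary classification: 1 iff ``probability >= threshold``.

    The default operating point of 0.5 is the convention of the standard
    confusion-matrix report; it is configurable throughout the pipeline.
    """
    if not (0.0 <= probability <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("probability and threshold must lie in [0, 1]")
    return int(probability >= threshold)


def predict(params: EposModelParams, tct: int, mi: int, threshold: float = 0.5) -> Prediction:
    p = predict_probability(params, tct, mi)
    return Prediction(probability=p, predicted_class=classify(p, threshold), threshold=threshold)


def pattern_probabilities(params: EposModelParams) -> dict[tuple[int, int], float]:
    """The model's four attainable probabilities, keyed by (tct, mi) pattern."""
    return {
        (t, m): predict_probability(params, t, m) for t in (0, 1) for m in (0, 1)
    }
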
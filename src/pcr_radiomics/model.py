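"""The published logistic pCR model.

Linear predictor over four covariates — clinical T and N stage entered as
ordinal integers, plus LoG-filtered skewness and entropy — mapped to a
probability through the logistic link and thresholded at the published
cut-off (0.267).  Coefficient standard deviations are carried as metadata
only; the model is applied, never refitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

from .errors import MissingDataError, SchemaError

_COEF_FIELDS = [
    "intercept",
    "coef_cT",
    "coef_cN",
    "coef_skewness",
    "coef_entropy",
]
_REQUIRED_FIELDS = _COEF_FIELDS + [
    "sd_intercept",
    "sd_cT",
    "sd_cN",
    "sd_skewness",
    "sd_entropy",
    "sigma_entropy_mm",
    "sigma_skewness_mm",
    "threshold",
]

PREDICT_POSITIVE = "predicted-pCR"
PREDICT_NEGATIVE = "predicted-non-pCR"


@dataclass(frozen=True)
class ModelSpec:
    """Coefficients, LoG kernel widths (mm) and decision threshold."""

    intercept: float
    coef_cT: float
    coef_cN: float
    coef_skewness: float
    coef_entropy: float
    sd_intercept: float
    sd_cT: float
    sd_cN: float
    sd_skewness: float
    sd_entropy: float
    sigma_entropy_mm: float
    sigma_skewness_mm: float
    threshold: float

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise SchemaError(f"threshold must lie in (0, 1), got {self.threshold}")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def coefficients(self) -> dict:
        return {k: getattr(self, k) for k in _COEF_FIELDS}


@dataclass
class PatientRecord:
    """One patient's covariates, outcome and (once predicted) model score."""

    id: str
    cT: int
    cN: int
    skewness: float | None = None
    entropy: float | None = None
    field_strength: float | None = None
    pcr_label: int | None = None
    score: float | None = None

    def to_row(self) -> dict:
        return {
            "id": self.id,
            "cT": self.cT,
            "cN": self.cN,
            "field_strength": self.field_strength,
            "skewness": self.skewness,
            "entropy": self.entropy,
            "score": self.score,
            "pcr_label": self.pcr_label,
        }


def _require_finite(rec: PatientRecord, name: str) -> float:
    val = getattr(rec, name)
    if val is None or not math.isfinite(float(val)):
        raise MissingDataError(name)
    return float(val)


def linear_predictor(rec: PatientRecord, spec: ModelSpec) -> float:
    """Log-odds of pCR: intercept + coefficient-weighted covariates."""
    ct = _require_finite(rec, "cT")
    cn = _require_finite(rec, "cN")
    skw = _require_finite(rec, "skewness")
    ent = _require_finite(rec, "entropy")
    return (
        spec.intercept
        + spec.coef_cT * ct
        + spec.coef_cN * cn
        + spec.coef_skewness * skw
        + spec.coef_entropy * ent
    )


def predict_pcr_probability(rec: PatientRecord, spec: ModelSpec) -> float:
    """Probability of pCR through the logistic link, 1/(1+exp(-lp))."""
    lp = linear_predictor(rec, spec)
    # guard against overflow in exp for extreme log-odds
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)


def classify(score: float, spec: ModelSpec) -> str:
    """Binary call at the model threshold; the boundary counts as positive."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    return PREDICT_POSITIVE if score >= spec.threshold else PREDICT_NEGATIVE


def load_model_spec(path) -> ModelSpec:
    """Load a model spec from JSON, validating all required fields."""
    with open(path) as fh:
        payload = json.load(fh)
    missing = [k for k in _REQUIRED_FIELDS if k not in payload]
    if missing:
        raise SchemaError(f"model spec {Path(path).name!r} misses fields {missing}")
    extra = {k for k in payload if k not in _REQUIRED_FIELDS}
    if extra:
        raise SchemaError(f"model spec has unknown fields {sorted(extra)}")
    return ModelSpec(**{k: float(payload[k]) for k in _REQUIRED_FIELDS})


def save_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_model_spec() -> ModelSpec:
    """The packaged published model (coefficients as printed)."""
    ref = resources.files("pcr_radiomics").joinpath("data/original_model.json")
    payload = json.loads(ref.read_text())
    return ModelSpec(**{k: float(payload[k]) for k in _REQUIRED_FIELDS})
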
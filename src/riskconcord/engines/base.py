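"""Shared infrastructure for the nine risk-prediction engines.

Each engine evaluates one published cardiovascular risk equation: a linear
predictor on transformed covariates mapped through the model's published
baseline-survival or logistic form.  Coefficients are not hard-coded in logic;
they live in human-readable YAML registry files (one per model) with
per-entry source citations, so transcription is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources

import yaml

__all__ = [
    "ModelId",
    "RiskEstimate",
    "load_registry",
    "chol_mgdl",
    "tg_mgdl",
    "clamp_risk",
    "MissingInputError",
]

#: documented unit-conversion constants (SI record -> mg/dL equations)
CHOL_MMOL_TO_MGDL = 38.67
TG_MMOL_TO_MGDL = 88.57


class ModelId(str, Enum):
    SCORE2 = "SCORE2"
    PREVENT = "PREVENT"
    PCE = "PCE"
    MESA = "MESA"
    QRISK3 = "QRISK3"
    ASSIGN = "ASSIGN"
    AUSCVD = "AUSCVD"
    FRS_HCHD = "FRS_HCHD"
    RRS = "RRS"


#: models whose prediction horizon is 5 years (all others: 10 years)
FIVE_YEAR_MODELS = frozenset({ModelId.AUSCVD})


def horizon_years(model: ModelId) -> int:
    return 5 if model in FIVE_YEAR_MODELS else 10


class MissingInputError(ValueError):
    """A required input for a specific model is absent from the record."""

    def __init__(self, model: ModelId, field_name: str):
        super().__init__(f"{model.value}: missing required input '{field_name}'")
        self.model = model
        self.field_name = field_name


@dataclass(frozen=True)
class RiskEstimate:
    """One model's predicted risk for one participant.

    ``risk`` is a percentage in [0, 100] over the model's native horizon.
    ``omitted_inputs`` logs every predictor the engine defaulted because the
    registry-style dataset does not carry it (e.g. coronary calcium for MESA,
    deprivation for ASSIGN, postcode terms for AusCVDRisk/PREVENT).
    """

    model: ModelId
    horizon: int
    risk: float
    omitted_inputs: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.risk <= 100.0):
            raise ValueError(f"risk {self.risk} outside [0, 100]")
        if self.horizon != horizon_years(self.model):
            raise ValueError(
                f"{self.model.value}: horizon {self.horizon} does not match model"
            )


@lru_cache(maxsize=None)
def load_registry(model: ModelId) -> dict:
    """Load the coefficient registry file for one model."""
    name = f"{model.value.lower()}.yaml"
    text = resources.files("riskconcord.engines.registry").joinpath(name).read_text()
    doc = yaml.safe_load(text)
    if not doc.get("source"):
        raise ValueError(f"registry for {model.value} lacks a source citation")
    return doc


def chol_mgdl(mmol: float) -> float:
    return mmol * CHOL_MMOL_TO_MGDL


def tg_mgdl(mmol: float) -> float:
    return mmol * TG_MMOL_TO_MGDL


def clamp_risk(percent: float) -> float:
    return min(100.0, max(0.0, float(percent)))
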
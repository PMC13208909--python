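"""Unified scoring interface over the nine cardiovascular risk engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cohort import ParticipantRecord
from .base import (
    MissingInputError,
    ModelId,
    RiskEstimate,
    horizon_years,
    load_registry,
)
from .equations import ENGINES

__all__ = [
    "ModelId",
    "RiskEstimate",
    "MissingInputError",
    "score",
    "score_all",
    "RiskTable",
    "list_model_metadata",
    "MODEL_ORDER",
]

#: canonical column order for risk and eligibility tables
MODEL_ORDER = tuple(m.value for m in ModelId)


def score(model: ModelId | str, record: ParticipantRecord, **kwargs) -> RiskEstimate:
    """Score one record with one model; raises on unknown model or missing
    required input."""
    model = ModelId(model)
    return ENGINES[model](record, **kwargs)


@dataclass
class RiskTable:
    """Risks for a cohort: one row per participant, one column per model,
    percent over each model's native horizon (5 y for AusCVDRisk, 10 y
    otherwise).  Per-cell failures are isolated into ``failures`` and the
    corresponding cell is NaN."""

    risks: pd.DataFrame
    sex: pd.Series
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return list(self.risks.index)


def score_all(cohort: list[ParticipantRecord]) -> RiskTable:
    """Score every record with all nine models, preserving row order."""
    rows = {}
    failures: list[tuple[str, str, str]] = []
    for rec in cohort:
        row = {}
        for model in ModelId:
            try:
                row[model.value] = ENGINES[model](rec).risk
            except Exception as exc:  # isolate per-cell failure, never crash
                row[model.value] = np.nan
                failures.append((rec.id, model.value, str(exc)))
        rows[rec.id] = row
    risks = pd.DataFrame.from_dict(rows, orient="index", columns=list(MODEL_ORDER))
    risks.index.name = "id"
    sex = pd.Series([r.sex.value for r in cohort], index=risks.index, name="sex")
    return RiskTable(risks=risks, sex=sex, failures=failures)


def list_model_metadata() -> pd.DataFrame:
    """Nine rows: model, horizon, outcome label, predictor list, source."""
    rows = []
    for model in ModelId:
        reg = load_registry(model)
        rows.append(
            {
                "model": model.value,
                "horizon_years": horizon_years(model),
                "outcome": reg["outcome"],
                "predictors": ", ".join(reg["predictors"]),
                "source": " ".join(reg["source"].split()),
            }
        )
    return pd.DataFrame(rows).set_index("model")
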
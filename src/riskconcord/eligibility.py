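"""Decision-level statin eligibility: risks -> binary decisions.

A participant is "statin-eligible" under a model when the calculated risk
meets or exceeds that model's guideline-mapped treatment threshold.  The
threshold policy is either a constant cut-point or an ordered set of age
bands, and is configuration-driven: the shipped defaults carry per-entry
source annotations and every report prints the active policy set.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .engines import MODEL_ORDER, ModelId, RiskTable

__all__ = [
    "ThresholdPolicy",
    "load_threshold_policies",
    "default_policies",
    "policy_fingerprint",
    "EligibilityMatrix",
    "classify_eligibility",
    "eligibility_rates",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Eligibility rule for one model: constant cut-point or ordered age
    bands, comparator always meets-or-exceeds."""

    model: ModelId
    #: ordered (lo, hi, cut) bands partitioning the eligible age range;
    #: a constant rule is a single band spanning all ages
    bands: tuple[tuple[float, float, float], ...]
    source: str = ""

    def __post_init__(self):
        if not self.bands:
            raise ValueError(f"{self.model.value}: empty threshold policy")
        prev_hi = None
        for lo, hi, cut in self.bands:
            if not (0.0 < cut < 100.0):
                raise ValueError(f"{self.model.value}: cut-point {cut} outside (0, 100)")
            if hi <= lo:
                raise ValueError(f"{self.model.value}: malformed band [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError(f"{self.model.value}: bands overlap or leave gaps")
            prev_hi = hi

    @classmethod
    def constant(cls, model: ModelId, cut: float, source: str = "") -> "ThresholdPolicy":
        return cls(model=model, bands=((0.0, 200.0, cut),), source=source)

    def cut_for_age(self, age: float) -> float:
        """Cut-point for a participant, selected by age in whole (truncated)
        years -- calculators take whole years."""
        whole = math.floor(age)
        for lo, hi, cut in self.bands:
            if lo <= whole < hi:
                return cut
        raise ValueError(f"{self.model.value}: age {age} outside all policy bands")

    def describe(self) -> dict:
        if len(self.bands) == 1:
            rule = {"constant": self.bands[0][2]}
        else:
            rule = {"bands": [{"lo": lo, "hi": hi, "cut": cut} for lo, hi, cut in self.bands]}
        return {"model": self.model.value, **rule, "source": self.source}


def _parse_policy(model: ModelId, spec: dict) -> ThresholdPolicy:
    source = spec.get("source", "")
    if "constant" in spec:
        return ThresholdPolicy.constant(model, float(spec["constant"]), source)
    if "bands" in spec:
        bands = tuple(
            (float(b["lo"]), float(b["hi"]), float(b["cut"])) for b in spec["bands"]
        )
        return ThresholdPolicy(model=model, bands=bands, source=source)
    raise ValueError(f"{model.value}: policy needs 'constant' or 'bands'")


def load_threshold_policies(config: dict | str | None = None) -> dict[ModelId, ThresholdPolicy]:
    """Load the nine threshold policies.

    ``config`` may be None (shipped defaults), a path to a YAML file, or an
    already-parsed mapping.  Overrides are merged model-by-model onto the
    defaults; a missing model or malformed band raises.
    """
    text = resources.files("riskconcord.data").joinpath("threshold_policies.yaml").read_text()
    doc = yaml.safe_load(text)["policies"]
    if config is not None:
        if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
            with open(config) as fh:
                override = yaml.safe_load(fh)
        else:
            override = config
        override = override.get("policies", override)
        for name, spec in override.items():
            ModelId(name)  # raises on unknown model
            doc[name] = spec
    policies = {}
    for model in ModelId:
        if model.value not in doc:
            raise ValueError(f"no threshold policy for model {model.value}")
        policies[model] = _parse_policy(model, doc[model.value])
    return policies


def default_policies() -> dict[ModelId, ThresholdPolicy]:
    return load_threshold_policies(None)


def policy_fingerprint(policies: dict[ModelId, ThresholdPolicy]) -> str:
    """Stable hash of the active policy set (canonical-JSON SHA-256)."""
    doc = [policies[m].describe() for m in ModelId]
    blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class EligibilityMatrix:
    """n x 9 binary decisions with ids, sex labels and the policy fingerprint."""

    decisions: pd.DataFrame  # bool, columns = MODEL_ORDER, index = ids
    sex: pd.Series
    fingerprint: str

    @property
    def ids(self) -> list[str]:
        return list(self.decisions.index)

    def __post_init__(self):
        if list(self.decisions.columns) != list(MODEL_ORDER):
            raise ValueError("decision columns must be the nine models in canonical order")
        if not self.decisions.index.equals(self.sex.index):
            raise ValueError("sex vector misaligned with decisions")


def classify_eligibility(
    risks: RiskTable,
    policies: dict[ModelId, ThresholdPolicy],
    ages: pd.Series | np.ndarray,
) -> EligibilityMatrix:
    """Apply the threshold policies to a risk table.

    decision = (risk >= applicable cut-point); the cut-point is selected by
    the participant's age band where the policy is banded.  Deterministic;
    NaN risks (flagged scoring failures) yield ineligible with no exception.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(risks.risks):
        raise ValueError("ages misaligned with risk table")
    decisions = {}
    for model in ModelId:
        policy = policies[model]
        cuts = np.array([policy.cut_for_age(a) for a in ages])
        col = risks.risks[model.value].to_numpy(dtype=float)
        decisions[model.value] = np.where(np.isnan(col), False, col >= cuts)
    df = pd.DataFrame(decisions, index=risks.risks.index, columns=list(MODEL_ORDER))
    return EligibilityMatrix(
        decisions=df.astype(bool),
        sex=risks.sex,
        fingerprint=policy_fingerprint(policies),
    )


def eligibility_rates(matrix: EligibilityMatrix, strata: str = "both") -> pd.DataFrame:
    """Per-model eligibility counts and percentages, overall and/or by sex.

    percent = 100 * count / stratum size, reported to 2 decimals.
    """
    if len(matrix.decisions) == 0:
        raise ValueError("empty eligibility matrix")
    wanted = {"overall": ["overall"], "by_sex": ["female", "male"],
              "both": ["overall", "female", "male"]}[strata]
    rows = []
    for stratum in wanted:
        if stratum == "overall":
            sub = matrix.decisions
        else:
            mask = (matrix.sex.astype(str) == stratum).to_numpy()
            sub = matrix.decisions.loc[mask]
        if len(sub) == 0:
            raise ValueError(f"empty stratum {stratum!r}")
        for model in MODEL_ORDER:
            count = int(sub[model].sum())
            rows.append(
                {
                    "model": model,
                    "stratum": stratum,
                    "count": count,
                    "denominator": len(sub),
                    "percent": round(100.0 * count / len(sub), 2),
                }
            )
    return pd.DataFrame(rows)
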
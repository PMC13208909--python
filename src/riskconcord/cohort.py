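"""Participant data model, record validation and metabolic-syndrome classification.

The analysis population is a primary-prevention cohort of adults aged 40-65
years, every one of whom satisfies the updated NCEP ATP III definition of the
metabolic syndrome (at least three of five criteria on blood pressure, central
adiposity, HDL cholesterol, triglycerides and glycemia).  This module defines
the per-participant record in SI clinical units, validates records against the
inclusion criteria and the input requirements of all nine risk engines, and
implements the MetS classifier with the printed inequality directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "Smoking",
    "ParticipantRecord",
    "MetSFlags",
    "classify_mets",
    "validate_record",
    "cohort_to_frame",
    "frame_to_cohort",
    "read_cohort",
    "write_cohort",
    "load_cohort_schema",
    "validate_cohort_frame",
    "EXTRA_FLAGS",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Smoking(str, Enum):
    CURRENT = "current"
    EX = "ex"
    NEVER = "never"


#: Optional predictors used only by QRISK3; absent (False) by default because the
#: source registry did not record them.
EXTRA_FLAGS = (
    "corticosteroids",
    "migraine",
    "atypical_antipsychotics",
    "sle",
    "severe_mental_illness",
    "erectile_dysfunction",
)

# Continuous fields that must be strictly positive and present for scoring.
_CONTINUOUS_REQUIRED = (
    "age", "sbp", "dbp", "waist", "bmi", "tc", "ldl", "hdl", "tg",
    "glucose", "creatinine", "egfr", "crp",
)

_BOOL_FIELDS = (
    "diabetes", "htn_dx", "htn_treated", "lipid_treated", "antiplatelet",
    "family_history_premature_cvd",
)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's predictors, in SI clinical units.

    Lipids and glucose are in mmol/L, creatinine in umol/L, CRP in mg/L, blood
    pressure in mmHg, waist in cm, BMI in kg/m^2, eGFR in mL/min/1.73m^2 and
    uACR in mg/g (optional; no implemented engine requires it).

    ``lipid_treated`` doubles as the triglyceride-lowering-therapy flag in the
    MetS classifier: the source registry does not distinguish fibrates from
    statins, so any lipid-lowering pharmacotherapy satisfies the TG criterion's
    treatment arm.
    """

    id: str
    sex: Sex
    age: float
    sbp: float
    dbp: float
    waist: float
    bmi: float
    tc: float
    ldl: float
    hdl: float
    tg: float
    glucose: float
    creatinine: float
    egfr: float
    crp: float
    smoking: Smoking
    diabetes: bool
    htn_dx: bool
    htn_treated: bool
    lipid_treated: bool
    antiplatelet: bool
    family_history_premature_cvd: bool
    uacr: float | None = None
    extras: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "smoking", Smoking(self.smoking))
        unknown = set(self.extras) - set(EXTRA_FLAGS)
        if unknown:
            raise ValueError(f"unknown extra flags: {sorted(unknown)}")
        object.__setattr__(self, "extras", frozenset(self.extras))

    def has_extra(self, name: str) -> bool:
        if name not in EXTRA_FLAGS:
            raise KeyError(name)
        return name in self.extras

    def with_(self, **changes) -> "ParticipantRecord":
        """Return a copy with the given fields replaced (test/CLI convenience)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class MetSFlags:
    """Outcome of the NCEP ATP III metabolic-syndrome classification."""

    bp_flag: bool
    waist_flag: bool
    hdl_flag: bool
    tg_flag: bool
    glycemia_flag: bool

    @property
    def count(self) -> int:
        return sum(
            (self.bp_flag, self.waist_flag, self.hdl_flag, self.tg_flag,
             self.glycemia_flag)
        )

    @property
    def mets(self) -> bool:
        return self.count >= 3


def classify_mets(record: ParticipantRecord) -> MetSFlags:
    """Classify a record against the updated NCEP ATP III criteria.

    Cut-points (inequality directions as printed in the criteria):

    * blood pressure: SBP >= 130 mmHg or DBP >= 85 mmHg, or a documented
      hypertension diagnosis;
    * central adiposity: waist >= 88 cm (women) / >= 102 cm (men);
    * HDL-C: strictly < 1.29 mmol/L (women) / < 1.03 mmol/L (men);
    * triglycerides: >= 1.7 mmol/L or on TG-lowering pharmacotherapy
      (approximated by ``lipid_treated``);
    * glycemia: fasting glucose >= 5.6 mmol/L or diagnosed diabetes.

    MetS requires at least three criteria.
    """
    for name in ("waist", "hdl", "tg", "sbp", "dbp", "glucose"):
        if getattr(record, name) is None:
            raise ValueError(f"MetS classification requires field '{name}'")
    female = record.sex is Sex.FEMALE
    return MetSFlags(
        bp_flag=record.sbp >= 130 or record.dbp >= 85 or record.htn_dx,
        waist_flag=record.waist >= (88 if female else 102),
        hdl_flag=record.hdl < (1.29 if female else 1.03),
        tg_flag=record.tg >= 1.7 or record.lipid_treated,
        glycemia_flag=record.glucose >= 5.6 or record.diabetes,
    )


def validate_record(record: ParticipantRecord) -> list[str]:
    """Return a list of human-readable issues; empty iff the record is usable.

    Checks the inclusion-range invariant (age 40-65), strict positivity of all
    continuous measurements, the physical constraint HDL <= TC, and presence of
    every field any of the nine risk engines needs.  Issues are returned, not
    raised, so callers can report all problems at once.
    """
    issues: list[str] = []
    if not record.id:
        issues.append("id: empty participant id")
    for name in _CONTINUOUS_REQUIRED:
        value = getattr(record, name)
        if value is None:
            issues.append(f"{name}: missing value required for risk estimation")
        elif not value > 0:
            issues.append(f"{name}: must be strictly positive, got {value!r}")
    if record.age is not None and not (40 <= record.age <= 65):
        issues.append(f"age: {record.age} out of 40-65 inclusion range")
    if record.uacr is not None and not record.uacr > 0:
        issues.append(f"uacr: must be strictly positive when present, got {record.uacr!r}")
    if (
        record.tc is not None
        and record.hdl is not None
        and record.hdl > record.tc
    ):
        issues.append("hdl: HDL exceeds total cholesterol")
    return issues


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    ["id", "sex", "age", "sbp", "dbp", "waist", "bmi", "tc", "ldl", "hdl",
     "tg", "glucose", "creatinine", "egfr", "crp", "uacr", "smoking"]
    + list(_BOOL_FIELDS)
    + list(EXTRA_FLAGS)
)


def load_cohort_schema() -> dict:
    """Load the cohort-CSV schema document shipped with the package."""
    text = resources.files("riskconcord.data").joinpath("cohort_schema.json").read_text()
    return json.loads(text)


def validate_cohort_frame(df: pd.DataFrame) -> None:
    """Enforce the shipped schema on a cohort table; raises ValueError on breach."""
    schema = load_cohort_schema()
    problems: list[str] = []
    for col, rule in schema["columns"].items():
        if col not in df.columns:
            if rule.get("required", True):
                problems.append(f"missing required column '{col}'")
            continue
        series = df[col]
        if rule["type"] == "number":
            values = pd.to_numeric(series, errors="coerce")
            bad = values.isna() & series.notna()
            if rule.get("required", True) and series.isna().any():
                problems.append(f"column '{col}': missing values")
            if bad.any():
                problems.append(f"column '{col}': non-numeric values")
            lo, hi = rule.get("min"), rule.get("max")
            if lo is not None and (values.dropna() < lo).any():
                problems.append(f"column '{col}': values below {lo}")
            if hi is not None and (values.dropna() > hi).any():
                problems.append(f"column '{col}': values above {hi}")
        elif rule["type"] == "enum":
            bad = ~series.isin(rule["values"])
            if bad.any():
                problems.append(
                    f"column '{col}': values outside {rule['values']}"
                )
        elif rule["type"] == "flag":
            if not series.isin([0, 1, True, False]).all():
                problems.append(f"column '{col}': flags must be 0/1")
    if problems:
        raise ValueError("cohort table violates schema: " + "; ".join(problems))


def cohort_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _CSV_COLUMNS if hasattr(r, name)}
        row["sex"] = r.sex.value
        row["smoking"] = r.smoking.value
        for b in _BOOL_FIELDS:
            row[b] = int(getattr(r, b))
        for e in EXTRA_FLAGS:
            row[e] = int(e in r.extras)
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[ParticipantRecord]:
    validate_cohort_frame(df)
    records = []
    for row in df.to_dict("records"):
        uacr = row.get("uacr")
        extras = frozenset(e for e in EXTRA_FLAGS if bool(int(row.get(e, 0) or 0)))
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                sex=Sex(row["sex"]),
                age=float(row["age"]),
                sbp=float(row["sbp"]),
                dbp=float(row["dbp"]),
                waist=float(row["waist"]),
                bmi=float(row["bmi"]),
                tc=float(row["tc"]),
                ldl=float(row["ldl"]),
                hdl=float(row["hdl"]),
                tg=float(row["tg"]),
                glucose=float(row["glucose"]),
                creatinine=float(row["creatinine"]),
                egfr=float(row["egfr"]),
                crp=float(row["crp"]),
                uacr=None if uacr is None or pd.isna(uacr) else float(uacr),
                smoking=Smoking(row["smoking"]),
                **{b: bool(int(row[b])) for b in _BOOL_FIELDS},
                extras=extras,
            )
        )
    return records


def write_cohort(records: Sequence[ParticipantRecord], path) -> None:
    """Write a cohort CSV conforming to the shipped schema (lossless round-trip)."""
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> list[ParticipantRecord]:
    """Read and schema-validate a cohort CSV (``#`` lines are comments)."""
    df = pd.read_csv(path, comment="#")
    return frame_to_cohort(df)
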
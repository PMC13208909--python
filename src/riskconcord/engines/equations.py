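"""The nine published risk equations.

Every function takes a validated :class:`~riskconcord.cohort.ParticipantRecord`
and returns a :class:`RiskEstimate` in percent over the model's native
horizon, using the sex-specific coefficient set from the YAML registry.
Paper-mandated input omissions (no coronary calcium for MESA, deprivation at
reference for ASSIGN, no postcode terms for PREVENT/AusCVDRisk, QRISK3 inputs
the registry lacks) are logged in ``omitted_inputs`` rather than silently
dropped.
"""

from __future__ import annotations

import math

from ..cohort import ParticipantRecord, Sex, Smoking
from .base import (
    MissingInputError,
    ModelId,
    RiskEstimate,
    chol_mgdl,
    clamp_risk,
    load_registry,
)

__all__ = ["ENGINES"]


def _require(record: ParticipantRecord, model: ModelId, *names: str) -> None:
    for name in names:
        if getattr(record, name) is None:
            raise MissingInputError(model, name)


def _sex_block(registry: dict, record: ParticipantRecord) -> dict:
    return registry["female" if record.sex is Sex.FEMALE else "male"]


# ---------------------------------------------------------------------------
# SCORE2
# ---------------------------------------------------------------------------

def score_score2(record: ParticipantRecord, region: str | None = None) -> RiskEstimate:
    """SCORE2 10-year CVD risk with region recalibration (default: the
    very-high-risk European region, which includes Lithuania)."""
    reg = load_registry(ModelId.SCORE2)
    _require(record, ModelId.SCORE2, "age", "sbp", "tc", "hdl")
    blk = _sex_block(reg, record)
    t = blk["terms"]
    cage = (record.age - 60.0) / 5.0
    csbp = (record.sbp - 120.0) / 20.0
    ctc = record.tc - 6.0
    chdl = (record.hdl - 1.3) / 0.5
    smoker = 1.0 if record.smoking is Smoking.CURRENT else 0.0
    lp = (
        t["cage"] * cage
        + t["smoker"] * smoker
        + t["csbp"] * csbp
        + t["ctc"] * ctc
        + t["chdl"] * chdl
        + t["smoker_x_cage"] * smoker * cage
        + t["csbp_x_cage"] * csbp * cage
        + t["ctc_x_cage"] * ctc * cage
        + t["chdl_x_cage"] * chdl * cage
    )
    uncal = 1.0 - blk["baseline_survival_10y"] ** math.exp(lp)
    region = region or reg["default_region"]
    scale1, scale2 = reg["recalibration"][region][record.sex.value]
    cal = 1.0 - math.exp(-math.exp(scale1 + scale2 * math.log(-math.log(1.0 - uncal))))
    return RiskEstimate(
        model=ModelId.SCORE2,
        horizon=10,
        risk=clamp_risk(100.0 * cal),
        warnings=(f"region recalibration: {region}",),
    )


# ---------------------------------------------------------------------------
# PCE
# ---------------------------------------------------------------------------

def score_pce(record: ParticipantRecord, race: str | None = None) -> RiskEstimate:
    """Pooled Cohort Equations 10-year hard ASCVD risk (White branch default)."""
    reg = load_registry(ModelId.PCE)
    _require(record, ModelId.PCE, "age", "sbp", "tc", "hdl")
    race = race or reg["default_race"]
    blk = reg[race]["female" if record.sex is Sex.FEMALE else "male"]
    t = blk["terms"]
    ln_age = math.log(record.age)
    ln_tc = math.log(chol_mgdl(record.tc))
    ln_hdl = math.log(chol_mgdl(record.hdl))
    ln_sbp = math.log(record.sbp)
    smoker = 1.0 if record.smoking is Smoking.CURRENT else 0.0
    treated = record.htn_treated
    lp = (
        t.get("ln_age", 0.0) * ln_age
        + t.get("ln_age_sq", 0.0) * ln_age**2
        + t.get("ln_tc", 0.0) * ln_tc
        + t.get("ln_age_x_ln_tc", 0.0) * ln_age * ln_tc
        + t.get("ln_hdl", 0.0) * ln_hdl
        + t.get("ln_age_x_ln_hdl", 0.0) * ln_age * ln_hdl
        + t.get("smoker", 0.0) * smoker
        + t.get("ln_age_x_smoker", 0.0) * ln_age * smoker
        + t.get("diabetes", 0.0) * record.diabetes
    )
    if treated:
        lp += t.get("ln_sbp_treated", 0.0) * ln_sbp
        lp += t.get("ln_age_x_ln_sbp_treated", 0.0) * ln_age * ln_sbp
    else:
        lp += t.get("ln_sbp_untreated", 0.0) * ln_sbp
        lp += t.get("ln_age_x_ln_sbp_untreated", 0.0) * ln_age * ln_sbp
    risk = 1.0 - blk["baseline_survival_10y"] ** math.exp(lp - blk["mean_lp"])
    return RiskEstimate(
        model=ModelId.PCE,
        horizon=10,
        risk=clamp_risk(100.0 * risk),
        warnings=(f"race branch: {race}",),
    )


# ---------------------------------------------------------------------------
# PREVENT (base model)
# ---------------------------------------------------------------------------

def score_prevent(record: ParticipantRecord) -> RiskEstimate:
    """AHA PREVENT base-model 10-year total CVD risk (no ZIP-linked index)."""
    reg = load_registry(ModelId.PREVENT)
    _require(record, ModelId.PREVENT, "age", "sbp", "tc", "hdl", "egfr")
    t = _sex_block(reg, record)["terms"]
    intercept = _sex_block(reg, record)["intercept"]
    c_age = (record.age - 55.0) / 10.0
    c_nonhdl = (record.tc - record.hdl) - 3.5
    c_hdl = (record.hdl - 1.3) / 0.3
    c_sbp_lo = (min(record.sbp, 110.0) - 110.0) / 20.0
    c_sbp_hi = (max(record.sbp, 110.0) - 130.0) / 20.0
    c_egfr_lo = (min(record.egfr, 60.0) - 60.0) / -15.0
    c_egfr_hi = (max(record.egfr, 60.0) - 90.0) / -15.0
    smoker = 1.0 if record.smoking is Smoking.CURRENT else 0.0
    antihtn = float(record.htn_treated)
    statin = float(record.lipid_treated)
    lp = (
        intercept
        + t["c_age"] * c_age
        + t["c_nonhdl"] * c_nonhdl
        + t["c_hdl"] * c_hdl
        + t["c_sbp_lo"] * c_sbp_lo
        + t["c_sbp_hi"] * c_sbp_hi
        + t["diabetes"] * record.diabetes
        + t["smoker"] * smoker
        + t["c_egfr_lo"] * c_egfr_lo
        + t["c_egfr_hi"] * c_egfr_hi
        + t["antihtn"] * antihtn
        + t["statin"] * statin
        + t["antihtn_x_sbp_hi"] * antihtn * c_sbp_hi
        + t["statin_x_nonhdl"] * statin * c_nonhdl
        + t["age_x_nonhdl"] * c_age * c_nonhdl
        + t["age_x_hdl"] * c_age * c_hdl
        + t["age_x_sbp_hi"] * c_age * c_sbp_hi
        + t["age_x_diabetes"] * c_age * record.diabetes
        + t["age_x_smoker"] * c_age * smoker
        + t["age_x_egfr_lo"] * c_age * c_egfr_lo
    )
    risk = 100.0 / (1.0 + math.exp(-lp))
    return RiskEstimate(
        model=ModelId.PREVENT,
        horizon=10,
        risk=clamp_risk(risk),
        omitted_inputs=("area_deprivation_index(ZIP)",),
    )


# ---------------------------------------------------------------------------
# MESA (no-CAC variant)
# ---------------------------------------------------------------------------

def score_mesa(record: ParticipantRecord) -> RiskEstimate:
    """MESA 10-year CHD risk, risk-factors-only (no-CAC) equation."""
    reg = load_registry(ModelId.MESA)
    _require(record, ModelId.MESA, "age", "sbp", "tc", "hdl")
    t = reg["terms"]
    lp = (
        t["age"] * record.age
        + t["male"] * (record.sex is Sex.MALE)
        + t["diabetes"] * record.diabetes
        + t["smoker"] * (record.smoking is Smoking.CURRENT)
        + t["tc_mgdl"] * chol_mgdl(record.tc)
        + t["hdl_mgdl"] * chol_mgdl(record.hdl)
        + t["lipid_med"] * record.lipid_treated
        + t["sbp"] * record.sbp
        + t["bp_med"] * record.htn_treated
        + t["family_history"] * record.family_history_premature_cvd
    )
    risk = 1.0 - reg["baseline_survival_factor"] ** math.exp(lp)
    return RiskEstimate(
        model=ModelId.MESA,
        horizon=10,
        risk=clamp_risk(100.0 * risk),
        omitted_inputs=("coronary_artery_calcium(no-CAC variant)",),
        warnings=("ethnicity at non-Hispanic White reference",),
    )


# ---------------------------------------------------------------------------
# QRISK3
# ---------------------------------------------------------------------------

def score_qrisk3(record: ParticipantRecord) -> RiskEstimate:
    """QRISK3 10-year CVD risk (main-effects transcription; see registry
    provenance for the documented reductions)."""
    reg = load_registry(ModelId.QRISK3)
    _require(record, ModelId.QRISK3, "age", "sbp", "tc", "hdl", "bmi")
    blk = _sex_block(reg, record)
    t, centers = blk["terms"], blk["centers"]
    dage = record.age / 10.0
    dbmi = record.bmi / 10.0
    if record.sex is Sex.FEMALE:
        age_1, age_2 = dage**-2, dage
    else:
        age_1, age_2 = dage**-1, dage**3
    bmi_1 = dbmi**-2
    bmi_2 = dbmi**-2 * math.log(dbmi)
    rati = record.tc / record.hdl
    lp = (
        t["age_1"] * (age_1 - centers["age_1"])
        + t["age_2"] * (age_2 - centers["age_2"])
        + t["bmi_1"] * (bmi_1 - centers["bmi_1"])
        + t["bmi_2"] * (bmi_2 - centers["bmi_2"])
        + t["rati"] * (rati - centers["rati"])
        + t["sbp"] * (record.sbp - centers["sbp"])
    )
    if record.smoking is Smoking.CURRENT:
        lp += t["smoke_current"]
    elif record.smoking is Smoking.EX:
        lp += t["smoke_ex"]
    lp += t["type2_diabetes"] * record.diabetes
    lp += t["bp_treatment"] * record.htn_treated
    lp += t["family_history"] * record.family_history_premature_cvd
    extras_used = []
    for flag, term in (
        ("migraine", "migraine"),
        ("corticosteroids", "corticosteroids"),
        ("sle", "sle"),
        ("severe_mental_illness", "severe_mental_illness"),
        ("atypical_antipsychotics", "atypical_antipsychotics"),
        ("erectile_dysfunction", "erectile_dysfunction"),
    ):
        if record.has_extra(flag):
            lp += t[term]
            extras_used.append(flag)
    risk = 1.0 - blk["baseline_survival_10y"] ** math.exp(lp)
    omitted = ["ethnicity(White reference)", "townsend_deprivation(reference)",
               "sbp_variability(not entered)"]
    omitted += [f"{f}(defaulted absent)" for f in
                ("migraine", "corticosteroids", "sle", "severe_mental_illness",
                 "atypical_antipsychotics", "erectile_dysfunction")
                if f not in extras_used]
    warn = ()
    if record.smoking is Smoking.CURRENT:
        warn = ("cigarettes/day unknown; current smoker scored as moderate (10-19/day)",)
    return RiskEstimate(
        model=ModelId.QRISK3,
        horizon=10,
        risk=clamp_risk(100.0 * risk),
        omitted_inputs=tuple(omitted),
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# ASSIGN
# ---------------------------------------------------------------------------

def score_assign(record: ParticipantRecord) -> RiskEstimate:
    """ASSIGN 10-year CVD risk; deprivation (SIMD) held at the SHHEC mean."""
    reg = load_registry(ModelId.ASSIGN)
    _require(record, ModelId.ASSIGN, "age", "sbp", "tc", "hdl")
    blk = _sex_block(reg, record)
    t, means = blk["terms"], blk["means"]
    cpd = reg["cigarettes_per_day_current"] if record.smoking is Smoking.CURRENT else 0.0
    values = {
        "age": record.age,
        "tc": record.tc,
        "hdl": record.hdl,
        "sbp": record.sbp,
        "diabetes": float(record.diabetes),
        "family_history": float(record.family_history_premature_cvd),
        "cpd": cpd,
        "simd": means["simd"],  # deprivation not applicable: reference value
    }
    lp = sum(t[k] * (values[k] - means[k]) for k in t)
    risk = 1.0 - blk["baseline_survival_10y"] ** math.exp(lp)
    return RiskEstimate(
        model=ModelId.ASSIGN,
        horizon=10,
        risk=clamp_risk(100.0 * risk),
        omitted_inputs=("simd_deprivation(reference value)",),
    )


# ---------------------------------------------------------------------------
# AusCVDRisk (PREDICT-derived)
# ---------------------------------------------------------------------------

def score_auscvd(record: ParticipantRecord) -> RiskEstimate:
    """AusCVDRisk 5-year CVD risk (PREDICT-1 equation; postcode terms at
    reference)."""
    reg = load_registry(ModelId.AUSCVD)
    _require(record, ModelId.AUSCVD, "age", "sbp", "tc", "hdl")
    blk = _sex_block(reg, record)
    t, c = blk["terms"], blk["centers"]
    cage = record.age - c["age"]
    csbp = record.sbp - c["sbp"]
    cratio = record.tc / record.hdl - c["ratio"]
    smoker = record.smoking is Smoking.CURRENT
    exsmoker = record.smoking is Smoking.EX
    lp = (
        t["age"] * cage
        + t["exsmoker"] * exsmoker
        + t["smoker"] * smoker
        + t["family_history"] * record.family_history_premature_cvd
        + t["af"] * 0.0  # atrial fibrillation: registry cohort excludes arrhythmias
        + t["diabetes"] * record.diabetes
        + t["sbp"] * csbp
        + t["ratio"] * cratio
        + t["lipid_med"] * record.lipid_treated
        + t["bp_med"] * record.htn_treated
        + t["antithrombotic"] * record.antiplatelet
        + t["age_x_diabetes"] * cage * record.diabetes
        + t["age_x_sbp"] * cage * csbp
        + t["bpmed_x_sbp"] * csbp * record.htn_treated
    )
    risk = 1.0 - blk["baseline_survival_5y"] ** math.exp(lp)
    return RiskEstimate(
        model=ModelId.AUSCVD,
        horizon=5,
        risk=clamp_risk(100.0 * risk),
        omitted_inputs=("postcode_SEIFA(reference)", "ethnicity(reference)"),
    )


# ---------------------------------------------------------------------------
# FRS-hCHD (ATP III point tables)
# ---------------------------------------------------------------------------

def _band_index(age: float, bands: list[list[float]]) -> int:
    for i, (lo, hi) in enumerate(bands):
        if lo <= age < hi:
            return i
    return len(bands) - 1 if age >= bands[-1][0] else 0


def score_frs_hchd(record: ParticipantRecord) -> RiskEstimate:
    """Framingham hard-CHD 10-year risk via the ATP III point tables.

    The model has no diabetes input; diabetic participants are scored with
    the same tables (see registry provenance).
    """
    reg = load_registry(ModelId.FRS_HCHD)
    _require(record, ModelId.FRS_HCHD, "age", "sbp", "tc", "hdl")
    blk = _sex_block(reg, record)
    age = record.age
    band = _band_index(age, reg["age_bands"])
    # decade group for TC/smoking points: 20-39 -> 0, 40-49 -> 1, ..., 70-79 -> 4
    decade = 0 if age < 40 else min((int(age) - 30) // 10, 4)
    points = blk["age_points"][band]
    tc = chol_mgdl(record.tc)
    tc_band = 0 if tc < 160 else 1 if tc < 200 else 2 if tc < 240 else 3 if tc < 280 else 4
    points += blk["tc_points"][tc_band][decade]
    if record.smoking is Smoking.CURRENT:
        points += blk["smoker_points"][decade]
    hdl = chol_mgdl(record.hdl)
    hp = blk["hdl_points"]
    points += (hp["ge60"] if hdl >= 60 else hp["b50_59"] if hdl >= 50
               else hp["b40_49"] if hdl >= 40 else hp["lt40"])
    sp = blk["sbp_points"]["treated" if record.htn_treated else "untreated"]
    sbp = record.sbp
    points += (sp["lt120"] if sbp < 120 else sp["b120_129"] if sbp < 130
               else sp["b130_139"] if sbp < 140 else sp["b140_159"] if sbp < 160
               else sp["ge160"])
    risk = 0.5  # "<1%" carried as 0.5
    for min_pts, pct in blk["risk_map"]:
        if points >= min_pts:
            risk = float(pct)
    warn = ()
    if record.diabetes:
        warn = ("model has no diabetes input; scored with the standard tables",)
    return RiskEstimate(
        model=ModelId.FRS_HCHD, horizon=10, risk=clamp_risk(risk), warnings=warn
    )


# ---------------------------------------------------------------------------
# Reynolds Risk Score
# ---------------------------------------------------------------------------

def score_rrs(record: ParticipantRecord) -> RiskEstimate:
    """Reynolds Risk Score 10-year risk (women 2007 / men 2008 equations);
    requires hsCRP."""
    reg = load_registry(ModelId.RRS)
    _require(record, ModelId.RRS, "age", "sbp", "tc", "hdl", "crp")
    blk = _sex_block(reg, record)
    t = blk["terms"]
    smoker = 1.0 if record.smoking is Smoking.CURRENT else 0.0
    fh = float(record.family_history_premature_cvd)
    omitted: tuple[str, ...] = ()
    if record.sex is Sex.FEMALE:
        b = (
            t["age"] * record.age
            + t["ln_sbp"] * math.log(record.sbp)
            + t["ln_crp"] * math.log(record.crp)
            + t["ln_tc"] * math.log(chol_mgdl(record.tc))
            + t["ln_hdl"] * math.log(chol_mgdl(record.hdl))
            + t["smoker"] * smoker
            + t["family_history"] * fh
        )
        if record.diabetes:
            b += t["hba1c_if_diabetic"] * reg["hba1c_percent_if_diabetic"]
            omitted = (f"hba1c(defaulted {reg['hba1c_percent_if_diabetic']}% for diabetic)",)
    else:
        b = (
            t["ln_age"] * math.log(record.age)
            + t["ln_sbp"] * math.log(record.sbp)
            + t["ln_tc"] * math.log(chol_mgdl(record.tc))
            + t["ln_hdl"] * math.log(chol_mgdl(record.hdl))
            + t["ln_crp"] * math.log(record.crp)
            + t["smoker"] * smoker
            + t["family_history"] * fh
        )
    risk = 1.0 - blk["baseline_survival_10y"] ** math.exp(b - blk["mean_b"])
    return RiskEstimate(
        model=ModelId.RRS, horizon=10, risk=clamp_risk(100.0 * risk),
        omitted_inputs=omitted,
    )


ENGINES = {
    ModelId.SCORE2: score_score2,
    ModelId.PREVENT: score_prevent,
    ModelId.PCE: score_pce,
    ModelId.MESA: score_mesa,
    ModelId.QRISK3: score_qrisk3,
    ModelId.ASSIGN: score_assign,
    ModelId.AUSCVD: score_auscvd,
    ModelId.FRS_HCHD: score_frs_hchd,
    ModelId.RRS: score_rrs,
}
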
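"""Risk engines: independent formula oracles, frozen synthetic fixtures and
structural invariants (monotonicity, sex branches, bounds).

The inline oracles below are straight-line re-implementations of five of the
published equations with their constants re-typed independently of the
package's YAML registries, so a transcription or machinery error in either
copy surfaces as a mismatch.  The frozen fixture file is *synthetic*: it
pins the package's own outputs on six profiles to guard against accidental
change; it is not a recording of the official web calculators.
"""

import json
import math
from pathlib import Path

import numpy as np
import pytest

from riskconcord.cohort import ParticipantRecord
from riskconcord.engines import (
    MODEL_ORDER,
    MissingInputError,
    ModelId,
    list_model_metadata,
    score,
    score_all,
)
from riskconcord.engines.equations import score_score2

DATA = Path(__file__).parent / "data"

PROFILES = {
    "f_base": dict(sex="female", age=57.0, sbp=137.0, tc=6.3, hdl=1.33, tg=1.9,
                   glucose=6.3, crp=3.1, egfr=89.0, bmi=31.8, smoking="never"),
    "f_smoker_dm": dict(sex="female", age=62.0, sbp=150.0, tc=7.1, hdl=1.1,
                        tg=2.4, glucose=7.5, crp=4.5, egfr=80.0, bmi=33.0,
                        smoking="current", diabetes=True, htn_treated=True,
                        htn_dx=True),
    "f_low_risk": dict(sex="female", age=44.0, sbp=118.0, tc=4.9, hdl=1.8,
                       tg=1.1, glucose=5.0, crp=0.8, egfr=105.0, bmi=24.0,
                       smoking="never"),
    "m_base": dict(sex="male", age=48.0, sbp=137.0, tc=6.0, hdl=1.09, tg=2.4,
                   glucose=6.3, crp=2.6, egfr=97.0, bmi=31.2, smoking="never"),
    "m_smoker": dict(sex="male", age=55.0, sbp=145.0, tc=6.8, hdl=0.95,
                     tg=2.9, glucose=6.0, crp=3.4, egfr=90.0, bmi=32.0,
                     smoking="current", family_history_premature_cvd=True),
    "m_treated": dict(sex="male", age=61.0, sbp=132.0, tc=5.2, hdl=1.2,
                      tg=1.8, glucose=6.9, crp=2.0, egfr=85.0, bmi=29.0,
                      smoking="ex", diabetes=True, htn_treated=True,
                      htn_dx=True, lipid_treated=True),
}


def build(name, **overrides):
    base = dict(id=name, dbp=84.0, waist=101.0, ldl=3.9, creatinine=72.0,
                diabetes=False, htn_dx=False, htn_treated=False,
                lipid_treated=False, antiplatelet=False,
                family_history_premature_cvd=False)
    base.update(PROFILES[name])
    base.update(overrides)
    return ParticipantRecord(**base)


# ---------------------------------------------------------------------------
# independent oracles (constants re-typed from the primary publications)
# ---------------------------------------------------------------------------

def oracle_score2(rec):
    female = rec.sex.value == "female"
    cage = (rec.age - 60) / 5
    csbp = (rec.sbp - 120) / 20
    ctc = rec.tc - 6
    chdl = (rec.hdl - 1.3) / 0.5
    sm = 1.0 if rec.smoking.value == "current" else 0.0
    if female:
        lp = (0.4648 * cage + 0.7744 * sm + 0.3131 * csbp + 0.1002 * ctc
              - 0.2606 * chdl - 0.1088 * sm * cage - 0.0277 * csbp * cage
              - 0.0226 * ctc * cage + 0.0613 * chdl * cage)
        u = 1 - 0.9776 ** math.exp(lp)
        s1, s2 = 0.9412, 0.8329
    else:
        lp = (0.3742 * cage + 0.6012 * sm + 0.2777 * csbp + 0.1458 * ctc
              - 0.2698 * chdl - 0.0755 * sm * cage - 0.0255 * csbp * cage
              - 0.0281 * ctc * cage + 0.0426 * chdl * cage)
        u = 1 - 0.9605 ** math.exp(lp)
        s1, s2 = 0.5836, 0.8294
    return 100 * (1 - math.exp(-math.exp(s1 + s2 * math.log(-math.log(1 - u)))))


def oracle_pce_white(rec):
    la = math.log(rec.age)
    lt = math.log(rec.tc * 38.67)
    lh = math.log(rec.hdl * 38.67)
    ls = math.log(rec.sbp)
    sm = 1.0 if rec.smoking.value == "current" else 0.0
    db = 1.0 if rec.diabetes else 0.0
    if rec.sex.value == "female":
        lp = (-29.799 * la + 4.884 * la**2 + 13.540 * lt - 3.114 * la * lt
              - 13.578 * lh + 3.149 * la * lh + 7.574 * sm - 1.665 * la * sm
              + 0.661 * db)
        lp += (2.019 if rec.htn_treated else 1.957) * ls
        return 100 * (1 - 0.9665 ** math.exp(lp - (-29.18)))
    lp = (12.344 * la + 11.853 * lt - 2.664 * la * lt - 7.990 * lh
          + 1.769 * la * lh + 7.837 * sm - 1.795 * la * sm + 0.658 * db)
    lp += (1.797 if rec.htn_treated else 1.764) * ls
    return 100 * (1 - 0.9144 ** math.exp(lp - 61.18))


def oracle_prevent(rec):
    f = rec.sex.value == "female"
    ca = (rec.age - 55) / 10
    cn = (rec.tc - rec.hdl) - 3.5
    ch = (rec.hdl - 1.3) / 0.3
    sl = (min(rec.sbp, 110) - 110) / 20
    sh = (max(rec.sbp, 110) - 130) / 20
    el = (min(rec.egfr, 60) - 60) / -15
    eh = (max(rec.egfr, 60) - 90) / -15
    sm = 1.0 if rec.smoking.value == "current" else 0.0
    db = 1.0 if rec.diabetes else 0.0
    ah = 1.0 if rec.htn_treated else 0.0
    stn = 1.0 if rec.lipid_treated else 0.0
    if f:
        lp = (-3.307728 + 0.7939329 * ca + 0.0305239 * cn - 0.1606857 * ch
              - 0.2394003 * sl + 0.360078 * sh + 0.8667604 * db
              + 0.5360739 * sm + 0.6045917 * el + 0.0433769 * eh
              + 0.3151672 * ah - 0.1477655 * stn - 0.0663612 * ah * sh
              + 0.1197879 * stn * cn - 0.0819715 * ca * cn
              + 0.0306769 * ca * ch - 0.0946348 * ca * sh - 0.27057 * ca * db
              - 0.078715 * ca * sm - 0.1637806 * ca * el)
    else:
        lp = (-3.031168 + 0.7688528 * ca + 0.0736174 * cn - 0.0954431 * ch
              - 0.4347345 * sl + 0.3362658 * sh + 0.7692857 * db
              + 0.4386871 * sm + 0.5378979 * el + 0.0164827 * eh
              + 0.288879 * ah - 0.1337349 * stn - 0.0475924 * ah * sh
              + 0.150273 * stn * cn - 0.0517874 * ca * cn
              + 0.0191169 * ca * ch - 0.1049477 * ca * sh
              - 0.2251948 * ca * db - 0.0895067 * ca * sm
              - 0.1543702 * ca * el)
    return 100 / (1 + math.exp(-lp))


def oracle_mesa(rec):
    lp = (0.0172 * rec.age + 0.4079 * (rec.sex.value == "male")
          + 0.7189 * rec.diabetes + 0.3735 * (rec.smoking.value == "current")
          + 0.0091 * rec.tc * 38.67 - 0.0199 * rec.hdl * 38.67
          + 0.1318 * rec.lipid_treated + 0.0106 * rec.sbp
          + 0.2889 * rec.htn_treated
          + 0.5433 * rec.family_history_premature_cvd)
    return 100 * (1 - 0.99963 ** math.exp(lp))


def oracle_rrs(rec):
    sm = 1.0 if rec.smoking.value == "current" else 0.0
    fh = 1.0 if rec.family_history_premature_cvd else 0.0
    if rec.sex.value == "female":
        b = (0.0799 * rec.age + 3.137 * math.log(rec.sbp)
             + 0.180 * math.log(rec.crp) + 1.382 * math.log(rec.tc * 38.67)
             - 1.172 * math.log(rec.hdl * 38.67) + 0.818 * sm + 0.438 * fh)
        if rec.diabetes:
            b += 0.134 * 7.0
        return 100 * (1 - 0.98634 ** math.exp(b - 22.325))
    b = (4.385 * math.log(rec.age) + 2.607 * math.log(rec.sbp)
         + 0.963 * math.log(rec.tc * 38.67) - 0.772 * math.log(rec.hdl * 38.67)
         + 0.102 * math.log(rec.crp) + 0.405 * sm + 0.541 * fh)
    return 100 * (1 - 0.8990 ** math.exp(b - 33.097))


ORACLES = {
    ModelId.SCORE2: oracle_score2,
    ModelId.PCE: oracle_pce_white,
    ModelId.PREVENT: oracle_prevent,
    ModelId.MESA: oracle_mesa,
    ModelId.RRS: oracle_rrs,
}


class TestOracleAgreement:
    @pytest.mark.parametrize("profile", sorted(PROFILES))
    @pytest.mark.parametrize("model", sorted(ORACLES, key=lambda m: m.value))
    def test_engine_matches_independent_formula(self, model, profile):
        rec = build(profile)
        assert score(model, rec).risk == pytest.approx(
            ORACLES[model](rec), abs=1e-9
        )

    @pytest.mark.parametrize("profile", sorted(PROFILES))
    def test_frozen_synthetic_fixtures(self, profile):
        """All nine engines reproduce the frozen fixture values within
        0.1 percentage points (regression guard on the package's own
        outputs; see module docstring)."""
        fixtures = json.loads((DATA / "engine_fixtures_synthetic.json").read_text())
        rec = build(profile)
        for model_name, expected in fixtures[profile].items():
            got = score(ModelId(model_name), rec).risk
            assert got == pytest.approx(expected, abs=0.1), (profile, model_name)


class TestStructuralInvariants:
    @pytest.mark.parametrize("model", [m for m in ModelId])
    @pytest.mark.parametrize("profile", ["f_base", "m_base"])
    def test_current_smoking_raises_risk(self, model, profile):
        never = build(profile, smoking="never")
        current = build(profile, smoking="current")
        assert score(model, current).risk > score(model, never).risk

    @pytest.mark.parametrize("model", [m for m in ModelId])
    @pytest.mark.parametrize("profile", ["f_base", "m_smoker"])
    def test_monotone_in_sbp_at_and_above_110(self, model, profile):
        """Risk is non-decreasing in SBP on [110, 200] (below 110 the PREVENT
        equation's published low-SBP term makes risk rise again as pressure
        falls, so the grid starts at 110)."""
        risks = [
            score(model, build(profile, sbp=s)).risk
            for s in np.linspace(110, 200, 10)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(risks, risks[1:]))

    @pytest.mark.parametrize("model", [m for m in ModelId])
    @pytest.mark.parametrize("profile", ["f_base", "m_base"])
    def test_monotone_in_age_over_inclusion_range(self, model, profile):
        risks = [
            score(model, build(profile, age=a)).risk
            for a in np.linspace(40, 65, 11)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(risks, risks[1:]))

    @pytest.mark.parametrize("model", [m for m in ModelId])
    def test_sex_branch_actually_switches(self, model):
        rec_f = build("f_smoker_dm")
        rec_m = build("f_smoker_dm", id="swap", sex="male")
        assert score(model, rec_f).risk != score(model, rec_m).risk

    def test_bounds_and_no_nan_on_synthetic_cohort(self, small_cohort):
        table = score_all(small_cohort[:100])
        assert table.failures == []
        values = table.risks.to_numpy()
        assert np.isfinite(values).all()
        assert (values >= 0).all() and (values <= 100).all()

    def test_score2_very_high_region_exceeds_low(self):
        rec = build("m_base")
        assert (score_score2(rec, region="very_high").risk
                > score_score2(rec, region="low").risk)


class TestScoringInterface:
    def test_one_record_gives_nine_estimates_consistent_with_score(self, make_record):
        rec = make_record()
        table = score_all([rec])
        assert table.risks.shape == (1, 9)
        for model in ModelId:
            assert table.risks.loc[rec.id, model.value] == score(model, rec).risk

    def test_missing_crp_names_model_and_field(self, make_record):
        rec = make_record().with_(crp=None)
        with pytest.raises(MissingInputError, match="RRS.*crp"):
            score(ModelId.RRS, rec)

    def test_per_cell_failure_is_isolated(self, make_record):
        good = make_record(id="ok")
        broken = make_record(id="broken").with_(crp=None)
        table = score_all([good, broken])
        assert np.isnan(table.risks.loc["broken", "RRS"])
        assert np.isfinite(table.risks.loc["broken", "SCORE2"])
        assert any(f[0] == "broken" and f[1] == "RRS" for f in table.failures)

    def test_unknown_model_rejected(self, make_record):
        with pytest.raises(ValueError):
            score("SCORE3", make_record())

    def test_metadata_table(self):
        meta = list_model_metadata()
        assert len(meta) == 9
        assert meta.loc["AUSCVD", "horizon_years"] == 5
        assert set(meta["horizon_years"]) == {5, 10}
        assert "fatal or nonfatal" in meta.loc["SCORE2", "outcome"]
        assert meta["source"].str.len().gt(0).all()
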
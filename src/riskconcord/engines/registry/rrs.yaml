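# Reynolds Risk Score: 10-year global cardiovascular risk with hsCRP and
# parental family history; separate models for women and men.
model: RRS
horizon_years: 10
outcome: "major cardiovascular events (MI, stroke, coronary revascularization, cardiovascular death)"
source: >
  Ridker PM et al. Development and validation of improved algorithms for the
  assessment of global cardiovascular risk in women: the Reynolds Risk Score.
  JAMA 2007;297:611-619 (clinical simplified model B); Ridker PM et al.
  C-reactive protein and parental history improve global cardiovascular risk
  prediction: the Reynolds Risk Score for men. Circulation 2008;118:2243-2251.
provenance: >
  Transcribed from the primary publications. Lipids in mg/dL (factor 38.67);
  hsCRP in mg/L; family history = parental MI before age 60. Women:
  risk = 1 - 0.98634^exp(B - 22.325); the HbA1c term applies only to diabetic
  women and the registry carries no HbA1c, so a documented default is entered
  and logged as an omitted input. Men: risk = 1 - 0.8990^exp(B - 33.097);
  the men's model carries no diabetes term.
predictors: [age, sex, sbp, tc, hdl, crp, smoking, family_history_premature_cvd, diabetes]
hba1c_percent_if_diabetic: 7.0
female:
  baseline_survival_10y: 0.98634
  mean_b: 22.325
  terms:
    age: 0.0799
    ln_sbp: 3.137
    ln_crp: 0.180
    ln_tc: 1.382
    ln_hdl: -1.172
    hba1c_if_diabetic: 0.134
    smoker: 0.818
    family_history: 0.438
male:
  baseline_survival_10y: 0.8990
  mean_b: 33.097
  terms:
    ln_age: 4.385
    ln_sbp: 2.607
    ln_tc: 0.963
    ln_hdl: -0.772
    ln_crp: 0.102
    smoker: 0.405
    family_history: 0.541
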
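# AusCVDRisk: 5-year CVD risk for Australian primary prevention, derived from
# the New Zealand PREDICT-1 equation.
model: AUSCVD
horizon_years: 5
outcome: "first cardiovascular disease event (5-year)"
source: >
  Pylypchuk R et al. Cardiovascular disease risk prediction equations in
  400,000 primary care patients in New Zealand (PREDICT): a derivation and
  validation study. Lancet 2018;391:1897-1907, supplementary appendix
  (sex-specific Cox coefficients, no-prior-CVD cohort); adopted with
  recalibration by the Australian Guideline for assessing and managing
  cardiovascular disease risk (2023).
provenance: >
  Best-effort transcription of the PREDICT-1 primary prevention equation;
  digits could not be re-verified offline and the Australian postcode/SEIFA
  recalibration constants are not publicly printed in transcribable form, so
  the engine evaluates the published PREDICT-1 equation with area-level
  deprivation and ethnicity at their reference values (logged per estimate).
  risk = 1 - S0(5)^exp(LP), LP on covariates centered at the PREDICT means.
predictors: [age, sex, sbp, tc, hdl, diabetes, smoking, family_history_premature_cvd, htn_treated, lipid_treated, antiplatelet]
female:
  baseline_survival_5y: 0.983169
  centers: {age: 56.13665, sbp: 129.0173, ratio: 3.726268}
  terms:
    age: 0.0756412
    exsmoker: 0.0855224
    smoker: 0.5058041
    family_history: 0.0725816
    af: 0.8759061
    diabetes: 0.5597023
    sbp: 0.0136606
    ratio: 0.1119911
    lipid_med: -0.0857113
    bp_med: 0.3399197
    antithrombotic: 0.1391524
    age_x_diabetes: -0.0209826
    age_x_sbp: -0.0004499
    bpmed_x_sbp: -0.0053077
male:
  baseline_survival_5y: 0.974755
  centers: {age: 51.79953, sbp: 129.1095, ratio: 4.38906}
  terms:
    age: 0.0675532
    exsmoker: 0.0753246
    smoker: 0.5400185
    family_history: 0.1326516
    af: 0.5924489
    diabetes: 0.4864682
    sbp: 0.0121294
    ratio: 0.1369966
    lipid_med: -0.0537314
    bp_med: 0.2947634
    antithrombotic: 0.0934141
    age_x_diabetes: -0.0133672
    age_x_sbp: -0.0004425
    bpmed_x_sbp: -0.0051746
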
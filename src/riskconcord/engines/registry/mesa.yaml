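# MESA 10-year CHD risk, no-CAC equation variant (coronary calcium
# unavailable in registry data), ages 45-85.
model: MESA
horizon_years: 10
outcome: "coronary heart disease events"
source: >
  McClelland RL et al. 10-Year Coronary Heart Disease Risk Prediction Using
  Coronary Artery Calcium and Traditional Risk Factors (MESA). J Am Coll
  Cardiol 2015;66:1643-1653, Table 2 (risk-factors-only Cox model).
provenance: >
  Transcribed from the publication's risk-factors-only (no-CAC) model; an
  imputed calcium score is never used. Lipids in mg/dL (factor 38.67).
  risk = 1 - 0.99963^exp(LP); race/ethnicity terms at the non-Hispanic White
  reference for this European cohort.
predictors: [age, sex, tc, hdl, sbp, htn_treated, lipid_treated, smoking, diabetes, family_history_premature_cvd]
baseline_survival_factor: 0.99963
terms:
  age: 0.0172
  male: 0.4079
  chinese: -0.3475
  black: 0.0353
  hispanic: -0.0222
  diabetes: 0.7189
  smoker: 0.3735
  tc_mgdl: 0.0091
  hdl_mgdl: -0.0199
  lipid_med: 0.1318
  sbp: 0.0106
  bp_med: 0.2889
  family_history: 0.5433
default_ethnicity: white
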
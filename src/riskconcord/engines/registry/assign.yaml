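# ASSIGN: 10-year CVD risk, Scotland (SHHEC derivation), with social
# deprivation (SIMD) and family history.
model: ASSIGN
horizon_years: 10
outcome: "cardiovascular disease (fatal or nonfatal) or coronary intervention"
source: >
  Woodward M, Brindle P, Tunstall-Pedoe H. Adding social deprivation and
  family history to cardiovascular risk assessment: the ASSIGN score from the
  Scottish Heart Health Extended Cohort (SHHEC). Heart 2007;93:172-176.
provenance: >
  Log hazard ratios derived from the hazard ratios printed in the primary
  publication (self-consistent to 4 decimals). Baseline 10-year survival and
  the SHHEC centering means are best-effort transcriptions and are flagged
  approximate: they could not be re-verified against the official calculator
  in an offline build. risk = 1 - S0^exp(LP - LP_at_means). The deprivation
  input is not applicable outside Scotland and is held at the SHHEC mean
  (zero contribution after centering), logged per estimate. Current smokers
  are entered as `cigarettes_per_day_current` cigarettes/day (registry data
  records status only), ex/never smokers as 0.
predictors: [age, sex, tc, hdl, sbp, diabetes, smoking, family_history_premature_cvd]
cigarettes_per_day_current: 15
female:
  baseline_survival_10y: 0.9365
  terms:
    age: 0.07203
    tc: 0.12720
    hdl: -0.55836
    sbp: 0.01064
    diabetes: 0.97727
    family_history: 0.49159
    cpd: 0.02724
    simd: 0.01056
  means:  # approximate SHHEC female covariate means
    age: 48.3
    tc: 6.36
    hdl: 1.65
    sbp: 130.8
    diabetes: 0.012
    family_history: 0.33
    cpd: 8.0
    simd: 24.3
male:
  baseline_survival_10y: 0.8831
  terms:
    age: 0.05698
    tc: 0.16598
    hdl: -0.42420
    sbp: 0.01183
    diabetes: 0.81558
    family_history: 0.27500
    cpd: 0.02005
    simd: 0.00863
  means:  # approximate SHHEC male covariate means
    age: 48.8
    tc: 6.25
    hdl: 1.36
    sbp: 134.2
    diabetes: 0.016
    family_history: 0.26
    cpd: 9.4
    simd: 24.4
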
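# SCORE2: 10-year risk of first fatal or nonfatal cardiovascular disease,
# Europe, ages 40-69, with country-group recalibration.
model: SCORE2
horizon_years: 10
outcome: "first fatal or nonfatal cardiovascular disease"
source: >
  SCORE2 working group and ESC Cardiovascular risk collaboration. SCORE2 risk
  prediction algorithms. Eur Heart J 2021;42:2439-2454, supplementary
  methods (sex-specific log hazard ratios, baseline survival, and region
  recalibration scales).
provenance: >
  Transcribed from the supplementary coefficient tables of the primary
  publication. Transforms: cage=(age-60)/5, csbp=(sbp-120)/20, ctc=(tc-6)/1,
  chdl=(hdl-1.3)/0.5 (mmol/L); uncalibrated = 1 - S0^exp(LP); calibrated
  risk = 1 - exp(-exp(scale1 + scale2*ln(-ln(1-uncalibrated)))).
predictors: [age, sex, sbp, tc, hdl, smoking]
female:
  baseline_survival_10y: 0.9776
  terms:
    cage: 0.4648
    smoker: 0.7744
    csbp: 0.3131
    ctc: 0.1002
    chdl: -0.2606
    smoker_x_cage: -0.1088
    csbp_x_cage: -0.0277
    ctc_x_cage: -0.0226
    chdl_x_cage: 0.0613
male:
  baseline_survival_10y: 0.9605
  terms:
    cage: 0.3742
    smoker: 0.6012
    csbp: 0.2777
    ctc: 0.1458
    chdl: -0.2698
    smoker_x_cage: -0.0755
    csbp_x_cage: -0.0255
    ctc_x_cage: -0.0281
    chdl_x_cage: 0.0426
# Region recalibration scales (scale1, scale2) by sex; Lithuania belongs to
# the very-high-risk region, the engine default.
recalibration:
  low:       {female: [-0.7380, 0.7019], male: [-0.5699, 0.7476]}
  moderate:  {female: [-0.3143, 0.7701], male: [-0.1565, 0.8009]}
  high:      {female: [ 0.5710, 0.9369], male: [ 0.3207, 0.9360]}
  very_high: {female: [ 0.9412, 0.8329], male: [ 0.5836, 0.8294]}
default_region: very_high
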
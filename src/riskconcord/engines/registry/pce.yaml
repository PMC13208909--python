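# Pooled Cohort Equations: 10-year first hard ASCVD event risk, US, ages 40-79.
model: PCE
horizon_years: 10
outcome: "first hard atherosclerotic cardiovascular disease event"
source: >
  Goff DC Jr et al. 2013 ACC/AHA Guideline on the Assessment of Cardiovascular
  Risk. Circulation 2014;129(25 Suppl 2):S49-S73, Appendix 7 (race- and
  sex-specific Cox coefficients, mean linear predictors and baseline survival).
provenance: >
  Transcribed from the guideline appendix. Lipids in mg/dL (record mmol/L
  values converted with the factor 38.67). risk = 1 - S0^exp(LP - mean_lp).
  The race branch applied to this European cohort defaults to non-Hispanic
  White; the African American branch is carried in the registry but is outside
  the fixture surface.
predictors: [age, sex, tc, hdl, sbp, htn_treated, smoking, diabetes]
white:
  female:
    baseline_survival_10y: 0.9665
    mean_lp: -29.18
    terms:
      ln_age: -29.799
      ln_age_sq: 4.884
      ln_tc: 13.540
      ln_age_x_ln_tc: -3.114
      ln_hdl: -13.578
      ln_age_x_ln_hdl: 3.149
      ln_sbp_treated: 2.019
      ln_sbp_untreated: 1.957
      smoker: 7.574
      ln_age_x_smoker: -1.665
      diabetes: 0.661
  male:
    baseline_survival_10y: 0.9144
    mean_lp: 61.18
    terms:
      ln_age: 12.344
      ln_tc: 11.853
      ln_age_x_ln_tc: -2.664
      ln_hdl: -7.990
      ln_age_x_ln_hdl: 1.769
      ln_sbp_treated: 1.797
      ln_sbp_untreated: 1.764
      smoker: 7.837
      ln_age_x_smoker: -1.795
      diabetes: 0.658
black:
  female:
    baseline_survival_10y: 0.9533
    mean_lp: 86.61
    terms:
      ln_age: 17.114
      ln_tc: 0.940
      ln_hdl: -18.920
      ln_age_x_ln_hdl: 4.475
      ln_sbp_treated: 29.291
      ln_age_x_ln_sbp_treated: -6.432
      ln_sbp_untreated: 27.820
      ln_age_x_ln_sbp_untreated: -6.087
      smoker: 0.691
      diabetes: 0.874
  male:
    baseline_survival_10y: 0.8954
    mean_lp: 19.54
    terms:
      ln_age: 2.469
      ln_tc: 0.302
      ln_hdl: -0.307
      ln_sbp_treated: 1.916
      ln_sbp_untreated: 1.809
      smoker: 0.549
      diabetes: 0.645
default_race: white
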
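# AHA PREVENT, base model: 10-year total CVD risk, US, ages 30-79.
model: PREVENT
horizon_years: 10
outcome: "total cardiovascular disease (ASCVD plus heart failure)"
source: >
  Khan SS et al. Development and validation of the American Heart Association
  Predicting Risk of cardiovascular disease EVENTs (PREVENT) equations.
  Circulation 2024;149:430-449, supplementary tables (base-model logistic
  coefficients for 10-year total CVD).
provenance: >
  Transcribed from the supplement. Base model without the optional
  social-deprivation-index add-on (the ZIP-linked index is not applicable
  outside the US and is omitted, logged per estimate). Transforms:
  c_age=(age-55)/10; c_nonhdl=(tc-hdl)-3.5 mmol/L; c_hdl=(hdl-1.3)/0.3;
  c_sbp_lo=(min(sbp,110)-110)/20; c_sbp_hi=(max(sbp,110)-130)/20;
  c_egfr_lo=(min(egfr,60)-60)/(-15); c_egfr_hi=(max(egfr,60)-90)/(-15).
  risk% = 100 * expit(intercept + LP).
predictors: [age, sex, tc, hdl, sbp, egfr, diabetes, smoking, htn_treated, lipid_treated]
female:
  intercept: -3.307728
  terms:
    c_age: 0.7939329
    c_nonhdl: 0.0305239
    c_hdl: -0.1606857
    c_sbp_lo: -0.2394003
    c_sbp_hi: 0.360078
    diabetes: 0.8667604
    smoker: 0.5360739
    c_egfr_lo: 0.6045917
    c_egfr_hi: 0.0433769
    antihtn: 0.3151672
    statin: -0.1477655
    antihtn_x_sbp_hi: -0.0663612
    statin_x_nonhdl: 0.1197879
    age_x_nonhdl: -0.0819715
    age_x_hdl: 0.0306769
    age_x_sbp_hi: -0.0946348
    age_x_diabetes: -0.27057
    age_x_smoker: -0.078715
    age_x_egfr_lo: -0.1637806
male:
  intercept: -3.031168
  terms:
    c_age: 0.7688528
    c_nonhdl: 0.0736174
    c_hdl: -0.0954431
    c_sbp_lo: -0.4347345
    c_sbp_hi: 0.3362658
    diabetes: 0.7692857
    smoker: 0.4386871
    c_egfr_lo: 0.5378979
    c_egfr_hi: 0.0164827
    antihtn: 0.288879
    statin: -0.1337349
    antihtn_x_sbp_hi: -0.0475924
    statin_x_nonhdl: 0.150273
    age_x_nonhdl: -0.0517874
    age_x_hdl: 0.0191169
    age_x_sbp_hi: -0.1049477
    age_x_diabetes: -0.2251948
    age_x_smoker: -0.0895067
    age_x_egfr_lo: -0.1543702
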
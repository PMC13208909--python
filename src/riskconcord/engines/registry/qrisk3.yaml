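# QRISK3 (2017): 10-year CVD risk, UK, ages 25-84; adds chronic conditions,
# corticosteroid use, migraine, SLE, severe mental illness, atypical
# antipsychotics and erectile dysfunction to conventional predictors.
model: QRISK3
horizon_years: 10
outcome: "cardiovascular disease (coronary heart disease, ischaemic stroke or TIA)"
source: >
  Hippisley-Cox J, Coupland C, Brindle P. Development and validation of
  QRISK3 risk prediction algorithms to estimate future risk of cardiovascular
  disease: prospective cohort study. BMJ 2017;357:j2099, and the ClinRisk
  open-source release of the QRISK3-2017 algorithm.
provenance: >
  Best-effort transcription; the open-source release was not reachable in an
  offline build, so digits could not be re-verified and the age-interaction
  terms of the full algorithm are omitted (main effects only). Fractional
  polynomial transforms: women age_1=(age/10)^-2, age_2=age/10; men
  age_1=(age/10)^-1, age_2=(age/10)^3; both sexes bmi_1=(bmi/10)^-2,
  bmi_2=(bmi/10)^-2*ln(bmi/10); rati=TC/HDL. Continuous covariates are
  centered at the published cohort means. Ethnicity (White reference),
  Townsend deprivation and SBP variability are held at reference/center
  (zero contribution) and logged as omitted inputs. Current smokers are
  scored in the moderate (10-19/day) category because the registry records
  status only. risk = 1 - S0(10)^exp(LP).
predictors: [age, sex, bmi, tc, hdl, sbp, smoking, diabetes, htn_treated, family_history_premature_cvd, extras]
female:
  baseline_survival_10y: 0.988876402378082
  centers:
    age_1: 0.053274843841791
    age_2: 4.332503318786621
    bmi_1: 0.154946178197861
    bmi_2: 0.144462317228317
    rati: 3.476326036453247
    sbp: 123.130012512207
  terms:
    age_1: -8.138810924772619
    age_2: 0.797338827173363
    bmi_1: 0.292360922754601
    bmi_2: -4.151330021383767
    rati: 0.153380354861202
    sbp: 0.013131488407103
    smoke_ex: 0.133869
    smoke_current: 0.587918
    type2_diabetes: 1.068877
    bp_treatment: 0.509696
    family_history: 0.454453
    migraine: 0.283517
    corticosteroids: 0.594956
    sle: 0.757955
    severe_mental_illness: 0.191256
    atypical_antipsychotics: 0.323928
    erectile_dysfunction: 0.0
male:
  baseline_survival_10y: 0.977268040180206
  centers:
    age_1: 0.232008963823318
    age_2: 16.188414573669434
    bmi_1: 0.146408438682556
    bmi_2: 0.140651300549507
    rati: 4.300998687744141
    sbp: 128.571578979492
  terms:
    age_1: -17.839781666005575
    age_2: 0.002296488060577
    bmi_1: 2.456277666053636
    bmi_2: -8.301112231471135
    rati: 0.173401968563271
    sbp: 0.012910126542553
    smoke_ex: 0.191282
    smoke_current: 0.638351
    type2_diabetes: 0.868931
    bp_treatment: 0.518202
    family_history: 0.540555
    migraine: 0.253495
    corticosteroids: 0.547249
    sle: 0.372688
    severe_mental_illness: 0.125583
    atypical_antipsychotics: 0.130469
    erectile_dysfunction: 0.223586
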
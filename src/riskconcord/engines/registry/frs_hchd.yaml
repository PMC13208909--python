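# Framingham Risk Score for hard coronary heart disease (coronary death or
# myocardial infarction), 10-year, ATP III point-based implementation.
model: FRS_HCHD
horizon_years: 10
outcome: "hard coronary heart disease (coronary death or myocardial infarction)"
source: >
  Third Report of the NCEP Expert Panel (Adult Treatment Panel III), final
  report. Circulation 2002;106:3143-3421 (Framingham point scores); after
  Wilson PWF et al. Circulation 1998;97:1837-1847. Point-based variant as
  implemented by common clinical calculators.
provenance: >
  Point tables transcribed from the ATP III report. Total cholesterol and
  smoking points depend on the age decade; lipids entered in mg/dL (factor
  38.67). The printed point-total-to-risk map is discrete; "<1%" is carried
  as 0.5% and ">=30%" as 30% internally. The model has no diabetes input;
  diabetic participants are scored with the same tables (prominently
  documented - the derivation treated diabetes as a CHD risk equivalent
  handled outside the score).
predictors: [age, sex, tc, hdl, sbp, htn_treated, smoking]
# age bands: [lo, hi) in years; the scoring age bands and per-band points
age_bands: [[20, 35], [35, 40], [40, 45], [45, 50], [50, 55], [55, 60], [60, 65], [65, 70], [70, 75], [75, 80]]
# cholesterol bands (mg/dL): [0,160), [160,200), [200,240), [240,280), [280,inf)
# points per decade-of-age group: 20-39, 40-49, 50-59, 60-69, 70-79
female:
  age_points: [-7, -3, 0, 3, 6, 8, 10, 12, 14, 16]
  tc_points:
    - [0, 0, 0, 0, 0]
    - [4, 3, 2, 1, 1]
    - [8, 6, 4, 2, 1]
    - [11, 8, 5, 3, 2]
    - [13, 10, 7, 4, 2]
  smoker_points: [9, 7, 4, 2, 1]
  hdl_points: {ge60: -1, b50_59: 0, b40_49: 1, lt40: 2}
  sbp_points:
    untreated: {lt120: 0, b120_129: 1, b130_139: 2, b140_159: 3, ge160: 4}
    treated: {lt120: 0, b120_129: 3, b130_139: 4, b140_159: 5, ge160: 6}
  risk_map:  # [minimum point total, percent risk]; below first entry => 0.5
    - [9, 1]
    - [13, 2]
    - [15, 3]
    - [16, 4]
    - [17, 5]
    - [18, 6]
    - [19, 8]
    - [20, 11]
    - [21, 14]
    - [22, 17]
    - [23, 22]
    - [24, 27]
    - [25, 30]
male:
  age_points: [-9, -4, 0, 3, 6, 8, 10, 11, 12, 13]
  tc_points:
    - [0, 0, 0, 0, 0]
    - [4, 3, 2, 1, 0]
    - [7, 5, 3, 1, 0]
    - [9, 6, 4, 2, 1]
    - [11, 8, 5, 3, 1]
  smoker_points: [8, 5, 3, 1, 1]
  hdl_points: {ge60: -1, b50_59: 0, b40_49: 1, lt40: 2}
  sbp_points:
    untreated: {lt120: 0, b120_129: 0, b130_139: 1, b140_159: 1, ge160: 2}
    treated: {lt120: 0, b120_129: 1, b130_139: 2, b140_159: 2, ge160: 3}
  risk_map:
    - [0, 1]
    - [5, 2]
    - [7, 3]
    - [8, 4]
    - [9, 5]
    - [10, 6]
    - [11, 8]
    - [12, 10]
    - [13, 12]
    - [14, 16]
    - [15, 20]
    - [16, 25]
    - [17, 30]
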
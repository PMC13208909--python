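# Default guideline-mapped statin-eligibility thresholds, one per model.
# A participant is eligible under a model when calculated risk meets or
# exceeds ("≥") the applicable cut-point; age-banded rules select the band by
# the participant's age in whole (truncated) years.  Every pipeline report
# prints the active policy set, so results are never silently
# policy-dependent.
policies:
  SCORE2:
    bands:                      # 2021 ESC prevention guidelines, ages 40-69,
      - {lo: 40, hi: 50, cut: 7.5}   # very-high-risk region thresholds
      - {lo: 50, hi: 70, cut: 10.0}
    source: "2021 ESC CVD prevention guidelines: >=7.5% at age 40-49, >=10% at 50-69"
  PREVENT:
    constant: 7.5
    source: "ACC/AHA primary-prevention mapping: >=7.5% 10-y total CVD treated as the statin-discussion threshold"
  PCE:
    constant: 7.5
    source: "2018 AHA/ACC cholesterol guideline: fixed >=7.5% 10-y ASCVD threshold"
  MESA:
    constant: 7.5
    source: "US framework threshold (>=7.5% 10-y CHD) applied to the MESA score"
  QRISK3:
    constant: 10.0
    source: "NICE CG181/NG238: QRISK >=10% 10-y CVD"
  ASSIGN:
    constant: 20.0
    source: "SIGN 149: ASSIGN >=20% 10-y CVD"
  AUSCVD:
    constant: 10.0
    source: "Australian CVD risk guideline 2023: high risk >=10% 5-y CVD"
  FRS_HCHD:
    constant: 10.0
    source: "NCEP ATP III: drug therapy considered from >=10% 10-y hard CHD"
  RRS:
    constant: 10.0
    source: "Reynolds framework: >=10% 10-y risk treated as statin-eligible"
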
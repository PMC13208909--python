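{
 "f_base": {
  "SCORE2": 10.502394,
  "PREVENT": 4.647145,
  "PCE": 3.518761,
  "MESA": 1.380543,
  "QRISK3": 6.2786,
  "ASSIGN": 9.981769,
  "AUSCVD": 2.230626,
  "FRS_HCHD": 3.0,
  "RRS": 3.147827
 },
 "f_low_risk": {
  "SCORE2": 1.77207,
  "PREVENT": 0.757525,
  "PCE": 0.396038,
  "MESA": 0.386026,
  "QRISK3": 0.966005,
  "ASSIGN": 2.144698,
  "AUSCVD": 0.489449,
  "FRS_HCHD": 0.5,
  "RRS": 0.274845
 },
 "f_smoker_dm": {
  "SCORE2": 33.131279,
  "PREVENT": 26.964685,
  "PCE": 35.308206,
  "MESA": 10.368747,
  "QRISK3": 74.771748,
  "ASSIGN": 58.159279,
  "AUSCVD": 13.577393,
  "FRS_HCHD": 14.0,
  "RRS": 43.910231
 },
 "m_base": {
  "SCORE2": 8.21811,
  "PREVENT": 3.906952,
  "PCE": 4.80092,
  "MESA": 1.919308,
  "QRISK3": 6.339183,
  "ASSIGN": 9.563629,
  "AUSCVD": 2.537309,
  "FRS_HCHD": 6.0,
  "RRS": 4.488623
 },
 "m_smoker": {
  "SCORE2": 25.609802,
  "PREVENT": 11.345452,
  "PCE": 22.035742,
  "MESA": 8.408929,
  "QRISK3": 44.133738,
  "ASSIGN": 29.875123,
  "AUSCVD": 10.214823,
  "FRS_HCHD": 30.0,
  "RRS": 27.468885
 },
 "m_treated": {
  "SCORE2": 13.487336,
  "PREVENT": 16.409373,
  "PCE": 22.060433,
  "MESA": 4.859181,
  "QRISK3": 48.961336,
  "ASSIGN": 31.301783,
  "AUSCVD": 8.973031,
  "FRS_HCHD": 16.0,
  "RRS": 8.962832
 }
}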
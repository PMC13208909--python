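id,sex,age,sbp,dbp,waist,bmi,tc,ldl,hdl,tg,glucose,creatinine,egfr,crp,uacr,smoking,diabetes,htn_dx,htn_treated,lipid_treated,antiplatelet,family_history_premature_cvd,corticosteroids,migraine,atypical_antipsychotics,sle,severe_mental_illness,erectile_dysfunction
g1,female,57,135,85,95,31,6,3.8,1.2,1.9,5.8,75,92,2.5,,never,0,0,0,0,0,0,0,0,0,0,0,0
g2,male,48,135,85,104,31,6,3.8,1,1.9,5.8,75,92,2.5,,current,1,0,0,0,0,0,0,0,0,0,0,0
g3,female,62,135,85,100,31,6,3.8,1.2,1.9,5.8,75,92,2.5,12.5,never,0,1,1,0,0,0,0,0,0,0,0,0
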
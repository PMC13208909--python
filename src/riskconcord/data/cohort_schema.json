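{
  "title": "riskconcord cohort table",
  "description": "One row per participant; SI clinical units; booleans as 0/1; smoking as current/ex/never. Enforced on every cohort read.",
  "columns": {
    "id": {"type": "string", "required": true},
    "sex": {"type": "enum", "values": ["female", "male"], "required": true},
    "age": {"type": "number", "min": 40, "max": 65, "required": true},
    "sbp": {"type": "number", "min": 60, "max": 280, "required": true},
    "dbp": {"type": "number", "min": 30, "max": 180, "required": true},
    "waist": {"type": "number", "min": 40, "max": 220, "required": true},
    "bmi": {"type": "number", "min": 12, "max": 80, "required": true},
    "tc": {"type": "number", "min": 1.0, "max": 20, "required": true},
    "ldl": {"type": "number", "min": 0.2, "max": 15, "required": true},
    "hdl": {"type": "number", "min": 0.2, "max": 5, "required": true},
    "tg": {"type": "number", "min": 0.1, "max": 30, "required": true},
    "glucose": {"type": "number", "min": 2, "max": 30, "required": true},
    "creatinine": {"type": "number", "min": 20, "max": 500, "required": true},
    "egfr": {"type": "number", "min": 10, "max": 200, "required": true},
    "crp": {"type": "number", "min": 0.01, "max": 200, "required": true},
    "uacr": {"type": "number", "min": 0, "max": 10000, "required": false},
    "smoking": {"type": "enum", "values": ["current", "ex", "never"], "required": true},
    "diabetes": {"type": "flag", "required": true},
    "htn_dx": {"type": "flag", "required": true},
    "htn_treated": {"type": "flag", "required": true},
    "lipid_treated": {"type": "flag", "required": true},
    "antiplatelet": {"type": "flag", "required": true},
    "family_history_premature_cvd": {"type": "flag", "required": true},
    "corticosteroids": {"type": "flag", "required": false},
    "migraine": {"type": "flag", "required": false},
    "atypical_antipsychotics": {"type": "flag", "required": false},
    "sle": {"type": "flag", "required": false},
    "severe_mental_illness": {"type": "flag", "required": false},
    "erectile_dysfunction": {"type": "flag", "required": false}
  }
}
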
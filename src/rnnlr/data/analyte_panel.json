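[
  {"name": "albumin", "low": 0.19, "high": 5.5, "units": "g/dL"},
  {"name": "amylase", "low": 5, "high": 11873, "units": "U/L"},
  {"name": "bnp", "low": 21.49, "high": 4942, "units": "pg/mL"},
  {"name": "bun", "low": 1, "high": 281, "units": "mmol/L"},
  {"name": "band", "low": 0.3, "high": 76, "units": "%"},
  {"name": "ca", "low": 0.8, "high": 14.49, "units": "mg/dL"},
  {"name": "creatinine", "low": 0.07, "high": 34.2, "units": "mg/dL"},
  {"name": "crp", "low": 0.2, "high": 679.2, "units": "mg/L"},
  {"name": "hematocrit", "low": 1, "high": 63.2, "units": "%"},
  {"name": "inr", "low": 0.79, "high": 12, "units": "ratio"},
  {"name": "k", "low": 1.6, "high": 18.86, "units": "mEq/L"},
  {"name": "lactate", "low": 5.49, "high": 240.6, "units": "mmol/L"},
  {"name": "wbc", "low": 0.2, "high": 141.5, "units": "1e9/L"},
  {"name": "platelets", "low": 0.7, "high": 1373, "units": "1e9/L"},
  {"name": "prealbumin", "low": 2, "high": 44.59, "units": "mg/dL"},
  {"name": "procalcitonin", "low": 4.56, "high": 45.49, "units": "ug/L"},
  {"name": "total_bilirubin", "low": 0.1, "high": 56.54, "units": "mg/dL"},
  {"name": "na", "low": 10, "high": 190, "units": "mEq/L"}
]
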
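{
  "description": "Held-out test confusion matrix of the published cost-sensitive recurrent predictor on the peritonitis cohort; rows = actual, columns = predicted, order neither/AHE/HRS.",
  "class_order": ["neither", "AHE", "HRS"],
  "matrix": [
    [1079, 18, 165],
    [7, 5, 0],
    [20, 1, 14]
  ]
}
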
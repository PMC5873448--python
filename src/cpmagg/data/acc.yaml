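model_id: acc
intercept: 0.0
coefficients:
  age_per_5: 0.122
  nyha_iv: 0.223
  copd: 0.511
  dialysis: 1.179
  non_tf_access: 0.673
  egfr_per_5: -0.069
  acuity_2: 0.451
  acuity_3: 0.993
  acuity_4: 1.207
metadata:
  source: American College of Cardiology model, 30-day mortality after TAVI
  intercept_unknown: true
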
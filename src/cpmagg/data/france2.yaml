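model_id: france2
intercept: 0.0
coefficients:
  age_ge_90: 0.420
  bmi_lt_18_5: 0.820
  bmi_18_5_29_9: 0.410
  nyha_iv: 0.580
  critical_preop: 0.870
  pulm_hypertension: 0.370
  copd: 0.500
  dialysis: 1.060
  ta_access: 0.700
  other_access: 0.780
metadata:
  source: FRANCE-2 model, 30-day mortality after TAVI
  intercept_unknown: true
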
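model_id: observant
intercept: 0.0
coefficients:
  nyha_iv: 0.600
  critical_preop: 0.750
  pulm_hypertension: 0.600
  lvef_lt_40: 0.450
  egfr_lt_45: 0.900
  diabetes: 0.600
  prior_bav: 0.450
metadata:
  source: Italian OBSERVANT model, 30-day mortality after TAVI
  intercept_unknown: true
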
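model_id: german_av
intercept: 0.0
coefficients:
  age_66_70: 0.461
  age_71_75: 0.909
  age_76_80: 1.292
  age_81_85: 1.782
  age_gt_85: 2.351
  female: 0.357
  bmi_lt_22: 0.359
  bmi_gt_35: 0.393
  nyha_iv: 0.532
  mi_3wk: 0.825
  critical_preop: 0.662
  pulm_hypertension: 0.398
  no_sinus_rhythm: 0.343
  lvef_30_50: 0.283
  lvef_lt_30: 0.570
  prior_cardiac_surgery: 0.307
  arterial_vessel_disease: 0.359
  copd: 0.318
  dialysis: 1.164
  emergency: 1.057
metadata:
  source: German Aortic Valve model, 30-day mortality after TAVI
  intercept_unknown: true
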
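{
 "name": "metabo_mortality_score_synthetic",
 "intercept": 0.0,
 "preprocessing": {
  "log": true,
  "zscale_scope": "per_dataset"
 },
 "weights": {
  "xxl_vldl_l": 0.1391,
  "s_hdl_l": -0.1959,
  "vldl_d": -0.3147,
  "pufa_by_fa": -0.585,
  "glucose": -0.0706,
  "lactate": 0.2495,
  "histidine": 0.0066,
  "isoleucine": 0.1024,
  "leucine": 0.2046,
  "valine": -0.1764,
  "phenylalanine": 0.5305,
  "acetoacetate": -0.1754,
  "albumin": 0.0747,
  "glyca": 0.5479
 },
 "note": "SYNTHETIC example weights in the documented score-file schema; not a published score. Real coefficient files are supplied by the user in this same format."
}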
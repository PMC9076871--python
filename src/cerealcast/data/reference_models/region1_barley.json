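{
  "cereal": "barley",
  "region": "region1",
  "terms": [
    {"variable": "TX", "month": "Mar", "coefficient": -0.39},
    {"variable": "TX", "month": "May", "coefficient": -0.33},
    {"variable": "PR", "month": "Apr", "coefficient": 0.53}
  ],
  "intercept": 0.0,
  "metrics": {"R": 0.88, "R2_adj": 0.73, "MAE": 0.38},
  "cv_metrics": {"R_cv": 0.82, "R2_adj_cv": 0.63, "MAE_cv": 0.45},
  "trace": []
}
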
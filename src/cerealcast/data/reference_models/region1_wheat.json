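{
  "cereal": "wheat",
  "region": "region1",
  "terms": [
    {"variable": "TX", "month": "Mar", "coefficient": -0.34},
    {"variable": "TX", "month": "May", "coefficient": -0.36},
    {"variable": "PR", "month": "Apr", "coefficient": 0.53}
  ],
  "intercept": 0.0,
  "metrics": {"R": 0.87, "R2_adj": 0.73, "MAE": 0.38},
  "cv_metrics": {"R_cv": 0.82, "R2_adj_cv": 0.62, "MAE_cv": 0.45},
  "trace": []
}
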
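{
  "cereal": "barley",
  "region": "region2",
  "terms": [
    {"variable": "TX", "month": "Nov", "coefficient": -0.54},
    {"variable": "TX", "month": "Mar", "coefficient": -0.36},
    {"variable": "TN", "month": "Oct", "coefficient": 0.38},
    {"variable": "PR", "month": "Apr", "coefficient": 0.33},
    {"variable": "PR", "month": "May", "coefficient": 0.48}
  ],
  "intercept": 0.0,
  "metrics": {"R": 0.91, "R2_adj": 0.78, "MAE": 0.33},
  "cv_metrics": {"R_cv": 0.85, "R2_adj_cv": 0.64, "MAE_cv": 0.44},
  "trace": []
}
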
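{
  "cereal": "wheat",
  "region": "region2",
  "terms": [
    {"variable": "TX", "month": "Dec", "coefficient": -0.25},
    {"variable": "PR", "month": "Nov", "coefficient": 0.33},
    {"variable": "PR", "month": "Mar", "coefficient": 0.49},
    {"variable": "PR", "month": "Apr", "coefficient": 0.69}
  ],
  "intercept": 0.0,
  "metrics": {"R": 0.85, "R2_adj": 0.67, "MAE": 0.42},
  "cv_metrics": {"R_cv": 0.78, "R2_adj_cv": 0.52, "MAE_cv": 0.52},
  "trace": []
}
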
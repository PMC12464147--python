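{
  "name": "SCORE2 10-year CVD risk, ages 40-69",
  "source": "SCORE2 working group and ESC Cardiovascular risk collaboration, Eur Heart J 2021;42:2439-2454 (doi:10.1093/eurheartj/ehab309), supplementary methods",
  "units": {"sbp": "mmHg", "total_cholesterol": "mmol/l", "hdl": "mmol/l"},
  "centering": {"age": [60, 5], "sbp": [120, 20], "total_cholesterol": [6, 1], "hdl": [1.3, 0.5]},
  "age_range": [40, 69],
  "sbp_range": [100, 179],
  "coefficients": {
    "male": {
      "age": 0.3742, "smoking": 0.6012, "sbp": 0.2777,
      "total_cholesterol": 0.1458, "hdl": -0.2698,
      "smoking_x_age": -0.0755, "sbp_x_age": -0.0255,
      "total_cholesterol_x_age": -0.0281, "hdl_x_age": 0.0426
    },
    "female": {
      "age": 0.4648, "smoking": 0.7744, "sbp": 0.3131,
      "total_cholesterol": 0.1002, "hdl": -0.2606,
      "smoking_x_age": -0.1088, "sbp_x_age": -0.0277,
      "total_cholesterol_x_age": -0.0226, "hdl_x_age": 0.0613
    }
  },
  "baseline_survival": {"male": 0.9605, "female": 0.9776},
  "calibration_scales": {
    "low":       {"male": [-0.5699, 0.7476], "female": [-0.7380, 0.7019]},
    "moderate":  {"male": [-0.1565, 0.8009], "female": [-0.3143, 0.7701]},
    "high":      {"male": [0.3207, 0.9360],  "female": [0.5710, 0.9369]},
    "very_high": {"male": [0.5836, 0.8294],  "female": [0.9412, 0.8329]}
  }
}
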
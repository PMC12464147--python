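{
  "name": "SCORE2-OP 10-year CVD risk, ages 70-89",
  "source": "SCORE2-OP working group and ESC Cardiovascular risk collaboration, Eur Heart J 2021;42:2455-2467 (doi:10.1093/eurheartj/ehab312), supplementary methods",
  "units": {"sbp": "mmHg", "total_cholesterol": "mmol/l", "hdl": "mmol/l"},
  "centering": {"age": [73, 1], "sbp": [150, 1], "total_cholesterol": [6, 1], "hdl": [1.4, 1]},
  "age_range": [70, 89],
  "sbp_range": [100, 179],
  "coefficients": {
    "male": {
      "age": 0.0634, "diabetes": 0.4245, "smoking": 0.3524, "sbp": 0.0094,
      "total_cholesterol": 0.0850, "hdl": -0.3564,
      "diabetes_x_age": -0.0174, "smoking_x_age": -0.0247, "sbp_x_age": -0.0005,
      "total_cholesterol_x_age": 0.0073, "hdl_x_age": 0.0091
    },
    "female": {
      "age": 0.0789, "diabetes": 0.6010, "smoking": 0.4921, "sbp": 0.0102,
      "total_cholesterol": 0.0605, "hdl": -0.3040,
      "diabetes_x_age": -0.0107, "smoking_x_age": -0.0255, "sbp_x_age": -0.0004,
      "total_cholesterol_x_age": -0.0009, "hdl_x_age": 0.0154
    }
  },
  "baseline_survival": {"male": 0.7576, "female": 0.8082},
  "mean_linear_predictor": {"male": 0.0929, "female": 0.3880},
  "calibration_scales": {
    "low":       {"male": [-0.34, 1.19], "female": [-0.52, 1.01]},
    "moderate":  {"male": [0.01, 1.25],  "female": [-0.30, 1.10]},
    "high":      {"male": [0.08, 1.15],  "female": [0.38, 1.10]},
    "very_high": {"male": [0.05, 0.70],  "female": [0.38, 0.69]}
  }
}
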
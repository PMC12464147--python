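{
  "name": "Framingham general cardiovascular disease 10-year risk",
  "source": "D'Agostino RB et al., General cardiovascular risk profile for use in primary care: the Framingham Heart Study. Circulation 2008;117:743-753 (doi:10.1161/CIRCULATIONAHA.107.699579), Table 2 (Cox, lipid-based)",
  "units": {"sbp": "mmHg", "total_cholesterol": "mg/dl", "hdl": "mg/dl"},
  "coefficients": {
    "male": {
      "ln_age": 3.06117, "ln_total_cholesterol": 1.12370, "ln_hdl": -0.93263,
      "ln_sbp_untreated": 1.93303, "ln_sbp_treated": 1.99881,
      "smoking": 0.65451, "diabetes": 0.57367
    },
    "female": {
      "ln_age": 2.32888, "ln_total_cholesterol": 1.20904, "ln_hdl": -0.70833,
      "ln_sbp_untreated": 2.76157, "ln_sbp_treated": 2.82263,
      "smoking": 0.52873, "diabetes": 0.69154
    }
  },
  "mean_linear_predictor": {"male": 23.9802, "female": 26.1931},
  "baseline_survival": {"male": 0.88936, "female": 0.95012}
}
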
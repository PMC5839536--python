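{
  "version": 1,
  "description": "Reduced Cox-type 10-year CVD risk coefficient set over the covariates available in the synthetic cohort. risk = 1 - S0(10)^exp(lp), lp centred at the reference profile. Users with the full covariate set (family history, CKD, AF, rheumatoid arthritis, Townsend score) may substitute a complete published file of the same shape.",
  "male": {
    "baseline_survival_10yr": 0.971,
    "reference": {"age": 42.0, "sbp": 125.0, "tchdl": 4.0, "bmi": 27.0, "deprivation": 3},
    "coefficients": {
      "age": 0.082,
      "age_squared": 0.0006,
      "sbp": 0.013,
      "tchdl": 0.18,
      "bmi": 0.025,
      "deprivation": 0.07,
      "smoking_ex": 0.18,
      "smoking_current": 0.62,
      "diabetes": 0.88,
      "treated_hypertension": 0.52,
      "ethnicity": {"white": 0.0, "indian": 0.30, "pakistani": 0.35, "caribbean": -0.06, "african": -0.20, "other": 0.05}
    }
  },
  "female": {
    "baseline_survival_10yr": 0.983,
    "reference": {"age": 42.0, "sbp": 125.0, "tchdl": 4.0, "bmi": 27.0, "deprivation": 3},
    "coefficients": {
      "age": 0.090,
      "age_squared": 0.0006,
      "sbp": 0.013,
      "tchdl": 0.16,
      "bmi": 0.028,
      "deprivation": 0.07,
      "smoking_ex": 0.20,
      "smoking_current": 0.70,
      "diabetes": 1.00,
      "treated_hypertension": 0.55,
      "ethnicity": {"white": 0.0, "indian": 0.32, "pakistani": 0.38, "caribbean": -0.05, "african": -0.18, "other": 0.05}
    }
  }
}
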
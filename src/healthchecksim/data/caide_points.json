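{
  "version": 1,
  "description": "Point-based 20-year dementia risk score from midlife cardiovascular risk factors: per-component point assignments and the monotone mapping from total points to 20-year risk. The physical-activity component has no counterpart variable in the cohort; its contribution is the configurable constant 'activity_points' (default 0).",
  "age_bands": [{"max_age": 46, "points": 0}, {"max_age": 53, "points": 3}, {"max_age": 200, "points": 4}],
  "education": {"ge10y": 0, "y7to9": 2, "le6y": 3},
  "sex": {"male": 1, "female": 0},
  "sbp_threshold": 140.0,
  "sbp_points": 2,
  "bmi_threshold": 30.0,
  "bmi_points": 2,
  "tc_threshold": 6.5,
  "tc_points": 2,
  "activity_points": 0,
  "risk_mapping": [
    {"max_points": 5, "risk": 0.010},
    {"max_points": 7, "risk": 0.019},
    {"max_points": 9, "risk": 0.042},
    {"max_points": 11, "risk": 0.074},
    {"max_points": 16, "risk": 0.164}
  ]
}
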
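{
  "version": 1,
  "description": "Synthetic EQ-5D-style utility table: baseline utility by age band, a multiplicative deprivation adjustment by quintile, and multiplicative disease decrements (combined multiplicatively under multimorbidity). Documented defaults in the range of published population norms; fully user-replaceable.",
  "age_bands": [
    {"max_age": 49, "utility": 0.87},
    {"max_age": 59, "utility": 0.85},
    {"max_age": 69, "utility": 0.82},
    {"max_age": 79, "utility": 0.78},
    {"max_age": 89, "utility": 0.73},
    {"max_age": 200, "utility": 0.68}
  ],
  "deprivation_multiplier": {"1": 1.00, "2": 0.99, "3": 0.98, "4": 0.97, "5": 0.95},
  "disease_multiplier": {"ihd": 0.88, "stroke": 0.80, "tia": 0.95, "dementia": 0.55, "lung_cancer": 0.70}
}
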
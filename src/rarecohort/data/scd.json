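{
  "name": "Sickle Cell Disease",
  "orpha_code": "232",
  "prevalence_denominator": 3300,
  "race_percent": {
    "African-American": 73.1,
    "European-American": 3.0,
    "Others": 23.9
  },
  "sex_percent": {
    "male": 50.0,
    "female": 50.0
  },
  "diagnosis": {
    "unit": "months",
    "low": 5.0,
    "high": 6.0,
    "mu": 5.5,
    "spread": 0.5
  },
  "death_rate_per_100k": {
    "<5": 0.47,
    "5-14": 0.3,
    "15-19": 0.7,
    "20-24": 1.35,
    "25-39": 2.75,
    "40-60": 2.85,
    ">60": 1.99
  },
  "clinical_params": [
    {
      "name": "complete_blood_count",
      "unit": "g/dL",
      "low": 6.0,
      "high": 11.0,
      "mu": 8.5,
      "spread": 2.5
    },
    {
      "name": "reticulocyte_count",
      "unit": "%",
      "low": 2.0,
      "high": 3.0,
      "mu": 2.5,
      "spread": 0.5
    }
  ]
}
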
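{
  "name": "Duchenne Muscular Dystrophy",
  "orpha_code": "98896",
  "prevalence_denominator": 6000,
  "race_percent": {
    "African-American": 29.0,
    "European-American": 43.0,
    "Others": 28.0
  },
  "sex_percent": {
    "male": 99.99,
    "female": 0.01
  },
  "diagnosis": {
    "unit": "years",
    "low": 1.0,
    "high": 3.0,
    "mu": 2.0,
    "spread": 1.0
  },
  "death_rate_per_100k": {
    "<5": 200.0,
    "5-14": 200.0,
    "15-19": 200.0,
    "20-24": 40500.0,
    "25-39": 73900.0,
    "40-60": 86700.0,
    ">60": 99990.0
  },
  "clinical_params": [
    {
      "name": "creatine_kinase",
      "unit": "units/L",
      "low": 350.0,
      "high": 23200.0,
      "mu": 11775.0,
      "spread": 6475.0
    }
  ]
}
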
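{
  "name": "Cystic Fibrosis",
  "orpha_code": "586",
  "prevalence_denominator": 10311,
  "race_percent": {
    "African-American": 3.5,
    "European-American": 91.4,
    "Others": 5.1
  },
  "sex_percent": {
    "male": 51.7,
    "female": 49.3
  },
  "diagnosis": {
    "unit": "days",
    "low": 2.0,
    "high": 3.0,
    "mu": 2.5,
    "spread": 0.5
  },
  "death_rate_per_100k": {
    "<5": 6.23,
    "5-14": 12.46,
    "15-19": 40.5,
    "20-24": 71.65,
    "25-39": 280.37,
    "40-60": 190.03,
    ">60": 121.5
  },
  "clinical_params": [
    {
      "name": "chloride_level",
      "unit": "mmol/L",
      "low": 30.0,
      "high": 118.6,
      "mu": 74.3,
      "spread": 44.3
    }
  ]
}
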
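{
  "none": {
    "n": 24662,
    "age_mean_sd": [53, 16],
    "asa": {"1": 2577, "2": 11533, "3": 10532},
    "outpatient": 16321,
    "male": 10833,
    "nonsmoker": 22571,
    "prior_ponv": 4604,
    "duration_mean_sd": [120, 94],
    "n2o_exposed": 3152,
    "high_risk_surgery": 4425,
    "prophylactic_median_iqr": [2, 2, 3],
    "pacu_opioids": 12969,
    "apfel_median_iqr": [2, 2, 3],
    "ponv_observed": 4255
  },
  "current": {
    "n": 1976,
    "age_mean_sd": [48, 15],
    "asa": {"1": 176, "2": 925, "3": 875},
    "outpatient": 1212,
    "male": 1055,
    "nonsmoker": 1526,
    "prior_ponv": 368,
    "duration_mean_sd": [126, 105],
    "n2o_exposed": 240,
    "high_risk_surgery": 341,
    "prophylactic_median_iqr": [2, 2, 3],
    "pacu_opioids": 1184,
    "apfel_median_iqr": [2, 1, 3],
    "ponv_observed": 372
  },
  "daily": {
    "n": 750,
    "age_mean_sd": [50, 14],
    "asa": {"1": 19, "2": 292, "3": 439},
    "outpatient": 438,
    "male": 390,
    "nonsmoker": 525,
    "prior_ponv": 191,
    "duration_mean_sd": [133, 110],
    "n2o_exposed": 111,
    "high_risk_surgery": 146,
    "prophylactic_median_iqr": [2, 1, 2],
    "pacu_opioids": 476,
    "apfel_median_iqr": [2, 1, 3],
    "ponv_observed": 164
  }
}
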
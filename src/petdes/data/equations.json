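{
  "ttc_ad": {
    "family": "lognormal_aft",
    "intercept": 4.571,
    "terms": {"male": 0.327, "mixed_ad": 0.252, "ckd": -0.353},
    "dispersion": 0.965,
    "time_unit": "days"
  },
  "ttc_vad": {
    "family": "lognormal_aft",
    "intercept": 4.529,
    "terms": {"diabetes": 0.158, "hypertension": 0.203, "stroke": 0.385},
    "dispersion": 1.005,
    "time_unit": "days"
  },
  "ttc_other": {
    "family": "lognormal_aft",
    "intercept": 6.558,
    "terms": {"age": -0.029, "stroke": 1.554, "lbd": 0.654, "ftd": 0.4},
    "dispersion": 0.896,
    "time_unit": "days"
  },
  "ttc_predementia": {
    "family": "lognormal_aft",
    "intercept": 3.981,
    "terms": {"age": 0.009, "ckd": -0.243, "cvd": -0.179},
    "dispersion": 0.994,
    "time_unit": "days"
  },
  "tti_dementia": {
    "family": "lognormal_aft",
    "intercept": 7.149,
    "terms": {"age": -0.022, "vad": 1.056, "other_nonad": 2.091, "time_to_dx_days": 0.004},
    "dispersion": 1.517,
    "time_unit": "days"
  },
  "tti_predementia": {
    "family": "lognormal_aft",
    "intercept": 18.781,
    "terms": {"age": -0.15},
    "dispersion": 3.996,
    "time_unit": "days"
  },
  "disc_dementia": {
    "family": "weibull_aft",
    "intercept": 7.487,
    "terms": {"time_to_dx_days": -0.0008},
    "dispersion": 0.922,
    "time_unit": "days"
  },
  "disc_predementia": {
    "family": "weibull_aft",
    "intercept": 7.122,
    "terms": {"converted": 0.443},
    "dispersion": 1.131,
    "time_unit": "days"
  },
  "conversion": {
    "family": "weibull_rate",
    "intercept": 0.0,
    "terms": {},
    "rate": 0.0212,
    "dispersion": 0.952,
    "time_unit": "months"
  },
  "inst_dementia": {
    "family": "weibull_aft",
    "intercept": 9.883,
    "terms": {"age": -0.02, "vad": 0.295, "other_nonad": 1.154, "time_to_dx_days": -0.001, "treated": 1.079},
    "dispersion": 0.933,
    "time_unit": "days"
  },
  "inst_predementia": {
    "family": "weibull_aft",
    "intercept": 11.469,
    "terms": {"age": -0.028},
    "dispersion": 1.373,
    "time_unit": "days"
  },
  "mortality_male": {
    "family": "gompertz",
    "intercept": -9.697,
    "terms": {},
    "dispersion": 0.087,
    "time_unit": "years"
  },
  "mortality_female": {
    "family": "gompertz",
    "intercept": -10.787,
    "terms": {},
    "dispersion": 0.097,
    "time_unit": "years"
  },
  "mmse_rate": {
    "family": "linear",
    "intercept": 5.4663,
    "terms": {"pm1": -0.42, "pm2": -0.0042, "pm3": 0.1415, "prev_rate": -0.079, "age": 0.07474},
    "time_unit": "years"
  },
  "npi_rate": {
    "family": "linear",
    "intercept": 5.74,
    "terms": {"treated": -0.64, "weeks": 0.03, "npi_base": -0.59, "npi_recent": 0.24, "white": -1.74, "black": -3.82, "psymed": 2.34, "mmse_base": 0.12, "mmse_recent": -0.22},
    "post_multiplier": 1.44,
    "time_unit": "years"
  },
  "adl_rate": {
    "family": "linear",
    "intercept": 1.35,
    "terms": {"treated": -0.81, "weeks": 0.06, "adl_base": -0.79, "iadl_previous": 0.71, "mmse_base": 0.12, "age": 0.09, "psymed": 0.81, "black": -3.05, "mmse_recent": -0.49},
    "time_unit": "years"
  },
  "iadl_rate": {
    "family": "linear",
    "intercept": 1.27,
    "terms": {"treated": 0.63, "weeks": 0.17, "treated_x_weeks": -0.06, "iadl_base": -0.84, "iadl_base_x_weeks": -0.002, "iadl_previous": 0.84, "male": -0.67, "mmse_base": 0.2, "mmse_recent": -0.28, "adl_base": -0.16, "adl_recent": 0.18},
    "time_unit": "years"
  },
  "patient_utility": {
    "family": "linear",
    "intercept": 0.408,
    "terms": {"mmse": 0.01, "npi": -0.004, "institutionalized": -0.159, "living_with_caregiver": 0.051},
    "time_unit": "years"
  },
  "caregiver_utility": {
    "family": "linear",
    "intercept": 0.9,
    "terms": {"caregiver_age": -0.003, "caregiver_male": 0.03, "male": 0.001, "npi": -0.001, "adl": -0.001, "iadl": -0.0004, "psymed": -0.01},
    "time_unit": "years"
  }
}
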
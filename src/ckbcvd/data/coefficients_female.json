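{
 "metadata": {
  "provenance": "Published sex-specific CKB-CVD 10-year risk models. Log hazard ratios are ln(HR) at the printed 2-decimal precision of the published hazard-ratio table; exact regression coefficients were not released.",
  "version": "ckb-cvd-1.0"
 },
 "schema_version": "1",
 "sex": "female",
 "submodels": {
  "HS": {
   "outcome": "HS",
   "predictors": {
    "age": {
     "center": 55.0,
     "hr_main": 1.51,
     "log_hr_main": 0.412109650826833
    },
    "bp_treatment": {
     "center": 0.0,
     "hr_age_interaction": 0.96,
     "hr_main": 1.62,
     "log_hr_age_interaction": -0.040821994520255166,
     "log_hr_main": 0.4824261492442928
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.28,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.2468600779315258
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.96,
     "hr_main": 1.32,
     "log_hr_age_interaction": -0.040821994520255166,
     "log_hr_main": 0.27763173659827955
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.95,
     "hr_main": 1.5,
     "log_hr_age_interaction": -0.05129329438755058,
     "log_hr_main": 0.4054651081081644
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.16,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.14842000511827322
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.99,
     "hr_main": 0.92,
     "log_hr_age_interaction": -0.01005033585350145,
     "log_hr_main": -0.08338160893905101
    }
   },
   "s0_10": 0.986
  },
  "IHD": {
   "outcome": "IHD",
   "predictors": {
    "age": {
     "center": 55.0,
     "hr_main": 1.4,
     "log_hr_main": 0.3364722366212129
    },
    "bp_treatment": {
     "center": 0.0,
     "hr_age_interaction": 0.95,
     "hr_main": 1.55,
     "log_hr_age_interaction": -0.05129329438755058,
     "log_hr_main": 0.4382549309311553
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.17,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.1570037488096647
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.99,
     "hr_main": 1.05,
     "log_hr_age_interaction": -0.01005033585350145,
     "log_hr_main": 0.04879016416943205
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.94,
     "hr_main": 1.59,
     "log_hr_age_interaction": -0.06187540371808753,
     "log_hr_main": 0.4637340162321402
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 1.0,
     "hr_main": 1.02,
     "log_hr_age_interaction": 0.0,
     "log_hr_main": 0.01980262729617973
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.16,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.14842000511827322
    }
   },
   "s0_10": 0.9
  },
  "IS": {
   "outcome": "IS",
   "predictors": {
    "age": {
     "center": 55.0,
     "hr_main": 1.45,
     "log_hr_main": 0.371563556432483
    },
    "bp_treatment": {
     "center": 0.0,
     "hr_age_interaction": 0.96,
     "hr_main": 1.54,
     "log_hr_age_interaction": -0.040821994520255166,
     "log_hr_main": 0.43178241642553783
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 0.93,
     "hr_main": 1.3,
     "log_hr_age_interaction": -0.07257069283483537,
     "log_hr_main": 0.26236426446749106
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.99,
     "hr_main": 1.11,
     "log_hr_age_interaction": -0.01005033585350145,
     "log_hr_main": 0.10436001532424286
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.9,
     "hr_main": 1.82,
     "log_hr_age_interaction": -0.10536051565782628,
     "log_hr_main": 0.598836501088704
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.09,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.08617769624105241
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.11,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.10436001532424286
    }
   },
   "s0_10": 0.91
  }
 }
}
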
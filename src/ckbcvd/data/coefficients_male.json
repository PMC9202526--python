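{
 "metadata": {
  "provenance": "Published sex-specific CKB-CVD 10-year risk models. Log hazard ratios are ln(HR) at the printed 2-decimal precision of the published hazard-ratio table; exact regression coefficients were not released.",
  "version": "ckb-cvd-1.0"
 },
 "schema_version": "1",
 "sex": "male",
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
     "hr_age_interaction": 0.95,
     "hr_main": 1.48,
     "log_hr_age_interaction": -0.05129329438755058,
     "log_hr_main": 0.3920420877760237
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 1.0,
     "hr_main": 1.1,
     "log_hr_age_interaction": 0.0,
     "log_hr_main": 0.09531017980432493
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.95,
     "hr_main": 1.33,
     "log_hr_age_interaction": -0.05129329438755058,
     "log_hr_main": 0.28517894223366247
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.96,
     "hr_main": 1.45,
     "log_hr_age_interaction": -0.040821994520255166,
     "log_hr_main": 0.371563556432483
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 0.99,
     "hr_main": 1.18,
     "log_hr_age_interaction": -0.01005033585350145,
     "log_hr_main": 0.16551443847757333
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.98,
     "hr_main": 0.92,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": -0.08338160893905101
    }
   },
   "s0_10": 0.983
  },
  "IHD": {
   "outcome": "IHD",
   "predictors": {
    "age": {
     "center": 55.0,
     "hr_main": 1.43,
     "log_hr_main": 0.3576744442718159
    },
    "bp_treatment": {
     "center": 0.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.59,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.4637340162321402
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.22,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.19885085874516517
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.1,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.09531017980432493
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.91,
     "hr_main": 1.82,
     "log_hr_age_interaction": -0.09431067947124129,
     "log_hr_main": 0.598836501088704
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 1.0,
     "hr_main": 1.05,
     "log_hr_age_interaction": 0.0,
     "log_hr_main": 0.04879016416943205
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.13,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.12221763272424911
    }
   },
   "s0_10": 0.929
  },
  "IS": {
   "outcome": "IS",
   "predictors": {
    "age": {
     "center": 55.0,
     "hr_main": 1.52,
     "log_hr_main": 0.41871033485818504
    },
    "bp_treatment": {
     "center": 0.0,
     "hr_age_interaction": 0.94,
     "hr_main": 1.59,
     "log_hr_age_interaction": -0.06187540371808753,
     "log_hr_main": 0.4637340162321402
    },
    "daily_smoker": {
     "center": 0.0,
     "hr_age_interaction": 0.97,
     "hr_main": 1.29,
     "log_hr_age_interaction": -0.030459207484708574,
     "log_hr_main": 0.25464221837358075
    },
    "dbp": {
     "center": 80.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.15,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.13976194237515863
    },
    "diabetes": {
     "center": 0.0,
     "hr_age_interaction": 0.94,
     "hr_main": 1.83,
     "log_hr_age_interaction": -0.06187540371808753,
     "log_hr_main": 0.6043159668533296
    },
    "sbp": {
     "center": 120.0,
     "hr_age_interaction": 0.98,
     "hr_main": 1.13,
     "log_hr_age_interaction": -0.020202707317519466,
     "log_hr_main": 0.12221763272424911
    },
    "waist": {
     "center": 80.0,
     "hr_age_interaction": 0.99,
     "hr_main": 1.08,
     "log_hr_age_interaction": -0.01005033585350145,
     "log_hr_main": 0.0769610411361284
    }
   },
   "s0_10": 0.928
  }
 }
}
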
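{
  "currency": "PPP_int$_2020",
  "screening": {
    "participation_healthy": {"value": 0.563, "source": "national campaign"},
    "participation_untreated": {"value": 0.673, "source": "national campaign"},
    "sensitivity": {"value": 0.746, "ci": [0.607, 0.848]},
    "specificity": {"value": 0.746, "ci": [0.479, 0.904]},
    "confirm_sensitivity": {"value": 1.0, "source": "assumption: perfect diagnostic test"},
    "confirm_specificity": {"value": 1.0, "source": "assumption: perfect diagnostic test"},
    "uptake_true_positive": {"value": 0.9, "source": "national campaign"},
    "p_false_positive": 0.254
  },
  "effects": {
    "rr_chd_on_treatment": {"value": 0.675, "ci": [0.633, 0.717]},
    "rr_stroke_on_treatment": {"value": 0.622, "ci": [0.526, 0.717]},
    "rr_chd_recurrence": {"value": 2.4, "ci": [1.9, 2.8]},
    "p_stroke_recurrence": {"value": 0.0485, "ci": [0.0312, 0.069]}
  },
  "decomposition": {
    "chd_fatal": {"value": 0.122, "ci": [0.066, 0.178]},
    "chd_mi": {"value": 0.261, "ci": [0.143, 0.378]},
    "chd_sa": {"value": 0.503, "ci": [0.377, 0.629]},
    "chd_ua": {"value": 0.157, "ci": [0.104, 0.209]},
    "stroke_fatal": {"value": 0.1435, "ci": [0.122, 0.165]},
    "stroke_nonfatal": {"value": 0.518, "ci": [0.517, 0.701]},
    "stroke_tia": {"value": 0.188, "ci": [0.134, 0.361]}
  },
  "post_risks": {
    "cv_death_post_mi": {"value": 0.027, "ci": [0.0248, 0.0291]},
    "cv_death_post_stroke": {"value": 0.027, "ci": [0.0259, 0.0285]},
    "cv_death_post_sa": {"value": 0.020, "ci": [0.0165, 0.0231]},
    "cv_death_post_ua": {"value": 0.022, "ci": [0.0205, 0.0233]},
    "cv_death_post_tia": {"value": 0.014, "ci": [0.011, 0.018]},
    "event_risk_false_positive_chd": {"value": 0.010, "ci": [0.0009, 0.019053]},
    "event_risk_false_positive_stroke": {"value": 0.003, "ci": [0.0003, 0.0048]},
    "event_risk_true_positive_chd": {"value": 0.014, "ci": [0.00171, 0.026]},
    "event_risk_true_positive_stroke": {"value": 0.006, "ci": [0.000702, 0.0119]},
    "event_risk_false_negative_chd": {"value": 0.014, "ci": [0.00171, 0.0265]},
    "event_risk_false_negative_stroke": {"value": 0.006, "ci": [0.0007, 0.0119]}
  },
  "costs": {
    "screening_contact": {"value": 1.56, "ci": [1.06, 2.07]},
    "confirmatory_workup": {"value": 212.57},
    "tx_new_no_screen": {"value": 137.85},
    "tx_new_with_screen": {"value": 139.41},
    "tx_previous": {"value": 57.56, "ci": [41.25, 73.86]},
    "tx_average": {"value": 63.72, "ci": [42.62, 84.81]},
    "event_year": {
      "mi": {"value": 16018.61, "ci": [10691.10, 21346.13]},
      "ua": {"value": 10484.27, "ci": [7815.56, 13153.0]},
      "sa": {"value": 8111.67, "ci": [3224.58, 12998.75]},
      "stroke": {"value": 45152.33, "ci": [40186.0, 50119.0]},
      "tia": {"value": 9077.78, "ci": [553.45, 17602.10]}
    },
    "post_event_incremental": {
      "post_mi": {"value": 471.33, "ci": [337.07, 605.60]},
      "post_stroke": {"value": 8618.0, "ci": [2376.4, 14859.7]},
      "post_sa": {"value": 121.68},
      "post_tia": {"value": 237.93},
      "post_ua": {"value": 282.80}
    },
    "death_year": {
      "chd": {"value": 8872.59},
      "stroke": {"value": 32119.09}
    }
  },
  "utilities": {
    "healthy": 1.0,
    "htn_off_tx": {"value": 0.946, "ci": [0.922, 0.97]},
    "htn_on_tx": 1.0,
    "post_mi": {"value": 0.760, "ci": [0.626, 0.894]},
    "post_stroke": {"value": 0.629, "ci": [0.323, 0.935]},
    "post_sa": {"value": 0.808, "ci": [0.674, 0.942]},
    "post_tia": 1.0,
    "post_ua": {"value": 0.770, "ci": [0.636, 0.904]},
    "dead": 0.0
  },
  "initial": {
    "healthy": 0.921,
    "htn_on_tx": 0.041,
    "htn_off_tx": 0.037
  },
  "config": {
    "discount_rate_costs": 0.05,
    "discount_rate_outcomes": 0.05,
    "n_cycles": 70,
    "cohort_entry_age": 30,
    "wtp_threshold": 20652.44,
    "psa_iterations": 1000,
    "rng_seed": 0
  }
}
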
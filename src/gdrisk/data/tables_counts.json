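{
  "note": "Published subgroup case/control counts for the analysis cohort of 3533 nulliparous women (132 gestational-diabetes cases, 3401 controls), transcribed from the stratified association tables of the source study. The 'printed' entries retain the published odds ratios (rest-of-cohort reference, Woolf 95% CI, Fisher exact p) and positive likelihood ratios (whole-cohort reference, bootstrap 95% CI) for cross-checking; counts are the primary payload.",
  "cohort": {"cases": 132, "controls": 3401},
  "covariate_blocks": {
    "family_history": {
      "parent": {"cases": 45, "controls": 591,
                 "printed": {"or": 2.5, "or_ci": [1.7, 3.6], "lr": 2.0, "lr_ci": [1.5, 2.5]}},
      "children": {
        "prs_bottom25": {"cases": 9, "controls": 129,
                         "printed": {"or": 1.9, "or_ci": [0.9, 3.7], "lr": 1.8, "lr_ci": [0.7, 3.1]}},
        "prs_top25": {"cases": 16, "controls": 172,
                      "printed": {"or": 2.6, "or_ci": [1.5, 4.5], "lr": 2.4, "lr_ci": [1.3, 3.7]}},
        "mets_ge450": {"cases": 21, "controls": 377,
                       "printed": {"or": 1.5, "or_ci": [0.9, 2.4], "lr": 1.4, "lr_ci": [0.9, 2.1]}},
        "mets_lt450": {"cases": 24, "controls": 214,
                       "printed": {"or": 3.3, "or_ci": [2.1, 5.3], "lr": 2.9, "lr_ci": [1.8, 4.1]}}
      }
    },
    "age_ge35": {
      "parent": {"cases": 33, "controls": 332,
                 "printed": {"or": 3.1, "or_ci": [2.1, 4.6], "lr": 2.6, "lr_ci": [1.8, 3.4]}},
      "children": {
        "prs_bottom25": {"cases": 6, "controls": 88,
                         "printed": {"or": 1.8, "or_ci": [0.8, 4.2], "lr": 1.8, "lr_ci": [0.6, 3.4]}},
        "prs_top25": {"cases": 14, "controls": 78,
                      "printed": {"or": 5.1, "or_ci": [2.8, 9.2], "lr": 4.6, "lr_ci": [2.4, 7.5]}},
        "mets_ge450": {"cases": 18, "controls": 237,
                       "printed": {"or": 2.1, "or_ci": [1.3, 3.5], "lr": 2.0, "lr_ci": [1.1, 2.9]}},
        "mets_lt450": {"cases": 15, "controls": 95,
                       "printed": {"or": 4.5, "or_ci": [2.5, 7.9], "lr": 4.1, "lr_ci": [2.2, 6.5]}}
      }
    },
    "bmi_ge25": {
      "parent": {"cases": 85, "controls": 1368,
                 "printed": {"or": 2.7, "or_ci": [1.9, 3.9], "lr": 1.6, "lr_ci": [1.4, 1.8]}},
      "children": {
        "prs_bottom25": {"cases": 12, "controls": 347,
                         "printed": {"or": 0.9, "or_ci": [0.5, 1.6], "lr": 0.9, "lr_ci": [0.4, 1.4]}},
        "prs_top25": {"cases": 34, "controls": 337,
                      "printed": {"or": 3.2, "or_ci": [2.1, 4.7], "lr": 2.6, "lr_ci": [1.8, 3.5]}},
        "mets_ge450": {"cases": 45, "controls": 854,
                       "printed": {"or": 1.5, "or_ci": [1.1, 2.2], "lr": 1.4, "lr_ci": [1.0, 1.7]}},
        "mets_lt450": {"cases": 40, "controls": 514,
                       "printed": {"or": 2.4, "or_ci": [1.7, 3.6], "lr": 2.0, "lr_ci": [1.5, 2.6]}}
      }
    }
  },
  "prs_mets": {
    "prs_bottom25": {"cases": 20, "controls": 863,
                     "printed": {"or": 0.5, "or_ci": [0.3, 0.9], "lr": 0.6, "lr_ci": [0.4, 0.9]},
      "children": {
        "mets_lt450": {"cases": 8, "controls": 264,
                       "printed": {"or": 0.8, "or_ci": [0.4, 1.6], "lr": 0.8, "lr_ci": [0.3, 1.4]}},
        "mets_ge450": {"cases": 12, "controls": 599,
                       "printed": {"or": 0.5, "or_ci": [0.3, 0.9], "lr": 0.5, "lr_ci": [0.3, 0.8]}}
      }
    },
    "prs_top25": {"cases": 55, "controls": 829,
                  "printed": {"or": 2.2, "or_ci": [1.6, 3.2], "lr": 1.7, "lr_ci": [1.4, 2.1]},
      "children": {
        "mets_lt450": {"cases": 31, "controls": 278,
                       "printed": {"or": 3.4, "or_ci": [2.3, 5.3], "lr": 2.9, "lr_ci": [2.0, 3.9]}},
        "mets_ge450": {"cases": 24, "controls": 551,
                       "printed": {"or": 1.1, "or_ci": [0.7, 1.8], "lr": 1.1, "lr_ci": [0.7, 1.6]}}
      }
    },
    "mets_ge450": {"cases": 74, "controls": 2291,
                   "printed": {"or": 0.6, "or_ci": [0.4, 0.9], "lr": 0.8, "lr_ci": [0.7, 1.0]},
      "children": {
        "prs_bottom25": {"cases": 12, "controls": 599,
                         "printed": {"or": 0.5, "or_ci": [0.3, 0.9], "lr": 0.5, "lr_ci": [0.3, 0.8]}},
        "prs_top25": {"cases": 24, "controls": 551,
                      "printed": {"or": 1.1, "or_ci": [0.7, 1.8], "lr": 1.1, "lr_ci": [0.7, 1.6]}}
      }
    },
    "mets_lt450": {"cases": 58, "controls": 1110,
                   "printed": {"or": 1.6, "or_ci": [1.1, 2.3], "lr": 1.3, "lr_ci": [1.1, 1.6]},
      "children": {
        "prs_bottom25": {"cases": 8, "controls": 264,
                         "printed": {"or": 0.8, "or_ci": [0.4, 1.6], "lr": 0.8, "lr_ci": [0.3, 1.4]}},
        "prs_top25": {"cases": 31, "controls": 278,
                      "printed": {"or": 3.4, "or_ci": [2.3, 5.3], "lr": 2.9, "lr_ci": [2.0, 3.9]}}
      }
    }
  },
  "figure_quartiles": {
    "prs_q4_vs_q1": {"printed": {"or": 2.9, "or_ci": [1.7, 4.8]},
                     "comment": "Top PRS quartile (55/829) vs the lowest quartile (20/863) as reference group."}
  }
}
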
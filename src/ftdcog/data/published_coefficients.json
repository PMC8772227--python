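{
  "description": "Published GENFI-Cog per-gene penalized logistic regression coefficients (change in log odds of carrier status per z-score unit) and the corresponding published composite weights. Tests with positive coefficients were excluded from the composites ('excluded': true); their printed weight is null.",
  "genes": {
    "C9orf72": [
      {"test": "category_fluency", "coefficient": -0.13, "printed_weight": 0.09, "excluded": false},
      {"test": "cwit_colour", "coefficient": -0.06, "printed_weight": 0.04, "excluded": false},
      {"test": "cwit_word", "coefficient": -0.04, "printed_weight": 0.03, "excluded": false},
      {"test": "tmt_b", "coefficient": -0.07, "printed_weight": 0.05, "excluded": false},
      {"test": "cwit_ink", "coefficient": -0.29, "printed_weight": 0.20, "excluded": false},
      {"test": "benson_copy", "coefficient": -0.09, "printed_weight": 0.06, "excluded": false},
      {"test": "fcsrt_free", "coefficient": -0.50, "printed_weight": 0.35, "excluded": false},
      {"test": "facial_emotion", "coefficient": -0.26, "printed_weight": 0.18, "excluded": false}
    ],
    "GRN": [
      {"test": "camel_cactus", "coefficient": -0.004, "printed_weight": 0.003, "excluded": false},
      {"test": "cwit_word", "coefficient": 0.09, "printed_weight": null, "excluded": true},
      {"test": "tmt_b", "coefficient": -0.28, "printed_weight": 0.23, "excluded": false},
      {"test": "cwit_ink", "coefficient": -0.24, "printed_weight": 0.20, "excluded": false},
      {"test": "phonemic_fluency", "coefficient": 0.24, "printed_weight": null, "excluded": true},
      {"test": "benson_recall", "coefficient": -0.06, "printed_weight": 0.05, "excluded": false},
      {"test": "fcsrt_total", "coefficient": -0.05, "printed_weight": 0.04, "excluded": false},
      {"test": "fcsrt_delayed_free", "coefficient": -0.16, "printed_weight": 0.13, "excluded": false},
      {"test": "facial_emotion", "coefficient": -0.42, "printed_weight": 0.35, "excluded": false}
    ],
    "MAPT": [
      {"test": "camel_cactus", "coefficient": -0.04, "printed_weight": 0.04, "excluded": false},
      {"test": "boston_naming", "coefficient": -0.39, "printed_weight": 0.40, "excluded": false},
      {"test": "cwit_colour", "coefficient": -0.09, "printed_weight": 0.09, "excluded": false},
      {"test": "benson_recall", "coefficient": -0.01, "printed_weight": 0.01, "excluded": false},
      {"test": "fcsrt_free", "coefficient": -0.06, "printed_weight": 0.06, "excluded": false},
      {"test": "fcsrt_total", "coefficient": -0.30, "printed_weight": 0.31, "excluded": false},
      {"test": "fcsrt_delayed_free", "coefficient": -0.01, "printed_weight": 0.01, "excluded": false},
      {"test": "facial_emotion", "coefficient": -0.08, "printed_weight": 0.08, "excluded": false}
    ]
  }
}
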
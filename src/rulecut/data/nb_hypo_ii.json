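{
  "schema_version": 1,
  "classes": ["Good", "Poor"],
  "rules": [
    {"rule_id": "1", "predicted_class": "Good",
     "conditions": [{"feature": "217356_s_at", "op": "LE", "threshold": 721},
                    {"feature": "226452_at", "op": "LT", "threshold": 326}],
     "stats": {"covering": 0.80, "error": 0.035, "fisher_p": 0.001}},
    {"rule_id": "2", "predicted_class": "Good",
     "conditions": [{"feature": "206686_at", "op": "LE", "threshold": 26},
                    {"feature": "226452_at", "op": "LE", "threshold": 326}],
     "stats": {"covering": 0.70, "error": 0.14, "fisher_p": 0.001}},
    {"rule_id": "3", "predicted_class": "Good",
     "conditions": [{"feature": "200738_s_at", "op": "LE", "threshold": 1846},
                    {"feature": "230630_at", "op": "GT", "threshold": 23}],
     "stats": {"covering": 0.62, "error": 0.10, "fisher_p": 0.001}},
    {"rule_id": "4", "predicted_class": "Good",
     "conditions": [{"feature": "209446_s_at", "op": "LE", "threshold": 57},
                    {"feature": "223172_s_at", "op": "LT", "threshold": 73}],
     "stats": {"covering": 0.60, "error": 0.10, "fisher_p": 0.001}},
    {"rule_id": "5", "predicted_class": "Good",
     "conditions": [{"feature": "202022_at", "op": "GT", "threshold": 131},
                    {"feature": "223193_x_at", "op": "LT", "threshold": 324}],
     "stats": {"covering": 0.60, "error": 0.14, "fisher_p": 0.001}},
    {"rule_id": "6", "predicted_class": "Good",
     "conditions": [{"feature": "224314_s_at", "op": "LE", "threshold": 29},
                    {"feature": "236180_at", "op": "LT", "threshold": 13}],
     "stats": {"covering": 0.48, "error": 0.071, "fisher_p": 0.001}},
    {"rule_id": "7", "predicted_class": "Poor",
     "conditions": [{"feature": "217356_s_at", "op": "GT", "threshold": 721}],
     "stats": {"covering": 0.92, "error": 0.17, "fisher_p": 0.001}},
    {"rule_id": "8", "predicted_class": "Poor",
     "conditions": [{"feature": "223172_s_at", "op": "GT", "threshold": 73},
                    {"feature": "226452_at", "op": "GT", "threshold": 326}],
     "stats": {"covering": 0.60, "error": 0.086, "fisher_p": 0.001}},
    {"rule_id": "9", "predicted_class": "Poor",
     "conditions": [{"feature": "206686_at", "op": "GT", "threshold": 26},
                    {"feature": "223172_s_at", "op": "GT", "threshold": 73}],
     "stats": {"covering": 0.57, "error": 0.074, "fisher_p": 0.001}}
  ],
  "relevance": {
    "signed": {
      "Good": {"200738_s_at": -0.49, "202022_at": 0.5, "206686_at": -0.48,
               "209446_s_at": -0.25, "217356_s_at": -0.74, "223172_s_at": -0.35,
               "223193_x_at": -0.1, "224314_s_at": -0.22, "226452_at": -0.26,
               "230630_at": 0.13, "236180_at": -0.25},
      "Poor": {"200738_s_at": 0, "202022_at": 0, "206686_at": 0.26,
               "209446_s_at": 0, "217356_s_at": 0.92, "223172_s_at": 0.48,
               "223193_x_at": 0, "224314_s_at": 0, "226452_at": 0.34,
               "230630_at": 0, "236180_at": 0}
    }
  },
  "majority_class": "Good",
  "metadata": {
    "name": "NB-hypo-II",
    "description": "9-rule neuroblastoma outcome classifier over 11 hypoxia probe sets; thresholds on the MAS5 intensity scale.",
    "fisher_p_printed": "<0.001",
    "cohort": {
      "training": {"n": 109, "Good": 81, "Poor": 28},
      "test": {"n": 73, "Good": 50, "Poor": 23},
      "signature_size": 62
    },
    "km_comparison": [
      {"row": 1, "feature": "223172_s_at", "overall_km": 107, "rulex": 73,
       "overall_worse": "high", "relapse_free_km": 107, "relapse_free_worse": "high"},
      {"row": 2, "feature": "200738_s_at", "overall_km": 1553, "rulex": 1846,
       "overall_worse": "high", "relapse_free_km": 1553, "relapse_free_worse": "high"},
      {"row": 3, "feature": "209446_s_at", "overall_km": 69, "rulex": 57,
       "overall_worse": "high", "relapse_free_km": 69, "relapse_free_worse": "high"},
      {"row": 4, "feature": "226452_at", "overall_km": 280, "rulex": 326,
       "overall_worse": "high", "relapse_free_km": 280, "relapse_free_worse": "high"},
      {"row": 5, "feature": "217356_s_at", "overall_km": 706, "rulex": 721,
       "overall_worse": "high", "relapse_free_km": 706, "relapse_free_worse": "high"},
      {"row": 6, "feature": "236180_at", "overall_km": 18, "rulex": 13,
       "overall_worse": "high", "relapse_free_km": 13, "relapse_free_worse": "high",
       "note": "source table prints the direction with a typo ('hgih'); recorded as high"},
      {"row": 7, "feature": "202022_at", "overall_km": 101, "rulex": 131,
       "overall_worse": "low", "relapse_free_km": 138, "relapse_free_worse": "low"},
      {"row": 8, "feature": "224314_s_at", "overall_km": 25, "rulex": 29,
       "overall_worse": "high", "relapse_free_km": 25, "relapse_free_worse": "high"},
      {"row": 9, "feature": "206686_at", "overall_km": 36, "rulex": 26,
       "overall_worse": "high", "relapse_free_km": 36, "relapse_free_worse": "high"},
      {"row": 10, "feature": "223193_x_at", "overall_km": 495, "rulex": 324,
       "overall_worse": "high", "relapse_free_km": 572, "relapse_free_worse": "high"},
      {"row": 11, "feature": "230630_at", "overall_km": 19, "rulex": 23,
       "overall_worse": "low", "relapse_free_km": 35, "relapse_free_worse": "low"}
    ]
  }
}
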
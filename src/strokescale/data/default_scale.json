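{
  "items": [
    {"name": "age_degree", "weight": 1.0, "feature": "age", "thresholds": [56.44], "points": [0.0, 1.0]},
    {"name": "history_dm", "weight": 1.0, "feature": "history", "key": "dm", "points": [0.0, 1.0]},
    {"name": "anxiety_day1", "weight": 1.0, "feature": "symptom_day1", "key": "anxiety", "points": [0.0, 1.0]},
    {"name": "nihss_degree_day1", "weight": 1.0, "feature": "nihss_day1", "thresholds": [2, 6], "points": [0.0, 1.0, 2.0]},
    {"name": "irritability_day1", "weight": 1.5, "feature": "symptom_day1", "key": "irritability", "points": [0.0, 1.5]},
    {"name": "delta_nihss_degree", "weight": 1.0, "feature": "delta_nihss", "thresholds": [-1], "points": [0.0, 1.0]},
    {"name": "circumrotating_change", "weight": 2.0, "feature": "change", "key": "circumrotating", "points": [0.0, 2.0, 4.0]},
    {"name": "tinnitus_change", "weight": 2.5, "feature": "change", "key": "tinnitus", "points": [0.0, 2.5, 5.0]}
  ],
  "cutoff": 9.5
}
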
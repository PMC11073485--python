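{
 "schema_version": 1,
 "predictors": ["omega1_bpm", "age", "phi1"],
 "comment": "Published rule on (omega1, age, phi1): omega1 < 107.6 bpm is normal; otherwise age >= 6 y is low LVEF, and under 6 y low LVEF requires phi1 < -0.65 rad. Leaf fractions are degenerate placeholders: the source cohort is not distributed.",
 "root": {
  "leaf": false,
  "feature": "omega1_bpm",
  "threshold": 107.6,
  "strict_right": false,
  "left": {"leaf": true, "label": false, "pos_fraction": 0.0, "n": 0},
  "right": {
   "leaf": false,
   "feature": "age",
   "threshold": 6.0,
   "strict_right": false,
   "left": {
    "leaf": false,
    "feature": "phi1",
    "threshold": -0.65,
    "strict_right": false,
    "left": {"leaf": true, "label": true, "pos_fraction": 1.0, "n": 0},
    "right": {"leaf": true, "label": false, "pos_fraction": 0.0, "n": 0}
   },
   "right": {"leaf": true, "label": true, "pos_fraction": 1.0, "n": 0}
  }
 }
}
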
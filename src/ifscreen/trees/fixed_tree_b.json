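{
 "schema_version": 1,
 "predictors": ["omega1_bpm", "omegai1"],
 "comment": "Published age-universal rule on (omega1, omegai1): omegai1 > 1.6 is low LVEF, omegai1 < 1.22 normal, and the intermediate band is decided by omega1 > 107.6 bpm. Encoded with omega1 as the top-level split as published; equivalent to the effective band rule. Leaf fractions are degenerate placeholders: the source cohort is not distributed.",
 "root": {
  "leaf": false,
  "feature": "omega1_bpm",
  "threshold": 107.6,
  "strict_right": true,
  "left": {
   "leaf": false,
   "feature": "omegai1",
   "threshold": 1.6,
   "strict_right": true,
   "left": {"leaf": true, "label": false, "pos_fraction": 0.0, "n": 0},
   "right": {"leaf": true, "label": true, "pos_fraction": 1.0, "n": 0}
  },
  "right": {
   "leaf": false,
   "feature": "omegai1",
   "threshold": 1.22,
   "strict_right": false,
   "left": {"leaf": true, "label": false, "pos_fraction": 0.0, "n": 0},
   "right": {"leaf": true, "label": true, "pos_fraction": 1.0, "n": 0}
  }
 }
}
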
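"""Full pipeline: synthetic cohort -> features -> CART + LOOCV screening.

Generates a 40-subject cohort with a planted low-LVEF effect (elevated
omega1, reduced phi1), extracts per-subject intrinsic-frequency features
from the raw recordings, trains a constrained CART on (omega1, omegai1)
and evaluates it by leave-one-out cross-validation.  Takes ~30 s.
"""

from ifscreen import if_core, screening as scr, synthetic as syn, waveform_io as wio
from ifscreen.features import features_table
from ifscreen.pipeline import extract_subject

cfg = syn.CohortConfig(n=40, prevalence=0.32, seed=5)
recordings, truths = syn.gen_cohort(cfg)

fit_cfg = if_core.FitConfig(omega1_range=(60, 200), omega2_range=(20, 160))
seg_cfg = wio.SegmentationConfig()
subjects = []
for rec, truth in zip(recordings, truths):
    sf = extract_subject(rec, truth.age, truth.lvef, seg_cfg, fit_cfg)
    if sf is not None:
        subjects.append(sf)

table = features_table(subjects)
print(table[["subject_id", "age", "lvef", "label", "omega1_bpm", "omegai1", "phi1"]]
      .head(8).to_string(index=False))
print(f"... {len(table)} subjects, {int(table.label.sum())} with low LVEF")

tree = scr.train_cart(subjects, ["omega1_bpm", "omegai1"])
print(f"trained CART: {tree.n_splits} splits (budget 3, min split node 11)")

report = scr.evaluate_loocv(subjects, ["omega1_bpm", "omegai1"])
print(f"LOOCV: sensitivity {report.sensitivity:.2f}, specificity {report.specificity:.2f}, "
      f"accuracy {report.accuracy:.2f}, AUC {report.auc:.3f}")
print("With the default planted effect (+15 bpm on omega1, three within-")
print("group SDs) the held-out AUC typically lands above 0.9.")
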
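"""Fit the intrinsic-frequency model to one synthetic cardiac cycle.

Builds a forward-model pressure cycle with known systolic/diastolic
intrinsic frequencies, adds 1% measurement noise, runs the constrained
grid-search fit and prints the recovered parameters next to the truth.
"""

from ifscreen import if_core, synthetic as syn

cfg = syn.CohortConfig(n=1, prevalence=0.0, seed=7)
truth = syn.make_subject_truth(cfg, 0, positive=False)
cycle = syn.gen_cycle(truth, noise_sd=0.01, seed=1, sampling_rate=cfg.sampling_rate)

fit_cfg = if_core.FitConfig(omega1_range=(60, 200), omega2_range=(20, 160))
result = if_core.fit_if(cycle, fit_cfg)

print(f"subject HR: {truth.HR:.1f} bpm, cycle T = {truth.T:.3f} s, T0 = {truth.T0:.3f} s")
print(f"{'':14s}{'true':>10s}{'fitted':>10s}")
rows = [
    ("omega1 (bpm)", if_core.to_bpm(truth.params.omega1), if_core.to_bpm(result.params.omega1)),
    ("omega2 (bpm)", if_core.to_bpm(truth.params.omega2), if_core.to_bpm(result.params.omega2)),
    ("phi1 (rad)", truth.params.phi1, result.params.phi1),
    ("phi2 (rad)", truth.params.phi2, result.params.phi2),
    ("Rs", truth.params.Rs, result.params.Rs),
    ("Rd", truth.params.Rd, result.params.Rd),
]
for name, t, f in rows:
    print(f"{name:14s}{t:10.3f}{f:10.3f}")
print(f"relative misfit: {result.residual:.2e}")
print("omega1 is the systolic intrinsic frequency (heart-aorta coupled);")
print("omega2 the diastolic one (vasculature alone); at 1% noise both are")
print("recovered to well under 2 bpm from a single beat.")
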
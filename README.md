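# ifscreen

Intrinsic-frequency analysis of carotid pressure waveforms and
decision-tree screening for low left-ventricular ejection fraction
(LVEF), aimed at pediatric cohorts where heart rate varies strongly
with age.

## The science

A single arterial pressure cycle p(t) on [0, T) with systolic duration
T₀ (the dicrotic-notch time, i.e. aortic-valve closure) is modeled as a
piecewise pair of sinusoids sharing a constant offset:

    minimize ‖ p(t) − χ[0,T₀)·(a₁cos ω₁t + b₁sin ω₁t)
                    − χ[T₀,T)·(a₂cos ω₂t + b₂sin ω₂t) − c ‖²

ω₁ (the systolic *intrinsic frequency*) reflects the dynamics of the
coupled left-ventricle–aorta system; ω₂ the vasculature alone after
valve closure.  Derived quantities are the intrinsic phases
φ₁ = tan⁻¹(a₁/b₁), φ₂ = tan⁻¹(a₂/b₂) and envelopes Rₛ = √(a₁²+b₁²),
R_d = √(a₂²+b₂²).  At fixed (ω₁, ω₂) the five remaining coefficients
are an equality-constrained linear least-squares problem (continuity at
T₀, closure over the beat); the frequencies are found by an exhaustive
coarse grid plus local refinement, because the objective is multi-modal.

For screening, ω₁ is expressed in beats per minute and combined with
age, φ₁, and the unitless HR-normalised index ωi₁ = ω₁/HR.  Two
published fixed decision rules are shipped (thresholds 107.6 bpm,
6 years, −0.65 rad, and 1.6/1.22 on ωi₁), and new trees can be trained
with a constrained CART (Gini impurity, at most 1 + #predictors splits,
split nodes must hold more than 10 subjects) evaluated by leave-one-out
cross-validation with pooled ROC/AUC.  The positive class is
LVEF < 50% (strict).

Because no public recording set exists, the package includes a
first-class synthetic-cohort generator that emits forward-model
waveforms with realistic beat morphology (foot, systolic peak, dicrotic
notch and bump), age-stratified heart rates, lognormal ventricular
volumes, and planted low-LVEF effects (elevated ω₁/ωi₁, reduced φ₁).

## Worked example

```python
from ifscreen import if_core, synthetic as syn

cfg = syn.CohortConfig(n=1, prevalence=0.0, seed=7)
truth = syn.make_subject_truth(cfg, 0, positive=False)
cycle = syn.gen_cycle(truth, noise_sd=0.01, seed=1, sampling_rate=cfg.sampling_rate)
fit = if_core.fit_if(cycle, if_core.FitConfig(omega1_range=(60, 200),
                                              omega2_range=(20, 160)))
print(if_core.to_bpm(truth.params.omega1), if_core.to_bpm(fit.params.omega1))
```

prints

```
105.68178641806855 105.75093418006622
```

— the systolic intrinsic frequency of a single noisy beat (1% of pulse
amplitude) is recovered to below 0.1 bpm here; across cohorts the
single-beat error at this noise level stays under ~2 bpm and per-subject
averages of 3–5 selected beats under ~1 bpm.  The `examples/` directory
has one narrative script per capability:

| script | shows |
|---|---|
| `01_fit_single_cycle.py` | model fit and parameter recovery on one beat |
| `02_segment_recording.py` | beat detection, notch timing, quality selection |
| `03_fixed_rules.py` | the two published screening rules with rule paths |
| `04_cohort_screening.py` | cohort generation → features → CART + LOOCV |

A thin CLI wraps the pipeline stages:

```bash
ifscreen --seed 7 synth   --out run/
ifscreen --seed 7 extract --data run/ --out run/
ifscreen --seed 7 screen  --features run/features.csv --out run/
# or: ifscreen --seed 7 run-all --out run/
```

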
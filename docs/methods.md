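# Methods

## Model

One cardiac cycle of carotid pressure p(t), t ∈ [0, T), is approximated
by two sinusoids joined at the systolic duration T₀ and sharing a
constant offset c:

    p(t) ≈ c + a₁cos(ω₁t) + b₁sin(ω₁t)   for t <  T₀   (systole)
    p(t) ≈ c + a₂cos(ω₂t) + b₂sin(ω₂t)   for t ≥  T₀   (diastole)

ω₁ and ω₂ are the systolic and diastolic intrinsic frequencies (rad/s
internally, bpm at reporting boundaries).  The systolic branch equals
c + Rₛ·sin(ω₁t + φ₁) with Rₛ = √(a₁²+b₁²) and φ₁ the two-argument
arctangent of (a₁, b₁) mapped to (−π, π]; for b₁ > 0 this coincides
with tan⁻¹(a₁/b₁).  The signed convention matters: the published
screening threshold φ₁ = −0.65 rad is only meaningful on a signed
branch, and the single-argument arctangent is ambiguous by π.

Assumptions: the beat is quasi-periodic (beat-to-beat pressure returns
to the foot value), the notch cleanly separates the two regimes, and
pressure units are arbitrary (uncalibrated tonometry) — every derived
screening quantity (ω₁, ω₂, φ₁, φ₂, ωi₁) is invariant to offset and
positive scaling of the input, which the tests assert.

## Fitting

At fixed (ω₁, ω₂) the five linear coefficients minimize the plain sum
of squared sample residuals on the uniform grid (no quadrature weights
— uniform sampling makes them a constant factor), subject to two linear
equality constraints in the default mode:

* continuity at T₀: both branches take the same value at the junction;
* closure at T: the diastolic branch returns to the systolic value at
  t = 0 (beat-to-beat periodicity).

The printed objective alone does not force these; reconstructions of
real pulses in the source literature are continuous and closed, so
continuity+closure is the default, with `continuity-only` and
`unconstrained` as config options.  The constrained problem is solved
by reduction to the constraint null space (SVD); a rank-deficient
design (e.g. ω·T₀ ≈ 0) yields a flagged degenerate solution with
residual 1.  The reported residual is ‖p − p̂‖₂ / ‖p − p̄‖₂ — the model
nests the best constant (a₁=b₁=a₂=b₂=0 is feasible), so this is always
in [0, 1] and offset-robust.

The outer problem in (ω₁, ω₂) is multi-modal, so `fit_if` runs an
exhaustive coarse grid (defaults: ω₁ ∈ [40, 300] bpm, ω₂ ∈ [20, 200]
bpm, 1-bpm step) followed by Nelder–Mead refinement from the best cell;
the refined objective is clamped never to exceed the best grid value.
The whole grid is solved in one vectorised pass: per-frequency Gram
blocks are precomputed (systolic and diastolic columns have disjoint
support), the constraint null spaces come from a batched SVD, and the
reduced 3×3 systems are solved with a batched pseudo-inverse so
near-singular cells degrade gracefully rather than poisoning the
search.  The winning cell is re-solved exactly before refinement
because the expanded quadratic form of the batched SSR loses precision
near zero misfit.

`refine_T0` (off by default) additionally refines the notch time.  The
misfit is only piecewise-smooth in T₀ (the systole/diastole sample
split jumps at grid points), so a simplex over (ω₁, ω₂, T₀) stalls on
the plateaus — and worse, at realistic noise the (T₀, ω₁) profile has a
shallow ridge along which joint optimization trades notch time against
frequency.  T₀ is therefore refined by scanning candidates at
sub-sample resolution, alternating with frequency refinement.  The
pipeline default keeps `refine_T0` off and instead relies on accurate
notch estimation (below).

## Segmentation

Beat onsets: the smoothed derivative is scanned for systolic upstrokes
(refractory period 60/HR_max, default HR range 40–220 bpm); each onset
candidate is the window minimum before the upstroke, snapped onto the
tail/upstroke corner by intersecting a line fitted to each side of the
raw signal.  A consistency pass then aligns every beat to the median
beat template (±20 ms search) and removes the residual common offset by
corner-locating the template's own foot — beat-to-beat onset jitter is
what dominates end-to-end ω₁ error, so this pass is load-bearing: on
synthetic recordings it brings onset error from roughly −0.7 ± 0.9
samples to 0.0 ± 0.5 at 500 Hz.

Dicrotic notch: the most prominent local minimum of the lightly
smoothed cycle within [0.15·T, 0.6·T] (physiologic systolic fractions;
configurable), refined to sub-sample precision by intersecting the two
limbs of the raw corner — smoothing alone biases the minimum toward the
shallow diastolic side.  With three or more cycles the notch is
re-estimated on the median beat template and shared across cycles as a
fraction of each period, since all beats of a subject share one
physiology and template noise is ~1/√n_beats.  When no minimum exists
(monotone tails) the estimate falls back to T₀ = 0.35·T and the cycle
is flagged, which multiplies its quality score by 0.8.

Quality and selection: each cycle is scored 1 − (RMS discrepancy from
the median beat template / template RMS amplitude), clipped to [0, 1];
the top min(5, available) cycles are kept in recording order, with ties
broken by earlier position, and fewer than 3 available sets an
insufficient-data flag.  This replaces manual good-quality-beat
selection with a deterministic, threshold-free ranking.

## Features and labels

Per cycle: ω₁, ω₂ (bpm), φ₁, φ₂ (rad), Rₛ, R_d, HR = 60/T (bpm) and
ωi₁ = ω₁[bpm]/HR[bpm] (unitless; compensates the strong age dependence
of pediatric heart rate).  Per subject: arithmetic means over the
selected cycles — parameters are averaged, not refit on an averaged
beat.  Phases are averaged arithmetically (per-subject spread is a few
hundredths of a radian; a circular mean is available as an option).
The label is LVEF < 50% strictly: exactly 50% is negative.  Age groups
are the integer-year brackets [0,6], [7,13], [14,20]; fractional ages
floor.

## Screening

Fixed rules (shipped both as functions and versioned JSON trees):

* Rule A (ω₁, age, φ₁): ω₁ < 107.6 bpm → normal; otherwise age ≥ 6 →
  low; under 6, low iff φ₁ < −0.65.
* Rule B (ω₁, ωi₁): ωi₁ > 1.6 → low; ωi₁ < 1.22 → normal; between,
  low iff ω₁ > 107.6.

Published inequalities are strict, so equality at a published strict
threshold falls to the non-strict side; internal trained-tree routing
uses `<` left / `≥` right.  These boundary conventions affect a
measure-zero set and are documented for reproducibility.  The JSON
fixtures carry degenerate leaf fractions (0/1) because the source
cohort is not distributed; ROC scores for fixed trees therefore come
from re-substituted leaf fractions on the user's cohort or a rule-depth
surrogate.

Trained trees: greedy binary CART on Gini impurity with thresholds at
midpoints of consecutive sorted distinct values, grown best-first
(largest weighted impurity decrease next) under two structural
constraints — total splits ≤ 1 + #predictors, and a node may be split
only if it holds more than 10 subjects (≥ 11).  Ties among equal-gain
splits break by lowest feature index, then smallest threshold, making
training deterministic and order-invariant.  Note that on
quadrant-structured data the greedy optimum may legitimately place a
cut just below the lowest positive rather than mid-gap (peeling extra
negatives); tests bound thresholds accordingly.

Evaluation: leave-one-out cross-validation (deterministic partitions; n
models for n subjects), pooled into a single confusion matrix
(prediction by leaf majority) and a single ROC built by sweeping all
distinct scores with ties grouped; the trapezoidal AUC then equals the
Mann–Whitney rank statistic exactly, which the tests assert to 1e-12.
Undefined metrics (zero denominators) are reported as None, never NaN.

## Synthetic cohorts

The generator is the package's test bed and defines its study
conditions; defaults: n = 50 subjects, prevalence 0.32 (a 16-in-50
split), uniform age-group weights, group mean heart rates 110/85/70 bpm
(SD 7, clipped to 55–185) for ages 0–6/7–13/14–20, baseline ω₁ ~
N(95, 5²) bpm, φ₁ ~ N(−0.25, 0.12²) rad, and planted low-LVEF effects
Δω₁ = +15 bpm (three within-group SDs) and Δφ₁ = −0.5 rad, matching the
reported directions (higher ω₁/ωi₁, lower φ₁ with reduced LVEF);
magnitudes are generator conventions, as no group means or SDs are
published.  LVEF comes from lognormal EDV/ESV volumes accepted by
rejection into the class band; the label column always equals
LVEF < 50 recomputed from the volumes.

Waveform construction: the systolic branch is chosen first (Rₛ = 1
arbitrary unit, offset c = 10); the junction is placed at a fixed
systolic phase (ω₁T₀ + φ₁ ≈ 2.2 rad, T₀/T clipped to [0.2, 0.55]) so
the notch sits on the falling limb at a stable fraction below the peak
across heart rates.  The diastolic coefficients are then forced by
continuity and closure once ω₂ is chosen, so ω₂ is rejection-sampled —
parameterised by the diastolic sweep angle ω₂(T−T₀) ∈ [1.8, 4.0] rad —
until a morphology gate passes: rising foot, falling systole into the
junction, a measurable dicrotic bump (≥ 1.5% of pulse, else the notch
detector sees only a shoulder), bump below the systolic peak, and a
tail that decays *into* the next foot (otherwise the beat's true
minimum precedes the cycle boundary and segmentation is biased).  Rare
extreme draws are rescued by shrinking φ₁ toward its mean and, as a
last resort, relaxing the bump-height margin.  Recordings tile 8
identical beats at 500 Hz plus white noise (SD 1% of pulse amplitude by
default) and optional slow sinusoidal baseline drift (off by default).
Per-subject random streams derive from (cohort seed, subject index), so
cohorts are byte-reproducible and insertion-order independent.

What the generator does not emulate: reflected-wave morphology,
Windkessel tails, respiratory/motion artifact beyond white noise and
optional drift, beat-to-beat HR variability, or sensor nonlinearity.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model and noise, not clinical performance on device data.

## Verification sizes and numerical choices

The acceptance checks use: 50 noiseless cycles for exact recovery
(ω within 0.25 bpm, residual < 1e-6); 20 cycles (12 in the standalone
script) against a dense 0.1-bpm brute-force grid over the configured
search domain, asserting the two-stage optimum never exceeds the grid
minimum by more than 1e-6 relative — the refined optimum may dip below
the grid, which samples the continuum at 0.1-bpm resolution; 50 random
frequency pairs for the constrained-solver contract (constraint
residuals ≤ 1e-10, constrained SSR ≥ unconstrained); >2×10⁴ grid points
straddling every published threshold for rule fidelity; 1000 random
confusion matrices and 200 random score sets for the evaluation
machinery; and a 100-subject cohort at 1% noise for the end-to-end
check (pooled LOOCV AUC > 0.9, median ω₁ recovery error < 1 bpm).
Bulk fitting tests use search ranges ω₁ ∈ [60, 200], ω₂ ∈ [20, 160]
bpm, which cover everything the generator can emit with wide margin.

Other numerical conventions: systole is the half-open interval
t < T₀ (a sample exactly at T₀ is diastolic); the cycle period T is
carried explicitly (not inferred from the grid) so the closure
constraint is exact even when T is not a whole number of samples;
Nelder–Mead uses a half-grid-step initial simplex, xatol 1e-7 bpm and a
relative fatol of 1e-8 times the coarse objective; batched
pseudo-inverses use rcond 1e-12.

## Limitations

* The notch estimator assumes a visible local minimum; waveforms with a
  genuinely absent notch (severe aortic regurgitation morphologies,
  heavy smoothing by tissue) fall back to 0.35·T.
* The fixed rules are encoded from their published thresholds; the
  structural arrangement of the (ω₁, ωi₁) tree is reproduced from its
  effective rule, which is equivalent point-wise but not structurally
  unique.
* An ejection-time correction of ω₁ is referenced in the source
  literature without a formula; none is applied, and
  `CycleFeatures`/`FitConfig` leave room to add one.
* LOOCV retrains one tree per subject; for cohorts beyond ~10³ subjects
  a k-fold scheme would be preferable.
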
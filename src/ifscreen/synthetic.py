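"""Synthetic waveform and cohort generation.

No public recording of the study data exists, so every pipeline stage is
exercised on synthetic cohorts built from the forward model itself: each
subject owns a ground-truth parameter set (age, heart rate, intrinsic
frequencies, phases, ventricular volumes) and each recording concatenates
several forward-model cycles plus white measurement noise and optional
baseline drift.  Low-LVEF subjects carry planted effects — an elevated
systolic intrinsic frequency (hence an elevated HR-normalised index) and
a reduced systolic phase — in the direction reported clinically; the
magnitudes are generator conventions, not literature values.

Determinism: every subject derives an independent random stream from the
cohort seed and the subject index, so cohorts are bit-reproducible and
insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .if_core import IFModelParams, from_bpm, reconstruct, signed_phase
from .waveform_io import Waveform

__all__ = [
    "SubjectTruth",
    "CohortConfig",
    "compute_lvef",
    "solve_diastolic_coeffs",
    "make_subject_truth",
    "gen_cycle",
    "gen_recording",
    "gen_cohort",
    "truth_table",
]


def compute_lvef(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction in percent: ``100*(EDV - ESV)/EDV``."""
    if not edv_ml > 0:
        raise ValueError("EDV must be positive")
    if not 0 <= esv_ml <= edv_ml:
        raise ValueError("require 0 <= ESV <= EDV")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    age: float            # years
    HR: float             # bpm
    T: float              # s, = 60/HR
    T0: float             # s, systolic duration
    params: IFModelParams
    EDV: float            # mL
    ESV: float            # mL
    lvef: float           # percent
    label: bool           # True = low LVEF (< 50%)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults emulate a pediatric screening cohort: three age brackets
    (0-6, 7-13, 14-20 years) with declining resting heart rate
    (110/85/70 bpm group means), a low-LVEF prevalence of 0.32 (the
    16-in-50 split of the motivating study design), and planted low-LVEF
    effects of +15 bpm on the systolic intrinsic frequency and -0.5 rad
    on its phase (three within-group SDs for the default omega1 SD of
    5 bpm).  ``seed`` is mandatory.
    """

    n: int = 50
    prevalence: float = 0.32
    seed: int = 0
    age_group_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hr_means: tuple[float, float, float] = (110.0, 85.0, 70.0)   # bpm per age group
    hr_sd: float = 7.0
    omega1_mean: float = 95.0      # bpm, normal-LVEF baseline
    omega1_sd: float = 5.0
    phi1_mean: float = -0.25       # rad
    phi1_sd: float = 0.12
    omega2_range: tuple[float, float] = (25.0, 135.0)  # bpm, admissible diastolic IF
    diastole_sweep: tuple[float, float] = (1.8, 4.0)   # rad, omega2*(T-T0) sampling band
    effect_domega1: float = 15.0   # bpm added to omega1 for low-LVEF subjects
    effect_domegai1: float = 0.0   # extra unitless omegai1 shift (as domega1 = shift*HR)
    effect_dphi1: float = -0.5     # rad added to phi1 for low-LVEF subjects
    notch_phase_mean: float = 2.2   # rad, systolic phase omega1*T0 + phi1 at the junction
    notch_phase_sd: float = 0.08
    t0_frac_bounds: tuple[float, float] = (0.2, 0.55)  # T0/T clipped to this band
    Rs: float = 1.0                # systolic envelope, arbitrary pressure units
    baseline: float = 10.0         # constant offset c, arbitrary units
    noise_sd: float = 0.01         # white-noise SD as fraction of pulse amplitude
    drift_amplitude: float = 0.0   # baseline drift, fraction of pulse amplitude
    drift_freq: float = 0.2        # Hz (respiratory-scale)
    cycles_per_subject: int = 8
    sampling_rate: float = 500.0   # Hz

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("cohort size n must be positive")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        for name in ("hr_sd", "omega1_sd", "phi1_sd", "notch_phase_sd", "noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def solve_diastolic_coeffs(
    omega1: float, a1: float, b1: float, omega2: float, T0: float, T: float
) -> tuple[float, float]:
    """Diastolic coefficients forced by continuity and closure.

    Given the systolic sinusoid, continuity of pressure at ``T0`` and
    closure at ``T`` (diastolic end value equals the systolic value at
    ``t = 0``) are two linear equations in ``(a2, b2)``; the 2x2 system
    is singular only when ``omega2*(T - T0)`` is a multiple of pi.
    """
    A = np.array([
        [math.cos(omega2 * T0), math.sin(omega2 * T0)],
        [math.cos(omega2 * T), math.sin(omega2 * T)],
    ])
    rhs = np.array([a1 * math.cos(omega1 * T0) + b1 * math.sin(omega1 * T0), a1])
    det = np.linalg.det(A)
    if abs(det) < 1e-9:
        raise ValueError("degenerate diastolic system: omega2*(T-T0) ~ k*pi")
    a2, b2 = np.linalg.solve(A, rhs)
    return float(a2), float(b2)


def _cycle_is_plausible(p: IFModelParams, T0: float, T: float, strict: bool = True) -> bool:
    """Morphology gate for generated truth parameters.

    Requires a rising foot at t=0, a falling systolic branch into the
    junction, a briefly rising diastolic branch after it (so the junction
    is a genuine dicrotic-notch local minimum), a dicrotic excursion that
    stays below the systolic peak, and a notch above the foot.  The
    non-strict variant drops the dicrotic-bump margin; it is used as a
    last resort for extreme heart-rate outliers, where the feasible
    diastolic frequencies leave no low-bump solution.
    """
    dsys_T0 = p.omega1 * (-p.a1 * math.sin(p.omega1 * T0) + p.b1 * math.cos(p.omega1 * T0))
    ddia_T0 = p.omega2 * (-p.a2 * math.sin(p.omega2 * T0) + p.b2 * math.cos(p.omega2 * T0))
    ddia_T = p.omega2 * (-p.a2 * math.sin(p.omega2 * T) + p.b2 * math.cos(p.omega2 * T))
    dsys_0 = p.omega1 * p.b1
    # the tail must decay INTO the next foot (ddia_T < 0): a diastolic
    # branch that rises into the closure point would put the beat's true
    # local minimum ahead of the cycle boundary and bias segmentation
    if not (dsys_0 > 0 and dsys_T0 < 0 and ddia_T0 > 0 and ddia_T < 0):
        return False
    t = np.linspace(0, T, 512, endpoint=False)
    wave = reconstruct(p, T0, T, t)
    sys_peak = wave[t < T0].max()
    dia = wave[t >= T0]
    notch_val = p.c + p.a1 * math.cos(p.omega1 * T0) + p.b1 * math.sin(p.omega1 * T0)
    foot_val = p.c + p.a1
    pulse = sys_peak - foot_val
    if strict and dia.max() >= sys_peak - 0.02 * pulse:
        return False
    # the dicrotic bump must rise measurably above the notch, or smoothing
    # in the notch detector will see a monotone shoulder instead of a minimum
    td = t[t >= T0]
    early_dia = wave[t >= T0][td <= T0 + 0.3 * (T - T0)]
    if early_dia.size and early_dia.max() - notch_val < 0.015 * pulse:
        return False
    if notch_val <= foot_val + 0.05 * pulse:
        return False
    if wave.min() < foot_val - 0.1 * pulse:
        return False
    return True


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


_AGE_BRACKETS = ((0, 6), (7, 13), (14, 20))


def _draw_volumes(rng: np.random.Generator, positive: bool) -> tuple[float, float, float]:
    """Lognormal EDV/ESV with the ejection fraction targeted by rejection."""
    for _ in range(10_000):
        edv = float(rng.lognormal(math.log(90.0), 0.30))
        esv = float(rng.lognormal(math.log(38.0), 0.35))
        if not 0 < esv <= edv:
            continue
        ef = compute_lvef(edv, esv)
        if positive and 15.0 <= ef < 50.0:
            return edv, esv, ef
        if not positive and 50.0 <= ef <= 80.0:
            return edv, esv, ef
    raise RuntimeError("volume rejection sampling failed")  # pragma: no cover


def make_subject_truth(cfg: CohortConfig, index: int, positive: bool) -> SubjectTruth:
    """Draw one subject's ground truth from the cohort configuration.

    The diastolic sinusoid is fully determined by the constraints once
    the systolic branch and ``omega2`` are chosen, so ``omega2`` is
    rejection-sampled within its range until the cycle morphology gate
    passes (dicrotic-notch local minimum present); on persistent failure
    the systolic phase is nudged as well.
    """
    rng = _subject_rng(cfg.seed, index)
    gi = int(rng.choice(3, p=np.asarray(cfg.age_group_weights) / np.sum(cfg.age_group_weights)))
    lo, hi = _AGE_BRACKETS[gi]
    age = float(rng.integers(lo, hi + 1))
    hr = float(np.clip(rng.normal(cfg.hr_means[gi], cfg.hr_sd), 55.0, 185.0))
    T = 60.0 / hr

    w1_bpm = rng.normal(cfg.omega1_mean, cfg.omega1_sd)
    phi1 = rng.normal(cfg.phi1_mean, cfg.phi1_sd)
    if positive:
        w1_bpm += cfg.effect_domega1 + cfg.effect_domegai1 * hr
        phi1 += cfg.effect_dphi1
    w1 = from_bpm(float(w1_bpm))
    # place the junction on the falling systolic limb at a fixed systolic
    # phase, so the notch pressure sits a stable fraction below the peak
    # regardless of heart rate
    notch_phase = rng.normal(cfg.notch_phase_mean, cfg.notch_phase_sd)
    t0_frac = float(np.clip((notch_phase - phi1) / (w1 * T), *cfg.t0_frac_bounds))
    T0 = t0_frac * T
    edv, esv, ef = _draw_volumes(rng, positive)

    params = None
    for attempt in range(6000):
        if attempt and attempt % 400 == 0:
            # rare rescue: pull an extreme phase back toward the population
            # mean, and recompute the junction placement to match
            phi1 = cfg.phi1_mean + 0.9 * (phi1 - cfg.phi1_mean)
            t0_frac = float(np.clip((notch_phase - phi1) / (w1 * T), *cfg.t0_frac_bounds))
            T0 = t0_frac * T
        strict = attempt < 4000
        a1 = cfg.Rs * math.sin(phi1)
        b1 = cfg.Rs * math.cos(phi1)
        # sample the diastolic sweep angle omega2*(T - T0): keeping it below a
        # full half-turn-and-a-bit makes the diastolic branch decay toward the
        # foot with at most a mild dicrotic bump, whatever the heart rate
        sweep = float(rng.uniform(*cfg.diastole_sweep))
        w2 = sweep / (T - T0)
        if not (from_bpm(cfg.omega2_range[0]) <= w2 <= from_bpm(cfg.omega2_range[1])):
            continue
        try:
            a2, b2 = solve_diastolic_coeffs(w1, a1, b1, w2, T0, T)
        except ValueError:
            continue
        candidate = IFModelParams(w1, w2, a1, b1, a2, b2, cfg.baseline)
        if _cycle_is_plausible(candidate, T0, T, strict=strict):
            params = candidate
            break
    if params is None:
        raise RuntimeError(
            f"could not construct a notched cycle for subject {index} "
            f"(HR={hr:.1f}, omega1={w1_bpm:.1f} bpm)"
        )
    return SubjectTruth(
        subject_id=f"S{index:04d}", age=age, HR=hr, T=T, T0=T0,
        params=params, EDV=edv, ESV=esv, lvef=ef,
        label=ef < 50.0,
    )


def gen_cycle(truth: SubjectTruth, noise_sd: float, seed: int, sampling_rate: float = 500.0):
    """One noisy forward-model cycle as a :class:`CardiacCycle`.

    White Gaussian noise with SD ``noise_sd`` times the pulse amplitude
    is added to the exact reconstruction; deterministic per seed.
    """
    from .waveform_io import CardiacCycle

    rng = np.random.default_rng(seed)
    n = int(round(truth.T * sampling_rate))
    t = np.arange(n) / sampling_rate
    clean = reconstruct(truth.params, truth.T0, truth.T, t)
    amp = float(np.ptp(clean))
    p = clean + rng.normal(0.0, noise_sd * amp, size=n) if noise_sd > 0 else clean.copy()
    return CardiacCycle(times=t, pressure=p, T=truth.T, T0=truth.T0,
                        subject_id=truth.subject_id)


def gen_recording(truth: SubjectTruth, cfg: CohortConfig, index: int) -> Waveform:
    """A subject's recording: concatenated cycles + noise + optional drift."""
    rng = _subject_rng(cfg.seed, index)
    rng = np.random.default_rng(rng.integers(0, 2**31))  # separate stream from truth draws
    n_per = int(round(truth.T * cfg.sampling_rate))
    one = reconstruct(truth.params, truth.T0, truth.T, np.arange(n_per) / cfg.sampling_rate)
    clean = np.tile(one, cfg.cycles_per_subject)
    t = np.arange(clean.size) / cfg.sampling_rate
    amp = float(np.ptp(one))
    p = clean.copy()
    if cfg.noise_sd > 0:
        p = p + rng.normal(0.0, cfg.noise_sd * amp, size=p.size)
    if cfg.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi)
        p = p + cfg.drift_amplitude * amp * np.sin(2 * math.pi * cfg.drift_freq * t + phase)
    return Waveform(subject_id=truth.subject_id, times=t, pressure=p,
                    sampling_rate=cfg.sampling_rate)


def gen_cohort(cfg: CohortConfig) -> tuple[list[Waveform], list[SubjectTruth]]:
    """Generate a full cohort of recordings with its ground-truth table.

    The number of positives is the deterministic rounding of
    ``prevalence * n`` (e.g. 16 of 50 at prevalence 0.32), assigned to a
    seed-permuted subset of subjects.  Fully reproducible from the seed.
    """
    import warnings

    n_pos = int(round(cfg.prevalence * cfg.n))
    if cfg.prevalence > 0 and n_pos == 0:
        warnings.warn("prevalence*n rounds to zero positives", stacklevel=2)
    assign_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(0xA551,)))
    positives = set(assign_rng.permutation(cfg.n)[:n_pos].tolist())
    truths, recordings = [], []
    for i in range(cfg.n):
        truth = make_subject_truth(cfg, i, i in positives)
        truths.append(truth)
        recordings.append(gen_recording(truth, cfg, i))
    return recordings, truths


def truth_table(truths: Sequence[SubjectTruth]) -> pd.DataFrame:
    """Ground-truth cohort table (one row per subject)."""
    from .if_core import to_bpm

    rows = []
    for s in truths:
        rows.append({
            "subject_id": s.subject_id,
            "age": s.age,
            "HR": s.HR,
            "T": s.T,
            "T0": s.T0,
            "EDV": s.EDV,
            "ESV": s.ESV,
            "lvef": s.lvef,
            "label": s.label,
            "true_omega1_bpm": to_bpm(s.params.omega1),
            "true_omega2_bpm": to_bpm(s.params.omega2),
            "true_phi1": s.params.phi1,
            "true_phi2": s.params.phi2,
            "true_Rs": s.params.Rs,
            "true_Rd": s.params.Rd,
            "true_c": s.params.c,
        })
    return pd.DataFrame(rows)
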
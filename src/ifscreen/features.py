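"""Per-cycle and per-subject feature derivation.

The screening classifiers consume a handful of scalars per subject: the
systolic intrinsic frequency ``omega1`` (bpm), its phase ``phi1`` (rad),
the heart rate ``HR = 60/T`` (bpm), the dimensionless HR-normalised index
``omegai1 = omega1/HR`` (which compensates for the strong age dependence
of pediatric heart rate), the subject's age, and the binary low-LVEF
label (positive iff LVEF < 50%, strict).  Cycle-level features from the
three to five selected beats are arithmetically averaged — each subject
ends up with exactly one feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .if_core import IFFitResult, signed_phase, to_bpm

__all__ = [
    "CycleFeatures",
    "SubjectFeatures",
    "AGE_GROUPS",
    "phase_envelope",
    "compute_heart_rate",
    "normalize_omega1",
    "cycle_features",
    "aggregate_subject",
    "age_group",
    "features_table",
    "LVEF_THRESHOLD",
]

#: Low-LVEF screening threshold, percent; positive class is LVEF < 50 (strict).
LVEF_THRESHOLD = 50.0

#: Pediatric age brackets in integer years: lower bound inclusive of 6 and 13.
AGE_GROUPS = ("0-6", "7-13", "14-20")


def phase_envelope(a: float, b: float) -> tuple[float, float]:
    """Phase and envelope of a sinusoid written as ``a*cos + b*sin``.

    Returns ``(phi, R)`` with ``R = sqrt(a^2 + b^2)`` and ``phi`` the
    signed arctangent of ``a`` over ``b`` in ``(-pi, pi]`` (the branch
    convention shared with the fitter).  ``(0, 0)`` has no defined phase.
    """
    return signed_phase(a, b), math.hypot(a, b)


def compute_heart_rate(cycle) -> float:
    """Heart rate in bpm from the cycle period: ``60 / T``."""
    if not cycle.T > 0:
        raise ValueError("cycle period must be positive")
    return 60.0 / cycle.T


def normalize_omega1(omega1_bpm: float, hr_bpm: float) -> float:
    """The unitless HR-normalised systolic IF index: ``omega1 / HR``."""
    if not hr_bpm > 0:
        raise ValueError("heart rate must be positive")
    return omega1_bpm / hr_bpm


@dataclass(frozen=True)
class CycleFeatures:
    """Intrinsic-frequency features of one fitted cardiac cycle."""

    omega1_bpm: float
    omega2_bpm: float
    phi1: float
    phi2: float
    Rs: float
    Rd: float
    HR: float
    omegai1: float
    residual: float = float("nan")


def cycle_features(fit: IFFitResult, cycle) -> CycleFeatures:
    """Assemble the feature vector of one cycle from its fit."""
    p = fit.params
    hr = compute_heart_rate(cycle)
    w1 = to_bpm(p.omega1)
    return CycleFeatures(
        omega1_bpm=w1,
        omega2_bpm=to_bpm(p.omega2),
        phi1=p.phi1,
        phi2=p.phi2,
        Rs=p.Rs,
        Rd=p.Rd,
        HR=hr,
        omegai1=normalize_omega1(w1, hr),
        residual=fit.residual,
    )


def age_group(age_years: float) -> str:
    """Assign the printed pediatric bracket; fractional ages floor to years."""
    a = math.floor(age_years)
    if a < 0:
        raise ValueError("age must be non-negative")
    if a <= 6:
        return AGE_GROUPS[0]
    if a <= 13:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


@dataclass(frozen=True)
class SubjectFeatures:
    """Cycle-averaged features plus demographics and the screening label."""

    subject_id: str
    age: float
    lvef: float
    label: bool
    omega1_bpm: float
    phi1: float
    HR: float
    omegai1: float
    omega2_bpm: float
    phi2: float
    Rs: float
    Rd: float
    n_cycles: int
    age_group: str
    insufficient_cycles: bool = False

    def feature(self, name: str) -> float:
        """Look up a predictor by its column name (for tree routing)."""
        if not hasattr(self, name):
            raise KeyError(f"unknown feature {name!r}")
        return float(getattr(self, name))


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def aggregate_subject(
    cycles: Sequence[CycleFeatures],
    subject_id: str,
    age: float,
    lvef: float,
    phi_circular: bool = False,
    insufficient: bool = False,
) -> SubjectFeatures:
    """Average cycle features into one per-subject record.

    Field-wise arithmetic means over the selected cycles (permutation
    invariant); the label is ``lvef < 50`` with exactly 50% counted
    normal.  Phases are averaged arithmetically by default — per-subject
    phase spread is small — with a circular mean available.
    """
    if not cycles:
        raise ValueError("aggregate_subject requires at least one cycle")
    mean = lambda xs: float(np.mean(xs))
    phis1 = np.array([c.phi1 for c in cycles])
    phis2 = np.array([c.phi2 for c in cycles])
    phi_mean = _circular_mean if phi_circular else (lambda a: float(np.mean(a)))
    return SubjectFeatures(
        subject_id=subject_id,
        age=float(age),
        lvef=float(lvef),
        label=bool(lvef < LVEF_THRESHOLD),
        omega1_bpm=mean([c.omega1_bpm for c in cycles]),
        phi1=phi_mean(phis1),
        HR=mean([c.HR for c in cycles]),
        omegai1=mean([c.omegai1 for c in cycles]),
        omega2_bpm=mean([c.omega2_bpm for c in cycles]),
        phi2=phi_mean(phis2),
        Rs=mean([c.Rs for c in cycles]),
        Rd=mean([c.Rd for c in cycles]),
        n_cycles=len(cycles),
        age_group=age_group(age),
        insufficient_cycles=insufficient,
    )


_TABLE_COLUMNS = [
    "subject_id", "age", "lvef", "label", "omega1_bpm", "phi1", "HR",
    "omegai1", "omega2_bpm", "phi2", "Rs", "Rd", "n_cycles",
]


def features_table(subjects: Sequence[SubjectFeatures]) -> pd.DataFrame:
    """Feature table with one row per subject (the screening interface)."""
    rows = [{col: getattr(s, col) for col in _TABLE_COLUMNS} for s in subjects]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df["label"] = df["label"].astype(bool)
    return df
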
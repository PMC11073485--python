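"""Intrinsic-frequency (IF) model fitting for single cardiac cycles.

The IF model treats the left ventricle and the arterial tree as a coupled
oscillator during systole and the vasculature alone during diastole.  One
pressure cycle ``p(t)`` on ``[0, T)`` with systolic duration ``T0`` is
approximated by a piecewise pair of sinusoids sharing a constant offset::

    p(t) ~ c + a1*cos(w1*t) + b1*sin(w1*t)     for t <  T0   (systole)
    p(t) ~ c + a2*cos(w2*t) + b2*sin(w2*t)     for t >= T0   (diastole)

and the two angular frequencies ``w1`` (systolic IF) and ``w2`` (diastolic
IF) are found by minimizing the discrete L2 misfit.  At fixed frequencies
the five remaining coefficients form a linear least-squares subproblem,
optionally subject to two physical side conditions:

* continuity of pressure at the dicrotic notch ``T0``, and
* closure over the beat: the diastolic branch at ``T`` returns to the
  systolic value at ``t = 0`` (the pulse is periodic beat to beat).

The outer problem in ``(w1, w2)`` is multi-modal, so the fitter runs an
exhaustive coarse grid (vectorised over all frequency pairs) followed by
deterministic Nelder--Mead refinement from the best grid cell.

Frequencies are handled in rad/s internally and exposed in beats per
minute (bpm) only at reporting boundaries via :func:`to_bpm`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import null_space

__all__ = [
    "IFModelParams",
    "IFFitResult",
    "FitConfig",
    "LinearCoeffFit",
    "reconstruct",
    "solve_linear_coeffs",
    "fit_if",
    "to_bpm",
    "from_bpm",
    "signed_phase",
]

_TWO_PI = 2.0 * math.pi


def to_bpm(omega: float) -> float:
    """Convert an angular frequency in rad/s to beats per minute."""
    return omega * 60.0 / _TWO_PI


def from_bpm(bpm: float) -> float:
    """Convert beats per minute to an angular frequency in rad/s."""
    return bpm * _TWO_PI / 60.0


def signed_phase(a: float, b: float) -> float:
    """Signed phase of ``a*cos(wt) + b*sin(wt) = R*sin(wt + phi)``.

    Computed as the two-argument arctangent of ``(a, b)`` mapped to
    ``(-pi, pi]``; for ``b > 0`` this coincides with ``atan(a/b)``.  The
    single-argument arctangent is ambiguous by pi, and the published
    screening threshold ``phi1 = -0.65`` requires the signed convention.
    """
    if a == 0.0 and b == 0.0:
        raise ValueError("phase undefined for zero envelope (a, b) == (0, 0)")
    phi = math.atan2(a, b)
    if phi <= -math.pi:
        phi = math.pi
    return phi


@dataclass(frozen=True)
class IFModelParams:
    """Parameters of the two-sinusoid intrinsic-frequency model.

    ``omega1``/``omega2`` are the systolic/diastolic intrinsic frequencies
    in rad/s; ``a1, b1, a2, b2`` the sinusoid coefficients and ``c`` the
    shared constant, all in the (arbitrary) pressure units of the input.
    """

    omega1: float
    omega2: float
    a1: float
    b1: float
    a2: float
    b2: float
    c: float

    def __post_init__(self) -> None:
        if not (self.omega1 > 0 and self.omega2 > 0):
            raise ValueError("intrinsic frequencies must be positive")

    @property
    def phi1(self) -> float:
        """Systolic intrinsic phase, rad, in (-pi, pi]."""
        return signed_phase(self.a1, self.b1)

    @property
    def phi2(self) -> float:
        """Diastolic intrinsic phase, rad, in (-pi, pi]."""
        return signed_phase(self.a2, self.b2)

    @property
    def Rs(self) -> float:
        """Systolic envelope sqrt(a1^2 + b1^2), pressure units."""
        return math.hypot(self.a1, self.b1)

    @property
    def Rd(self) -> float:
        """Diastolic envelope sqrt(a2^2 + b2^2), pressure units."""
        return math.hypot(self.a2, self.b2)


@dataclass(frozen=True)
class LinearCoeffFit:
    """Solution of the linear coefficient subproblem at fixed frequencies."""

    a1: float
    b1: float
    a2: float
    b2: float
    c: float
    ssr: float        # sum of squared sample residuals
    residual: float   # relative L2 misfit in [0, 1]
    degenerate: bool = False

    @property
    def coeffs(self) -> tuple[float, float, float, float, float]:
        return (self.a1, self.b1, self.a2, self.b2, self.c)


@dataclass(frozen=True)
class IFFitResult:
    """Outcome of a full intrinsic-frequency fit on one cardiac cycle."""

    params: IFModelParams
    residual: float
    ssr: float
    grid_cell: tuple[int, int]
    converged: bool
    coarse_ssr: float = float("inf")
    T0: float = float("nan")


#: Constraint modes for the linear subproblem.
MODES = ("continuity+closure", "continuity-only", "unconstrained")


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for :func:`fit_if`.

    Frequency ranges and the grid step are in bpm (the clinical reporting
    unit); the defaults bracket pediatric systolic and diastolic intrinsic
    frequencies with a wide margin.
    """

    omega1_range: tuple[float, float] = (40.0, 300.0)
    omega2_range: tuple[float, float] = (20.0, 200.0)
    grid_step: float = 1.0
    constraint_mode: str = "continuity+closure"
    refine_tol: float = 1e-8
    refine_T0: bool = False
    refine_maxiter: int = 400

    def __post_init__(self) -> None:
        for lo, hi in (self.omega1_range, self.omega2_range):
            if not (0 < lo < hi):
                raise ValueError("frequency ranges must be positive and non-empty")
        if not self.grid_step > 0:
            raise ValueError("grid step must be positive")
        if self.constraint_mode not in MODES:
            raise ValueError(f"constraint_mode must be one of {MODES}")


def reconstruct(params: IFModelParams, T0: float, T: float, times: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise IF model on a time grid over ``[0, T)``.

    Systole is the half-open interval ``t < T0``, diastole ``t >= T0``;
    equivalently the systolic branch is ``c + Rs*sin(w1*t + phi1)``.
    """
    if not (0 < T0 < T):
        raise ValueError(f"require 0 < T0 < T, got T0={T0}, T={T}")
    t = np.asarray(times, dtype=float)
    sys_mask = t < T0
    out = np.empty_like(t)
    ts, td = t[sys_mask], t[~sys_mask]
    out[sys_mask] = params.c + params.a1 * np.cos(params.omega1 * ts) + params.b1 * np.sin(params.omega1 * ts)
    out[~sys_mask] = params.c + params.a2 * np.cos(params.omega2 * td) + params.b2 * np.sin(params.omega2 * td)
    return out


def _constraint_matrix(omega1: float, omega2: float, T0: float, T: float, mode: str) -> np.ndarray | None:
    """Linear equality constraints ``C @ (a1,b1,a2,b2,c) = 0`` for a mode."""
    continuity = [
        math.cos(omega1 * T0), math.sin(omega1 * T0),
        -math.cos(omega2 * T0), -math.sin(omega2 * T0), 0.0,
    ]
    # closure: diastolic value at T equals systolic value at t=0 (= c + a1)
    closure = [-1.0, 0.0, math.cos(omega2 * T), math.sin(omega2 * T), 0.0]
    if mode == "continuity+closure":
        return np.array([continuity, closure])
    if mode == "continuity-only":
        return np.array([continuity])
    if mode == "unconstrained":
        return None
    raise ValueError(f"unknown constraint mode {mode!r}")


def _design_matrix(t: np.ndarray, T0: float, omega1: float, omega2: float) -> np.ndarray:
    sys_mask = t < T0
    A = np.zeros((t.size, 5))
    ts, td = t[sys_mask], t[~sys_mask]
    A[sys_mask, 0] = np.cos(omega1 * ts)
    A[sys_mask, 1] = np.sin(omega1 * ts)
    A[~sys_mask, 2] = np.cos(omega2 * td)
    A[~sys_mask, 3] = np.sin(omega2 * td)
    A[:, 4] = 1.0
    return A


def _relative_residual(p: np.ndarray, fitted: np.ndarray) -> float:
    denom = float(np.linalg.norm(p - p.mean()))
    if denom == 0.0:
        return 1.0
    return float(np.linalg.norm(p - fitted)) / denom


def solve_linear_coeffs(
    t: np.ndarray,
    p: np.ndarray,
    T0: float,
    omega1: float,
    omega2: float,
    mode: str = "continuity+closure",
    T: float | None = None,
) -> LinearCoeffFit:
    """Solve the linear coefficient subproblem at fixed ``(omega1, omega2)``.

    Minimizes the sum of squared sample residuals over ``(a1, b1, a2, b2, c)``
    subject to the equality constraints of ``mode`` (continuity at ``T0``
    and/or closure at ``T``), via reduction to the constraint null space.
    Frequencies are rad/s.  A rank-deficient design (e.g. ``omega*T0``
    nearly zero) yields a flagged degenerate solution with residual 1.
    """
    if not (omega1 > 0 and omega2 > 0):
        raise ValueError("frequencies must be positive")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if T is None:
        # default: the cycle covers [0, T) on a uniform grid
        T = float(t[-1] + (t[1] - t[0])) if t.size > 1 else float(T0 * 2)
    n_sys = int(np.count_nonzero(t < T0))
    degenerate_out = LinearCoeffFit(0.0, 0.0, 0.0, 0.0, float(p.mean()), float(np.sum((p - p.mean()) ** 2)), 1.0, True)
    if n_sys < 2 or t.size - n_sys < 2:
        return degenerate_out

    A = _design_matrix(t, T0, omega1, omega2)
    C = _constraint_matrix(omega1, omega2, T0, T, mode)
    if C is None:
        x, _, rank, sv = np.linalg.lstsq(A, p, rcond=None)
        if rank < 5 or sv[0] <= 0 or sv[-1] / sv[0] < 1e-10:
            return degenerate_out
    else:
        Z = null_space(C)
        AZ = A @ Z
        y, _, rank, sv = np.linalg.lstsq(AZ, p, rcond=None)
        if rank < Z.shape[1] or sv[0] <= 0 or sv[-1] / sv[0] < 1e-10:
            return degenerate_out
        x = Z @ y
    fitted = A @ x
    ssr = float(np.sum((p - fitted) ** 2))
    return LinearCoeffFit(*x, ssr=ssr, residual=_relative_residual(p, fitted))


# ---------------------------------------------------------------------------
# Vectorised coarse grid
# ---------------------------------------------------------------------------

def _grid_ssr(
    t: np.ndarray,
    p: np.ndarray,
    T0: float,
    T: float,
    w1: np.ndarray,
    w2: np.ndarray,
    mode: str,
) -> np.ndarray:
    """SSR surface over the (w1, w2) grid, solved for all cells at once.

    Per-frequency Gram blocks are precomputed on the systolic and diastolic
    sample sets (their supports are disjoint, so the 5x5 normal matrix is
    block-structured), the constraint null space is obtained by a batched
    SVD, and the reduced normal equations are solved with a batched
    pseudo-inverse so near-singular cells degrade gracefully instead of
    poisoning the search.
    """
    sys_mask = t < T0
    ts, td = t[sys_mask], t[~sys_mask]
    ps, pd_ = p[sys_mask], p[~sys_mask]
    n1, n2 = w1.size, w2.size
    N = t.size
    pp = float(p @ p)
    sp = float(p.sum())

    C1 = np.cos(np.outer(w1, ts)); S1 = np.sin(np.outer(w1, ts))
    C2 = np.cos(np.outer(w2, td)); S2 = np.sin(np.outer(w2, td))

    # systolic Gram entries per w1, diastolic per w2
    g1 = np.stack([(C1 * C1).sum(1), (C1 * S1).sum(1), (S1 * S1).sum(1)], axis=-1)
    g2 = np.stack([(C2 * C2).sum(1), (C2 * S2).sum(1), (S2 * S2).sum(1)], axis=-1)
    u1 = np.stack([C1.sum(1), S1.sum(1)], axis=-1)      # against constant column
    u2 = np.stack([C2.sum(1), S2.sum(1)], axis=-1)
    v1 = np.stack([C1 @ ps, S1 @ ps], axis=-1)
    v2 = np.stack([C2 @ pd_, S2 @ pd_], axis=-1)

    G = np.zeros((n1, n2, 5, 5))
    G[:, :, 0, 0] = g1[:, None, 0]; G[:, :, 0, 1] = G[:, :, 1, 0] = g1[:, None, 1]
    G[:, :, 1, 1] = g1[:, None, 2]
    G[:, :, 2, 2] = g2[None, :, 0]; G[:, :, 2, 3] = G[:, :, 3, 2] = g2[None, :, 1]
    G[:, :, 3, 3] = g2[None, :, 2]
    G[:, :, 0, 4] = G[:, :, 4, 0] = u1[:, None, 0]
    G[:, :, 1, 4] = G[:, :, 4, 1] = u1[:, None, 1]
    G[:, :, 2, 4] = G[:, :, 4, 2] = u2[None, :, 0]
    G[:, :, 3, 4] = G[:, :, 4, 3] = u2[None, :, 1]
    G[:, :, 4, 4] = N

    b = np.zeros((n1, n2, 5))
    b[:, :, 0] = v1[:, None, 0]; b[:, :, 1] = v1[:, None, 1]
    b[:, :, 2] = v2[None, :, 0]; b[:, :, 3] = v2[None, :, 1]
    b[:, :, 4] = sp

    if mode == "unconstrained":
        x = np.einsum("...ij,...j->...i", np.linalg.pinv(G, rcond=1e-12), b)
    else:
        n_con = 2 if mode == "continuity+closure" else 1
        Cmat = np.zeros((n1, n2, n_con, 5))
        Cmat[:, :, 0, 0] = np.cos(w1 * T0)[:, None]
        Cmat[:, :, 0, 1] = np.sin(w1 * T0)[:, None]
        Cmat[:, :, 0, 2] = -np.cos(w2 * T0)[None, :]
        Cmat[:, :, 0, 3] = -np.sin(w2 * T0)[None, :]
        if n_con == 2:
            Cmat[:, :, 1, 0] = -1.0
            Cmat[:, :, 1, 2] = np.cos(w2 * T)[None, :]
            Cmat[:, :, 1, 3] = np.sin(w2 * T)[None, :]
        _, _, vh = np.linalg.svd(Cmat, full_matrices=True)
        Z = np.swapaxes(vh[:, :, n_con:, :], -1, -2)        # (n1, n2, 5, 5-n_con)
        M = np.einsum("...ji,...jk,...kl->...il", Z, G, Z)
        r = np.einsum("...ji,...j->...i", Z, b)
        y = np.einsum("...ij,...j->...i", np.linalg.pinv(M, rcond=1e-12), r)
        x = np.einsum("...ij,...j->...i", Z, y)

    ssr = pp - 2.0 * np.einsum("...i,...i->...", x, b) + np.einsum(
        "...i,...ij,...j->...", x, G, x
    )
    ssr = np.where(np.isfinite(ssr), np.maximum(ssr, 0.0), np.inf)
    return ssr


def fit_if(cycle, cfg: FitConfig | None = None) -> IFFitResult:
    """Fit the intrinsic-frequency model to one cardiac cycle.

    Runs an exhaustive coarse grid over ``(omega1, omega2)`` with the
    constrained linear subproblem solved in every cell, then refines the
    best cell with derivative-free Nelder--Mead.  Deterministic for a
    fixed configuration.

    Parameters
    ----------
    cycle
        A :class:`~ifscreen.waveform_io.CardiacCycle` (anything exposing
        ``times``, ``pressure``, ``T`` and ``T0``).
    cfg
        Search configuration; defaults to :class:`FitConfig`.
    """
    cfg = cfg or FitConfig()
    t = np.asarray(cycle.times, dtype=float)
    p = np.asarray(cycle.pressure, dtype=float)
    T, T0 = float(cycle.T), float(cycle.T0)
    if not (0 < T0 < T):
        raise ValueError("cycle must satisfy 0 < T0 < T")

    w1_bpm = np.arange(cfg.omega1_range[0], cfg.omega1_range[1] + cfg.grid_step / 2, cfg.grid_step)
    w2_bpm = np.arange(cfg.omega2_range[0], cfg.omega2_range[1] + cfg.grid_step / 2, cfg.grid_step)
    ssr = _grid_ssr(t, p, T0, T, from_bpm(w1_bpm), from_bpm(w2_bpm), cfg.constraint_mode)
    if not np.isfinite(ssr).any():
        raise RuntimeError("intrinsic-frequency fit failed: all grid cells degenerate")
    i, j = np.unravel_index(int(np.argmin(ssr)), ssr.shape)
    # re-solve the winning cell exactly; the batched SSR uses the expanded
    # quadratic form, which loses precision near zero misfit
    coarse = solve_linear_coeffs(t, p, T0, from_bpm(w1_bpm[i]), from_bpm(w2_bpm[j]), cfg.constraint_mode, T=T)
    coarse_ssr = coarse.ssr

    lo = np.array([cfg.omega1_range[0], cfg.omega2_range[0]])
    hi = np.array([cfg.omega1_range[1], cfg.omega2_range[1]])
    pp = float(p @ p)

    def refine_freqs(x0: np.ndarray, t0: float, f0: float):
        """Nelder--Mead on (w1, w2) in bpm at fixed T0."""

        def objective(z):
            if np.any(z < lo) or np.any(z > hi):
                return np.inf
            return solve_linear_coeffs(t, p, t0, from_bpm(z[0]), from_bpm(z[1]), cfg.constraint_mode, T=T).ssr

        simplex = np.vstack([x0] + [x0 + 0.5 * cfg.grid_step * e for e in np.eye(2)])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": 1e-7,
                "fatol": max(cfg.refine_tol * f0, 1e-15 * pp, 1e-300),
                "maxiter": cfg.refine_maxiter,
                "maxfev": 4 * cfg.refine_maxiter,
            },
        )
        return (res.x, res.fun, bool(res.success)) if res.fun <= f0 else (x0, f0, True)

    z = np.array([w1_bpm[i], w2_bpm[j]])
    T0_out = T0
    z, f_best, ok = refine_freqs(z, T0_out, coarse_ssr)

    if cfg.refine_T0:
        # the misfit is only piecewise-smooth in T0 (the systole/diastole
        # sample split jumps at grid points), so T0 is refined by scanning
        # candidates at sub-sample resolution, alternating with frequency
        # refinement
        dt = float(t[1] - t[0]) if t.size > 1 else T / max(t.size, 1)
        for half_width, step in ((0.05 * T, dt / 2), (2 * dt, dt / 8)):
            cands = np.arange(T0_out - half_width, T0_out + half_width + step / 2, step)
            cands = cands[(cands > 2 * dt) & (cands < T - 2 * dt)]
            ssr_t0 = [solve_linear_coeffs(t, p, c, from_bpm(z[0]), from_bpm(z[1]),
                                          cfg.constraint_mode, T=T).ssr for c in cands]
            k = int(np.argmin(ssr_t0))
            if ssr_t0[k] < f_best:
                T0_out, f_best = float(cands[k]), float(ssr_t0[k])
            z, f_best, ok = refine_freqs(z, T0_out, f_best)

    best = solve_linear_coeffs(t, p, T0_out, from_bpm(z[0]), from_bpm(z[1]), cfg.constraint_mode, T=T)
    if best.ssr > coarse_ssr:  # refinement must never lose to the grid
        z, best, T0_out = np.array([w1_bpm[i], w2_bpm[j]]), coarse, T0
    params = IFModelParams(from_bpm(float(z[0])), from_bpm(float(z[1])), *best.coeffs)
    return IFFitResult(
        params=params,
        residual=best.residual,
        ssr=best.ssr,
        grid_cell=(int(i), int(j)),
        converged=bool(ok or best.ssr <= coarse_ssr),
        coarse_ssr=coarse_ssr,
        T0=T0_out,
    )
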
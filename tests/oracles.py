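"""Independent brute-force oracles used by the test suite.

These deliberately take different computational routes from the package:
the constrained least-squares oracle assembles the KKT saddle-point
system per frequency pair (the implementation reduces to the constraint
null space via SVD), the dense-grid oracle exhausts the frequency plane
at fine resolution, the AUC oracle counts positive/negative pairs, and
the CART cross-check is scikit-learn.
"""

from __future__ import annotations

import numpy as np


def normal_equations_unconstrained(t, p, T0, omega1, omega2):
    """Plain normal-equations solve of the 5-coefficient subproblem."""
    sys_mask = t < T0
    A = np.zeros((t.size, 5))
    A[sys_mask, 0] = np.cos(omega1 * t[sys_mask])
    A[sys_mask, 1] = np.sin(omega1 * t[sys_mask])
    A[~sys_mask, 2] = np.cos(omega2 * t[~sys_mask])
    A[~sys_mask, 3] = np.sin(omega2 * t[~sys_mask])
    A[:, 4] = 1.0
    x = np.linalg.solve(A.T @ A, A.T @ p)
    return x, float(np.sum((p - A @ x) ** 2))


def kkt_constrained(t, p, T0, T, omega1, omega2):
    """Equality-constrained least squares via the KKT saddle system."""
    import math

    sys_mask = t < T0
    A = np.zeros((t.size, 5))
    A[sys_mask, 0] = np.cos(omega1 * t[sys_mask])
    A[sys_mask, 1] = np.sin(omega1 * t[sys_mask])
    A[~sys_mask, 2] = np.cos(omega2 * t[~sys_mask])
    A[~sys_mask, 3] = np.sin(omega2 * t[~sys_mask])
    A[:, 4] = 1.0
    C = np.array([
        [math.cos(omega1 * T0), math.sin(omega1 * T0),
         -math.cos(omega2 * T0), -math.sin(omega2 * T0), 0.0],
        [-1.0, 0.0, math.cos(omega2 * T), math.sin(omega2 * T), 0.0],
    ])
    K = np.zeros((7, 7))
    K[:5, :5] = A.T @ A
    K[:5, 5:] = C.T
    K[5:, :5] = C
    rhs = np.concatenate([A.T @ p, np.zeros(2)])
    x = np.linalg.pinv(K) @ rhs
    coef = x[:5]
    return coef, float(np.sum((p - A @ coef) ** 2))


def dense_grid_min_ssr(t, p, T0, T, w1_bpm, w2_bpm):
    """Minimum constrained SSR over a dense (w1, w2) grid in bpm.

    Loops over w1 and solves every w2 cell of that row at once through
    batched KKT pseudo-inverses.
    """
    two_pi = 2.0 * np.pi
    w1s = np.asarray(w1_bpm, dtype=float) * two_pi / 60.0
    w2s = np.asarray(w2_bpm, dtype=float) * two_pi / 60.0
    sys_mask = t < T0
    ts, td = t[sys_mask], t[~sys_mask]
    ps, pd_ = p[sys_mask], p[~sys_mask]
    N = t.size
    pp = float(p @ p)
    sp = float(p.sum())
    n2 = w2s.size

    C2 = np.cos(np.outer(w2s, td)); S2 = np.sin(np.outer(w2s, td))
    g2 = np.stack([(C2 * C2).sum(1), (C2 * S2).sum(1), (S2 * S2).sum(1)], -1)
    u2 = np.stack([C2.sum(1), S2.sum(1)], -1)
    v2 = np.stack([C2 @ pd_, S2 @ pd_], -1)
    c2T0, s2T0 = np.cos(w2s * T0), np.sin(w2s * T0)
    c2T, s2T = np.cos(w2s * T), np.sin(w2s * T)

    best = np.inf
    best_w = (np.nan, np.nan)
    K = np.zeros((n2, 7, 7))
    rhs = np.zeros((n2, 7))
    for i, w1 in enumerate(w1s):
        c1 = np.cos(w1 * ts); s1 = np.sin(w1 * ts)
        K[:] = 0.0
        K[:, 0, 0] = c1 @ c1; K[:, 0, 1] = K[:, 1, 0] = c1 @ s1; K[:, 1, 1] = s1 @ s1
        K[:, 2, 2] = g2[:, 0]; K[:, 2, 3] = K[:, 3, 2] = g2[:, 1]; K[:, 3, 3] = g2[:, 2]
        K[:, 0, 4] = K[:, 4, 0] = c1.sum(); K[:, 1, 4] = K[:, 4, 1] = s1.sum()
        K[:, 2, 4] = K[:, 4, 2] = u2[:, 0]; K[:, 3, 4] = K[:, 4, 3] = u2[:, 1]
        K[:, 4, 4] = N
        # constraint rows/cols
        K[:, 5, 0] = K[:, 0, 5] = np.cos(w1 * T0)
        K[:, 5, 1] = K[:, 1, 5] = np.sin(w1 * T0)
        K[:, 5, 2] = K[:, 2, 5] = -c2T0
        K[:, 5, 3] = K[:, 3, 5] = -s2T0
        K[:, 6, 0] = K[:, 0, 6] = -1.0
        K[:, 6, 2] = K[:, 2, 6] = c2T
        K[:, 6, 3] = K[:, 3, 6] = s2T
        rhs[:, 0] = c1 @ ps; rhs[:, 1] = s1 @ ps
        rhs[:, 2] = v2[:, 0]; rhs[:, 3] = v2[:, 1]; rhs[:, 4] = sp
        rhs[:, 5:] = 0.0
        try:
            sol = np.linalg.solve(K, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.einsum("nij,nj->ni", np.linalg.pinv(K, rcond=1e-12), rhs)
        x = sol[:, :5]
        G = K[:, :5, :5]
        ssr = pp - 2.0 * np.einsum("ni,ni->n", x, rhs[:, :5]) + np.einsum(
            "ni,nij,nj->n", x, G, x)
        ssr = np.where(np.isfinite(ssr), np.maximum(ssr, 0.0), np.inf)
        j = int(np.argmin(ssr))
        if ssr[j] < best:
            best = float(ssr[j])
            best_w = (float(w1_bpm[i]), float(w2_bpm[j]))
    return best, best_w


def pairwise_rank_auc(scores, labels):
    """Mann-Whitney AUC by exhaustive pair counting (ties count half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def autocorrelation_period(p, fs):
    """Dominant beat period (s) from the autocorrelation peak."""
    x = np.asarray(p, dtype=float)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    # first peak after the zero-lag fall-off
    k = 1
    while k < ac.size - 1 and ac[k] > ac[k + 1]:
        k += 1
    lag = k + int(np.argmax(ac[k:min(ac.size, k + int(2 * fs))]))
    return lag / fs
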
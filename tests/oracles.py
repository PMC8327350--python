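"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the equilibrium oracle
is an iterative grid search, the tau_c oracle a dense grid scan, and the
RMSD oracle a from-scratch Kabsch superposition via SVD.
"""

from __future__ import annotations

import numpy as np


def grid_solve_equilibrium(k_aa, k_bb, k_ab, a_total, b_total,
                           levels: int = 14, n: int = 161, window: int = 8):
    """Brute-force (log a, log b) grid search for the dimer equilibrium.

    Minimizes the maximum per-species-normalized residual of the two
    conservation equations on a zooming grid in log space (the free
    monomer amounts can sit many decades below the totals when binding is
    tight, which a linear grid cannot resolve).  The zoom window is
    generous (``window`` cells each side) because the argmin can sit a few
    cells along the residual valley away from the true crossing.  Returns
    (a, b) free monomer amounts.
    """
    scale_a = max(a_total, 1e-300)
    scale_b = max(b_total, 1e-300)
    lo_a, hi_a = np.log(a_total) - 35.0, np.log(a_total)
    lo_b = hi_b = None
    if b_total > 0:
        lo_b, hi_b = np.log(b_total) - 35.0, np.log(b_total)
    a_best, b_best = a_total, b_total
    for _ in range(levels):
        a = np.exp(np.linspace(lo_a, hi_a, n))
        b = (np.exp(np.linspace(lo_b, hi_b, n)) if b_total > 0
             else np.array([0.0]))
        aa, bb = np.meshgrid(a, b, indexing="ij")
        res_a = aa + 2 * aa ** 2 / k_aa + aa * bb / k_ab - a_total
        res_b = bb + 2 * bb ** 2 / k_bb + aa * bb / k_ab - b_total
        res = np.maximum(np.abs(res_a) / scale_a, np.abs(res_b) / scale_b)
        i, j = np.unravel_index(np.argmin(res), res.shape)
        a_best, b_best = a[i], b[j]
        da = (hi_a - lo_a) / (n - 1)
        lo_a = np.log(a_best) - window * da
        hi_a = min(np.log(a_best) + window * da, np.log(a_total))
        if b_total > 0:
            db = (hi_b - lo_b) / (n - 1)
            lo_b = np.log(b_best) - window * db
            hi_b = min(np.log(b_best) + window * db, np.log(b_total))
    return a_best, b_best


def grid_fractions(k_aa, k_bb, k_ab, a_total, b_total):
    """A-chain species fractions from the grid oracle."""
    a, b = grid_solve_equilibrium(k_aa, k_bb, k_ab, a_total, b_total)
    aa = a * a / k_aa
    ab = a * b / k_ab
    return np.array([a, 2 * aa, ab]) / a_total


def grid_invert_tau(rate, field_mhz, forward, n: int = 100_000):
    """Dense tau_c grid scan (ns) picking the closest forward rate."""
    taus = np.linspace(0.5, 50.0, n)
    rates = np.array([forward(t, field_mhz) for t in taus])
    return taus[np.argmin(np.abs(rates - rate))]


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via an explicit SVD Kabsch rotation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    s_corr = np.array([1.0, 1.0, d])
    rot = u @ np.diag(s_corr) @ vt
    diff = a - b @ rot.T
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


def min_image_27(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> float:
    """Minimum distance over all 27 periodic images (brute force)."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(p2 + shift - p1)))
    return best
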
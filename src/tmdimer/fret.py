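"""FRET efficiency versus surface concentration.

Pixel-level records of donor concentration, acceptor concentration and
FRET efficiency (receptors/um^2, dimensionless E) are binned by total
concentration, tested against the zero-FRET control expectation, and
compared with a two-species 2D mass-action heterodimer forward model.
Proximity (random) FRET is deliberately not modelled: the constructs the
analysis targets are designed so that unspecific proximity gives no
signal; ``hetero_fret_forward`` accepts an ``e_proximity`` hook should
that assumption need revisiting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmdimer.equilibrium import EquilibriumParams, solve_equilibrium

REQUIRED_COLUMNS = ("donor_conc", "acceptor_conc", "efficiency")


@dataclass
class BinnedFret:
    """Per-bin mean FRET efficiency with SEM; empty bins are absent."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, mean, sem, n

    def __len__(self) -> int:
        return len(self.table)


def bin_fret(records: pd.DataFrame, edges) -> BinnedFret:
    """Bin records by total (donor + acceptor) concentration.

    Bins are half-open ``[lo, hi)``; records outside the edge range are
    dropped.  Mean efficiency, SEM and count are reported per occupied bin.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    total = records["donor_conc"].to_numpy() + records["acceptor_conc"].to_numpy()
    idx = np.digitize(total, edges)  # [lo, hi) convention
    rows = []
    for b in range(1, edges.size):
        sel = records.loc[idx == b, "efficiency"]
        if sel.empty:
            continue
        n = len(sel)
        sem = float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"bin_lo": edges[b - 1], "bin_hi": edges[b],
                     "mean": float(sel.mean()), "sem": sem, "n": n})
    if not rows:
        warnings.warn("no records fall inside the bin range", stacklevel=2)
        return BinnedFret(pd.DataFrame(
            columns=["bin_lo", "bin_hi", "mean", "sem", "n"]))
    return BinnedFret(pd.DataFrame(rows))


@dataclass
class NonzeroTest:
    """Per-bin one-sample test of mean E against zero with FDR control."""

    table: pd.DataFrame  # bin_lo, bin_hi, n, t, p, p_adj, reject
    skipped: pd.DataFrame  # bins with insufficient n
    positive_call: bool


def test_nonzero(binned: BinnedFret, alpha: float = 0.05,
                 min_n: int = 3) -> NonzeroTest:
    """Is the binned FRET signal positive overall?

    Each bin with at least ``min_n`` records gets a one-sided one-sample
    t statistic ``t = mean / SEM`` (df = n - 1) against E = 0; p-values
    are Benjamini-Hochberg adjusted across bins, and the overall positive
    call requires a strict majority of tested bins to reject.
    """
    tbl = binned.table
    testable = tbl[tbl["n"] >= min_n].copy()
    skipped = tbl[tbl["n"] < min_n].copy()
    if testable.empty:
        return NonzeroTest(testable.assign(t=[], p=[], p_adj=[], reject=[]),
                           skipped, False)
    with np.errstate(divide="ignore"):
        t = np.where(testable["sem"] > 0,
                     testable["mean"] / testable["sem"], np.inf)
    p = stats.t.sf(t, df=testable["n"] - 1)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    testable["t"] = t
    testable["p"] = p
    testable["p_adj"] = p_adj
    testable["reject"] = reject
    positive = int(reject.sum()) > len(testable) / 2
    return NonzeroTest(testable, skipped, bool(positive))


# the name starts with "test_" for API reasons; it is not a pytest test
test_nonzero.__test__ = False


def hetero_fret_forward(donor_conc, acceptor_conc, kd_2d: float,
                        e_intrinsic: float, e_proximity: float = 0.0):
    """Predicted FRET efficiency under a 1:1 2D heterodimer equilibrium.

    The donor-bound fraction comes from the two-species mass-action
    equilibrium (the competition solver with the homodimer channels
    disabled); E = e_intrinsic x bound fraction.  ``e_proximity`` is a
    hook for a future random-FRET term and defaults to zero.
    """
    if not kd_2d > 0:
        raise ValueError("kd_2d must be positive")
    if not 0.0 <= e_intrinsic <= 1.0:
        raise ValueError("e_intrinsic must lie in [0, 1]")
    params = EquilibriumParams(np.inf, np.inf, kd_2d)
    donor = np.atleast_1d(np.asarray(donor_conc, dtype=float))
    acceptor = np.atleast_1d(np.asarray(acceptor_conc, dtype=float))
    donor, acceptor = np.broadcast_arrays(donor, acceptor)
    out = np.empty(donor.shape)
    for i in np.ndindex(donor.shape):
        if donor[i] == 0 or acceptor[i] == 0:
            out[i] = 0.0
            continue
        frac_d, _ = solve_equilibrium(params, donor[i], acceptor[i])
        out[i] = e_intrinsic * frac_d.f_het
    out = out + e_proximity
    return float(out[0]) if out.size == 1 and np.isscalar(donor_conc) else out
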
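"""Competitive homo/heterodimer equilibrium in the hydrophobic phase.

Two transmembrane helices A (isotope-labelled, observed) and B (unlabelled
titrant) partition between five species: free monomers ``a`` and ``b``,
homodimers AA and BB, and the heterodimer AB.  Mass action in
hydrophobic-phase mole-fraction units with dissociation constants
``k_aa``, ``k_bb``, ``k_ab``:

    [AA] = a^2 / k_aa     [BB] = b^2 / k_bb     [AB] = a * b / k_ab

and chain conservation

    a_total = a + 2 a^2/k_aa + a b/k_ab
    b_total = b + 2 b^2/k_bb + a b/k_ab

The solution is unique for positive constants: for fixed ``b`` the first
equation is a quadratic in ``a`` with one positive root, and the residual
of the second equation is then strictly increasing in ``b``.

The same solver doubles as the two-species 2D heterodimer model used in the
FRET analysis (homodimer channels disabled with infinite constants), in
which case concentrations are surface densities (molecules / um^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

DEFAULT_RESIDUES = (259, 263, 266, 269, 270)
STATES = ("monomer", "homodimer", "heterodimer")


@dataclass(frozen=True)
class EquilibriumParams:
    """Dissociation constants (hydrophobic-phase mole fractions, > 0).

    ``inf`` disables a channel (e.g. disulfide-locked dimers that do not
    exchange are represented as a non-participating species, and the
    heterodimer-only FRET model uses infinite homodimer constants).
    """

    k_aa: float
    k_bb: float
    k_ab: float

    def __post_init__(self) -> None:
        for name in ("k_aa", "k_bb", "k_ab"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of labelled chains in each state (sum to 1)."""

    f_mono: float
    f_homo: float
    f_het: float

    @property
    def dimer_relative(self) -> float:
        """Homodimer share of all dimerized chains, f_homo/(f_homo + f_het)."""
        denom = self.f_homo + self.f_het
        if denom == 0:
            return float("nan")
        return self.f_homo / denom

    def as_array(self) -> np.ndarray:
        return np.array([self.f_mono, self.f_homo, self.f_het])


def _monomer_a(b: float, a_total: float, k_aa: float, k_ab: float) -> float:
    """Positive root of 2a^2/k_aa + a(1 + b/k_ab) - a_total = 0."""
    beta = 1.0 + b / k_ab
    if not np.isfinite(k_aa):
        return a_total / beta
    alpha = 2.0 / k_aa
    # numerically stable form of the positive quadratic root
    return 2.0 * a_total / (beta + np.sqrt(beta * beta + 4.0 * alpha * a_total))


def solve_equilibrium(
    params: EquilibriumParams,
    a_total: float,
    b_total: float,
    *,
    rtol: float = 1e-12,
) -> tuple[SpeciesFractions, SpeciesFractions]:
    """Solve the competing dimerization equilibrium.

    Returns the species fractions of A chains and of B chains.  Mass is
    conserved to better than 1e-10 relative; non-convergence raises with
    the residuals.
    """
    if a_total < 0 or b_total < 0:
        raise ValueError("totals must be non-negative")
    k_aa, k_bb, k_ab = params.k_aa, params.k_bb, params.k_ab

    if b_total == 0:
        b = 0.0
        a = _monomer_a(0.0, a_total, k_aa, k_ab)
    else:

        def residual(b: float) -> float:
            a = _monomer_a(b, a_total, k_aa, k_ab)
            homo = 2.0 * b * b / k_bb if np.isfinite(k_bb) else 0.0
            return b + homo + a * b / k_ab - b_total

        b = brentq(residual, 0.0, b_total, xtol=1e-300, rtol=1e-15,
                   maxiter=300)
        a = _monomer_a(b, a_total, k_aa, k_ab)
        # one Newton polish to push the b-side residual toward machine noise
        for _ in range(2):
            r = residual(b)
            beta = 1.0 + b / k_ab
            alpha = 0.0 if not np.isfinite(k_aa) else 2.0 / k_aa
            da_db = -(a / k_ab) / (2.0 * alpha * a + beta)
            db_homo = 4.0 * b / k_bb if np.isfinite(k_bb) else 0.0
            dr = 1.0 + db_homo + (a + b * da_db) / k_ab
            step = r / dr
            if b - step < 0:
                break
            b -= step
            a = _monomer_a(b, a_total, k_aa, k_ab)

    aa = a * a / k_aa if np.isfinite(k_aa) else 0.0
    bb = b * b / k_bb if np.isfinite(k_bb) else 0.0
    ab = a * b / k_ab if np.isfinite(k_ab) else 0.0

    res_a = abs(a + 2 * aa + ab - a_total)
    res_b = abs(b + 2 * bb + ab - b_total)
    scale = max(a_total, b_total, 1e-300)
    if max(res_a, res_b) / scale > max(rtol, 1e-10):
        raise RuntimeError(
            f"equilibrium solver did not converge: residuals "
            f"({res_a:.3e}, {res_b:.3e}) for totals ({a_total}, {b_total})")

    def fractions(total: float, mono: float, homo: float, het: float) -> SpeciesFractions:
        if total == 0:
            return SpeciesFractions(1.0, 0.0, 0.0)
        return SpeciesFractions(mono / total, 2 * homo / total, het / total)

    return (fractions(a_total, a, aa, ab), fractions(b_total, b, bb, ab))


def monomer_closed_form(a_total: float, k_aa: float) -> float:
    """Free monomer for a pure homodimer equilibrium (no partner present).

    Closed form of a_total = a + 2a^2/k_aa:
    a = k_aa (-1 + sqrt(1 + 8 a_total/k_aa)) / 4.
    """
    return k_aa * (-1.0 + np.sqrt(1.0 + 8.0 * a_total / k_aa)) / 4.0


# ---------------------------------------------------------------------------
# Titration series and population extraction
# ---------------------------------------------------------------------------


@dataclass
class TitrationPoint:
    """Peak intensities at one partner:labelled molar ratio.

    ``intensities`` maps residue -> state -> intensity (arbitrary units);
    states are ``monomer``, ``homodimer``, ``heterodimer``.
    """

    ratio: float
    intensities: dict[int, dict[str, float]]


@dataclass
class TitrationSeries:
    """A titration at constant lipid(detergent)-to-protein ratio.

    ``labeled_total`` is the labelled-chain mole fraction of the
    hydrophobic phase; at LPR 80 one peptide per 80 detergents gives
    1/80 = 0.0125.
    """

    points: list[TitrationPoint]
    lpr: float = 80.0
    labeled_total: float = 1.0 / 80.0
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ratios = [p.ratio for p in self.points]
        if any(r < 0 for r in ratios):
            raise ValueError("ratios must be non-negative")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        for p in self.points:
            for res, states in p.intensities.items():
                for s, v in states.items():
                    if v < 0:
                        raise ValueError(
                            f"negative intensity for residue {res} state {s}")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])


@dataclass
class PopulationEstimate:
    fractions: SpeciesFractions
    per_residue: dict[int, SpeciesFractions]
    excluded: list[int]


def populations_from_intensities(
    point: TitrationPoint,
    residues: tuple[int, ...] | None = None,
    denominator: str = "all_states",
) -> PopulationEstimate:
    """Convert per-residue peak intensities into species populations.

    ``denominator='dimer_only'`` reproduces the homodimer-vs-heterodimer
    share (homodimer intensity divided by the summed homo- and heterodimer
    intensities, averaged across residues); ``'all_states'`` returns the
    full three-state fractions.  Peak intensity is assumed proportional to
    population with one scale factor per residue shared across states.
    Residues with a zero denominator are excluded with a warning.
    """
    if denominator not in ("dimer_only", "all_states"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if residues is None:
        residues = tuple(r for r in DEFAULT_RESIDUES if r in point.intensities) \
            or tuple(sorted(point.intensities))
    per_residue: dict[int, SpeciesFractions] = {}
    excluded: list[int] = []
    for res in residues:
        try:
            states = point.intensities[res]
            vals = [states[s] for s in STATES]
        except KeyError as exc:
            raise KeyError(f"residue {res} missing state intensity: {exc}") from exc
        mono, homo, het = vals
        if denominator == "dimer_only":
            denom = homo + het
            if denom == 0:
                excluded.append(res)
                continue
            per_residue[res] = SpeciesFractions(0.0, homo / denom, het / denom)
        else:
            denom = mono + homo + het
            if denom == 0:
                excluded.append(res)
                continue
            per_residue[res] = SpeciesFractions(mono / denom, homo / denom,
                                                het / denom)
    if excluded:
        warnings.warn(f"residues with zero denominator excluded: {excluded}",
                      stacklevel=2)
    if not per_residue:
        raise ValueError("no residue with a nonzero denominator")
    arr = np.mean([f.as_array() for f in per_residue.values()], axis=0)
    return PopulationEstimate(SpeciesFractions(*arr), per_residue, excluded)


# ---------------------------------------------------------------------------
# Fitting the titration
# ---------------------------------------------------------------------------

_LOGK_BOUNDS = (-8.0, 2.0)


@dataclass
class TitrationFit:
    params: EquilibriumParams
    covariance: np.ndarray  # covariance of the fitted log10 constants
    residuals: np.ndarray
    free_names: tuple[str, ...]
    identifiable: bool
    message: str

    def se_log10(self) -> dict[str, float]:
        d = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.free_names, d))


def _series_fractions(series: TitrationSeries,
                      residues: tuple[int, ...] | None) -> np.ndarray:
    obs = []
    for point in series.points:
        est = populations_from_intensities(point, residues, "all_states")
        obs.append(est.fractions.as_array())
    return np.array(obs)


def fit_titration(
    series: TitrationSeries,
    fixed: dict[str, float] | None = None,
    residues: tuple[int, ...] | None = None,
    n_starts: int = 4,
) -> TitrationFit:
    """Weighted least-squares fit of the competition model to a titration.

    Observed three-state fractions of the labelled chain at every titration
    point are fitted against the model fractions from ``solve_equilibrium``
    with the labelled total held at ``series.labeled_total`` and the
    partner total at ``ratio * labeled_total``.  Constants are optimised in
    log10 space with multi-start; the covariance of the log-constants comes
    from the Jacobian at the optimum.  A fit is flagged non-identifiable
    when a constant runs into its bounds or its log10 standard error
    exceeds 2 (a 100-fold uncertainty).
    """
    fixed = dict(fixed or {})
    names = [n for n in ("k_aa", "k_bb", "k_ab") if n not in fixed]
    if not names:
        raise ValueError("no free parameters")
    if len(series.points) < 3:
        raise ValueError("need at least 3 titration points")
    if len(series.points) < len(names):
        raise ValueError("fewer titration points than free parameters")

    observed = _series_fractions(series, residues)
    a_tot = series.labeled_total
    b_tots = series.ratios * a_tot

    def unpack(theta: np.ndarray) -> EquilibriumParams:
        vals = dict(fixed)
        for n, t in zip(names, theta):
            vals[n] = 10.0 ** t
        return EquilibriumParams(**vals)

    def resid(theta: np.ndarray) -> np.ndarray:
        p = unpack(theta)
        model = np.array([
            solve_equilibrium(p, a_tot, bt)[0].as_array() for bt in b_tots
        ])
        return (model - observed).ravel()

    lo, hi = _LOGK_BOUNDS
    rng_starts = np.linspace(-3.5, -0.5, n_starts)
    best = None
    for s in rng_starts:
        theta0 = np.full(len(names), s)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
        except RuntimeError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("titration fit failed from every start")

    n_obs, n_par = best.fun.size, len(names)
    dof = max(n_obs - n_par, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * 2 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.inf)

    at_bound = np.any(np.abs(best.x - lo) < 1e-6) or np.any(
        np.abs(best.x - hi) < 1e-6)
    big_se = np.any(np.sqrt(np.abs(np.diag(cov))) > 2.0)
    identifiable = not (at_bound or big_se)
    msg = "ok" if identifiable else (
        "non-identifiable: parameter at bound" if at_bound
        else "non-identifiable: log10 SE > 2")
    return TitrationFit(unpack(best.x), cov, best.fun, tuple(names),
                        identifiable, msg)


# ---------------------------------------------------------------------------
# Chemical shift perturbation
# ---------------------------------------------------------------------------


def cs_perturbation(
    shifts,
    weight_n: float = 0.154,
    threshold: float = 0.1,
):
    """Combined amide chemical-shift perturbation per residue.

    ``shifts`` is a DataFrame with columns ``residue, h_ref, n_ref,
    h_pert, n_pert`` (ppm).  Delta = sqrt(dH^2 + (weight_n * dN)^2); residues
    with Delta strictly greater than ``threshold`` are flagged.  Residues
    missing either state (NaN) are excluded and listed.

    Returns (DataFrame with residue, delta_h, delta_n, delta, flagged;
    list of excluded residues).
    """
    import pandas as pd

    df = shifts.copy()
    required = {"residue", "h_ref", "n_ref", "h_pert", "n_pert"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    complete = df[["h_ref", "n_ref", "h_pert", "n_pert"]].notna().all(axis=1)
    excluded = df.loc[~complete, "residue"].astype(int).tolist()
    df = df[complete]
    dh = df["h_pert"] - df["h_ref"]
    dn = df["n_pert"] - df["n_ref"]
    delta = np.sqrt(dh ** 2 + (weight_n * dn) ** 2)
    out = pd.DataFrame({
        "residue": df["residue"].astype(int),
        "delta_h": dh,
        "delta_n": dn,
        "delta": delta,
        "flagged": delta > threshold,
    }).reset_index(drop=True)
    return out, excluded
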
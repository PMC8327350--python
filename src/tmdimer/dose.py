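"""Three-parameter log(agonist)-response fitting and EC50 comparison.

The model is the GraphPad-style three-parameter log-logistic curve with
unit Hill slope,

    Y = bottom + (top - bottom) / (1 + 10^(logEC50 - X)),

where X is the log10 molar agonist dose and EC50 = 10^logEC50 is the dose
giving a response halfway between bottom and top.  Doses tabulated in
ng/ml are converted to molar with a configurable agonist molar mass
(default: the 26.5 kDa NGF dimer); zero doses enter the fit at a
configurable log-floor (default: one decade below the lowest nonzero
dose) because a log-dose model has no zero abscissa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, OptimizeWarning
from scipy.stats import norm, t as t_dist

#: NGF is active as a homodimer of ~26.5 kDa.
DEFAULT_AGONIST_MASS_KDA = 26.5


def logistic3(x, bottom: float, top: float, logec50: float):
    """The three-parameter log-logistic response."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - np.asarray(x)))


def ng_ml_to_molar(dose_ng_ml, mass_kda: float = DEFAULT_AGONIST_MASS_KDA):
    """ng/ml -> mol/l for an agonist of the given molar mass (kDa)."""
    return np.asarray(dose_ng_ml, dtype=float) * 1e-6 / (mass_kda * 1e3)


def log_molar_doses(dose_ng_ml, mass_kda: float = DEFAULT_AGONIST_MASS_KDA,
                    zero_floor_decades: float = 1.0) -> np.ndarray:
    """log10 molar doses with zero doses floored below the lowest nonzero dose."""
    molar = ng_ml_to_molar(dose_ng_ml, mass_kda)
    nonzero = molar[molar > 0]
    if nonzero.size == 0:
        raise ValueError("all doses are zero")
    floor = np.log10(nonzero.min()) - zero_floor_decades
    out = np.where(molar > 0, np.log10(np.where(molar > 0, molar, 1.0)), floor)
    return out


def normalize_response(phospho_band, total_band, scale: str = "raw_ratio"):
    """Phospho/total band ratio, optionally min-max scaled.

    ``raw_ratio`` divides the phospho signal by the total-protein signal;
    ``minmax`` additionally rescales the ratios to [0, 1].
    """
    phospho = np.asarray(phospho_band, dtype=float)
    total = np.asarray(total_band, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total band intensity must be positive")
    ratio = phospho / total
    if scale == "raw_ratio":
        return ratio
    if scale == "minmax":
        lo, hi = ratio.min(), ratio.max()
        if hi == lo:
            raise ValueError("cannot min-max scale a constant response")
        return (ratio - lo) / (hi - lo)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    logec50: float
    logec50_se: float
    bottom_se: float
    top_se: float
    covariance: np.ndarray
    converged: bool
    message: str
    n_points: int

    @property
    def ec50(self) -> float:
        return ec50_from_log(self.logec50)

    def ci_logec50(self, level: float = 0.95) -> tuple[float, float]:
        # t-based interval: the dose grids are short, so the normal
        # quantile would undercover
        df = max(self.n_points - 3, 1)
        q = t_dist.ppf(0.5 + level / 2, df)
        return (self.logec50 - q * self.logec50_se,
                self.logec50 + q * self.logec50_se)


def ec50_from_log(logec50: float) -> float:
    """EC50 (molar) from its base-10 logarithm."""
    if not np.isfinite(logec50):
        raise ValueError("logec50 must be finite")
    return float(10.0 ** logec50)


def fit_logistic(data: pd.DataFrame, x_col: str = "log10_molar",
                 y_col: str = "response", n_starts: int = 7) -> DoseResponseFit:
    """Nonlinear least-squares fit of the three-parameter curve.

    Multi-start over a logEC50 grid spanning the dosed range guards
    against local minima; standard errors come from the parameter
    covariance.  Flat data (top ~ bottom) is flagged as a failed fit.
    """
    x = np.asarray(data[x_col], dtype=float)
    y = np.asarray(data[y_col], dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points spanning the transition")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct doses")

    span = y.max() - y.min()
    best = None
    for lec0 in np.linspace(x.min(), x.max(), n_starts):
        try:
            with warnings.catch_warnings():
                # a perfect (zero-residual) fit has no estimable covariance
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    logistic3, x, y, p0=[y.min(), y.max(), lec0], maxfev=10000)
        except RuntimeError:
            continue
        rss = float(np.sum((logistic3(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.full((3, 3), np.nan), False,
                               "no start converged", x.size)
    _, popt, pcov = best
    bottom, top, logec50 = popt
    se = np.sqrt(np.abs(np.diag(pcov)))
    flat = span == 0 or abs(top - bottom) < 1e-3 * max(span, 1e-12)
    msg = "ok"
    if flat:
        msg = "flat data: top ~ bottom, EC50 undefined"
    return DoseResponseFit(float(bottom), float(top), float(logec50),
                           float(se[2]), float(se[0]), float(se[1]),
                           pcov, not flat, msg, x.size)


@dataclass
class CurveComparison:
    delta_logec50: float
    se: float
    z: float
    p_value: float
    fold_change: float


def compare_curves(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> CurveComparison:
    """Shift of logEC50 between conditions: B - A, with propagated SE.

    ``fold_change`` = 10^delta is the EC50 ratio (B over A); a fold above 1
    means condition B needs more agonist for the half-maximal response.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    delta = fit_b.logec50 - fit_a.logec50
    se = float(np.hypot(fit_a.logec50_se, fit_b.logec50_se))
    z = delta / se if se > 0 else np.inf * np.sign(delta)
    p = 2 * norm.sf(abs(z))
    return CurveComparison(float(delta), se, float(z), float(p),
                           float(10.0 ** delta))
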
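"""Typed tabular I/O for every table kind the pipeline consumes.

Tables are TSV (CSV accepted) with ``#`` header comments recording units.
Every reader validates the mandatory columns of its kind and reports
unparsable numerics with the offending row index; writer/reader pairs
round-trip bit-identically for text tables.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from tmdimer.dose import log_molar_doses, DEFAULT_AGONIST_MASS_KDA
from tmdimer.equilibrium import TitrationPoint, TitrationSeries

#: kind -> (mandatory columns, unit comment lines)
TABLE_SPECS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "titration": (
        ("ratio", "residue", "monomer", "homodimer", "heterodimer"),
        ("ratio: partner:labeled molar ratio (dimensionless)",
         "monomer/homodimer/heterodimer: peak intensity (arbitrary units)"),
    ),
    "relaxation": (
        ("residue", "state", "rate", "error"),
        ("rate, error: eta_xy cross-correlated relaxation rate (s^-1)",),
    ),
    "shifts": (
        ("residue", "h_ref", "n_ref", "h_pert", "n_pert"),
        ("h_*, n_*: amide 1H and 15N chemical shifts (ppm)",),
    ),
    "dose_response": (
        ("dose_ng_ml", "response", "replicate", "condition"),
        ("dose_ng_ml: agonist dose (ng/ml)",
         "response: normalized phospho/total signal (dimensionless)"),
    ),
    "fret": (
        ("donor_conc", "acceptor_conc", "efficiency", "label"),
        ("donor_conc, acceptor_conc: receptors/um^2",
         "efficiency: FRET efficiency (dimensionless)"),
    ),
}

_NUMERIC = {
    "titration": ("ratio", "residue", "monomer", "homodimer", "heterodimer"),
    "relaxation": ("residue", "rate", "error"),
    "shifts": ("residue", "h_ref", "n_ref", "h_pert", "n_pert"),
    "dose_response": ("dose_ng_ml", "response", "replicate"),
    "fret": ("donor_conc", "acceptor_conc", "efficiency"),
}


def read_table(path, kind: str, *,
               mass_kda: float = DEFAULT_AGONIST_MASS_KDA) -> pd.DataFrame:
    """Read and validate a typed table; row order is preserved.

    Dose-response tables gain a ``log10_molar`` column from the configured
    agonist molar mass (the ng/ml -> molar conversion is never silent: the
    mass used is recorded in ``df.attrs``).
    """
    if kind not in TABLE_SPECS:
        raise ValueError(f"unknown table kind {kind!r}; "
                         f"expected one of {sorted(TABLE_SPECS)}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # round_trip parsing so written values survive read->write bit-identically
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    required, _ = TABLE_SPECS[kind]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing mandatory columns: "
                         f"{sorted(missing)}")
    for col in _NUMERIC[kind]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{kind} table column {col!r}: unparsable "
                             f"numeric at row {int(bad[0])}")
        df[col] = coerced
    if kind == "titration":
        neg = df[["monomer", "homodimer", "heterodimer"]].lt(0).any(axis=1)
        if neg.any():
            raise ValueError(f"titration table: negative intensity at row "
                             f"{int(df.index[neg][0])}")
    if kind == "relaxation" and (df["rate"] <= 0).any():
        raise ValueError("relaxation table: rates must be positive")
    if kind == "fret" and (df[["donor_conc", "acceptor_conc"]] < 0).any().any():
        raise ValueError("fret table: concentrations must be non-negative")
    if kind == "dose_response":
        if (df["dose_ng_ml"] < 0).any():
            raise ValueError("dose_response table: doses must be non-negative")
        df["log10_molar"] = log_molar_doses(df["dose_ng_ml"].to_numpy(),
                                            mass_kda)
        df.attrs["mass_kda"] = mass_kda
    return df


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a typed table as TSV with unit header comments."""
    if kind not in TABLE_SPECS:
        raise ValueError(f"unknown table kind {kind!r}")
    required, units = TABLE_SPECS[kind]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing mandatory columns: "
                         f"{sorted(missing)}")
    buf = io.StringIO()
    for line in units:
        buf.write(f"# {line}\n")
    df[list(required)].to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Conversions between tables and domain objects
# ---------------------------------------------------------------------------


def titration_to_table(series: TitrationSeries) -> pd.DataFrame:
    rows = []
    for point in series.points:
        for res, states in sorted(point.intensities.items()):
            rows.append({"ratio": point.ratio, "residue": res, **states})
    return pd.DataFrame(rows)


def titration_from_table(df: pd.DataFrame, lpr: float = 80.0,
                         labeled_total: float = 1.0 / 80.0) -> TitrationSeries:
    points = []
    for ratio, grp in df.groupby("ratio", sort=True):
        intensities = {
            int(row.residue): {"monomer": row.monomer,
                               "homodimer": row.homodimer,
                               "heterodimer": row.heterodimer}
            for row in grp.itertuples()
        }
        points.append(TitrationPoint(float(ratio), intensities))
    return TitrationSeries(points, lpr=lpr, labeled_total=labeled_total)
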
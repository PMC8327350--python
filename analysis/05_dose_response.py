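#!/usr/bin/env python
"""Fit the three-parameter log(agonist)-response model per condition.

Reads results/data/dose_response.tsv (four cotransfection conditions over
0-100 ng/ml NGF), fits Y = bottom + (top-bottom)/(1+10^(LogEC50-X)) per
condition, converts LogEC50 to molar EC50 (26.5 kDa NGF dimer) and
compares every condition against the TrkA + p75-wt curve.  Writes
results/dose_response_fits.json and a fitted-curves figure.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from tmdimer import dose, tables


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    df = tables.read_table(args.data / "dose_response.tsv", "dose_response")
    truth = json.loads((args.data / "dose_response_truth.json").read_text())

    fits, report = {}, {"fits": {}, "comparisons": {}}
    fig, ax = plt.subplots(figsize=(5.5, 3.8))
    grid = np.linspace(df["log10_molar"].min(), df["log10_molar"].max(), 200)
    for cond, grp in df.groupby("condition"):
        fit = dose.fit_logistic(grp)
        fits[cond] = fit
        report["fits"][cond] = {
            "logec50": round(fit.logec50, 3),
            "logec50_se": round(fit.logec50_se, 3),
            "ec50_molar": float(f"{fit.ec50:.3g}"),
            "truth_logec50": truth[cond],
        }
        print(f"{cond:14s} LogEC50 {fit.logec50:7.3f} ± {fit.logec50_se:.3f} "
              f"(truth {truth[cond]:7.3f})  EC50 {fit.ec50:.2e} M")
        ax.plot(grp["log10_molar"], grp["response"], "o", ms=3, alpha=0.6)
        ax.plot(grid, dose.logistic3(grid, fit.bottom, fit.top, fit.logec50),
                label=cond)

    ref = "trka_p75wt"
    for cond, fit in fits.items():
        if cond == ref:
            continue
        cmp = dose.compare_curves(fits[ref], fit)
        report["comparisons"][f"{ref}_vs_{cond}"] = {
            "delta_logec50": round(cmp.delta_logec50, 3),
            "fold_change": round(cmp.fold_change, 2),
            "p": float(f"{cmp.p_value:.3g}"),
        }
        print(f"  vs {ref}: {cond} shifts EC50 "
              f"{cmp.fold_change:.1f}-fold (p = {cmp.p_value:.2g})")

    ax.set_xlabel("log10 NGF (M)")
    ax.set_ylabel("normalized phospho-TrkA")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(args.out / "dose_response_curves.png", dpi=150)
    (args.out / "dose_response_fits.json").write_text(
        json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
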
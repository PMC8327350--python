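#!/usr/bin/env python
"""Generate every synthetic input class with known ground truth.

Writes under results/data/: a three-state NMR titration table (2% peak
noise, LPR 80), a short two-helix association trajectory (XYZ), four
dose-response tables at the reference LogEC50 per condition, and
unliganded + control FRET tables.  Ground-truth sidecars accompany each
dataset so downstream recovery can be judged.
"""

import argparse
import json
from pathlib import Path

from tmdimer import synthetic, tables, trajio

CONDITIONS = {
    "trka": -9.219,
    "trka_p75wt": -9.524,
    "trka_p75tnfr": -8.56,
    "trka_p75aga": -8.776,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    series = synthetic.gen_titration(
        synthetic.TitrationSimSpec(noise_sd=0.02, seed=args.seed))
    tables.write_table(tables.titration_to_table(series),
                       out / "titration.tsv", "titration")
    p = series.truth["params"]
    (out / "titration_truth.json").write_text(json.dumps(
        {"k_aa": p.k_aa, "k_bb": p.k_bb, "k_ab": p.k_ab}, indent=2))
    print(f"titration: {len(series.points)} points, truth k = "
          f"({p.k_aa}, {p.k_bb}, {p.k_ab}) mole fraction")

    traj = synthetic.gen_trajectory(synthetic.TrajectorySimSpec(
        n_frames=40, seed=args.seed, jitter_sd=0.3, start_separation=12.0))
    trajio.write_trajectory(traj, out / "two_helix_demo.xyz", "xyz")
    print(f"trajectory demo: {traj.n_frames} frames, "
          f"{traj.lipids.shape[1]} lipid beads, box {traj.box[0].round(1)}")

    frames = []
    for cond, logec50 in CONDITIONS.items():
        df = synthetic.gen_dose_response(logec50=logec50, top=1.0,
                                         bottom=0.1, noise_sd=0.05,
                                         seed=args.seed, condition=cond)
        frames.append(df)
    import pandas as pd
    dose = pd.concat(frames, ignore_index=True)
    tables.write_table(dose, out / "dose_response.tsv", "dose_response")
    (out / "dose_response_truth.json").write_text(
        json.dumps(CONDITIONS, indent=2))
    print(f"dose-response: {len(dose)} rows over {len(CONDITIONS)} conditions")

    fret = synthetic.gen_fret(n_regions=400, seed=args.seed)
    control = synthetic.gen_fret(n_regions=400, control=True,
                                 seed=args.seed + 1)
    tables.write_table(pd.concat([fret, control], ignore_index=True),
                       out / "fret.tsv", "fret")
    print(f"fret: {len(fret)} unliganded + {len(control)} control regions")


if __name__ == "__main__":
    main()
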
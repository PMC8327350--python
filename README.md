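# tmdimer

Quantitative analysis of transmembrane-domain (TMD) mediated receptor
heterodimerization, built around the interaction between the neurotrophin
receptors p75 (residues 245–284) and TrkA (residues 410–447).

Whether two single-pass receptors touch through their transmembrane
helices is hard to establish with any single technique. This package
implements, as one tested pipeline, the complementary quantitative
analyses that together make the case — each runnable on synthetic data
with known ground truth:

- **`tmdimer.equilibrium`** — competitive mass-action modelling of NMR
  titrations in detergent micelles. Labelled chains A partition between
  monomer, homodimer AA and heterodimer AB with dissociation constants in
  hydrophobic-phase mole fractions:

  `[AA] = a²/k_AA`, `[BB] = b²/k_BB`, `[AB] = a·b/k_AB`,
  with `a_tot = a + 2a²/k_AA + ab/k_AB` and symmetrically for B.

  Peak intensities → species populations → weighted least-squares fit of
  (k_AA, k_BB, k_AB); plus combined amide chemical-shift perturbations
  Δδ = √(ΔδH² + (0.154·ΔδN)²).
- **`tmdimer.sizing`** — oligomer sizing from DD–CSA cross-correlated
  relaxation: η_xy → rotational correlation time τc (numerical inversion
  of the monotone rate expression) → equivalent-sphere radius via the
  rotational Stokes–Einstein relation `r = (3 k_B T τc / 4πη)^{1/3}`,
  and nearest-reference oligomer classification.
- **`tmdimer.trajectory`** — two-helix trajectory analysis: minimum-image
  inter-helix distances, dwell-based dimerization detection, residue-pair
  contact occupancy and interface motifs in `x`-gap notation, helix
  crossing angles, endpoint azimuth/sector statistics, Kabsch-RMSD
  single-linkage clustering of endpoint conformations, and membrane
  descriptors (periodic Voronoi area per lipid, reference-plane bilayer
  thickness, electron density profiles).
- **`tmdimer.dose`** — the three-parameter log(agonist)–response model
  `Y = bottom + (top − bottom)/(1 + 10^{LogEC50 − X})`, EC50 extraction
  and between-condition curve comparison.
- **`tmdimer.fret`** — FRET efficiency versus receptor surface
  concentration: binning, per-bin testing against a zero-FRET control
  with FDR correction, and a 2D heterodimer forward model.
- **`tmdimer.synthetic`** — generators for every input class (titrations
  at detergent-to-protein ratio 80, Brownian two-helix association
  trajectories with an attractive interface patch, sigmoidal dose
  responses over 0–100 ng/ml, FRET fields with a zero-control
  population), all seeded and carrying their ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data; each prints what it found and writes tables under `results/`:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_titration_equilibrium.py
python analysis/03_oligomer_sizing.py
python analysis/04_trajectory_analysis.py --seed 1
python analysis/05_dose_response.py
python analysis/06_fret_analysis.py
```

Selected output (seed 1):

```
dissociation constants (hydrophobic-phase mole fraction):
  k_aa: fitted 0.00993 vs truth 0.01000 (0.7% off)
  k_ab: fitted 0.00992 vs truth 0.01000 (0.8% off)
  k_ab/k_aa = 1.00: homo- and heterodimerization constants of comparable magnitude

monomer      tau_c 10.20 ns -> radius 2.618 nm
homodimer    tau_c 13.10 ns -> radius 2.846 nm
heterodimer  tau_c 12.70 ns -> radius 2.817 nm
heterocomplex tau_c sits nearest the homodimer reference: dimer-sized

stable heterodimer in 11/12 runs; 12/12 endpoints share one azimuthal sector
p75 interface motif:  C257 S258 xx A261 A262 xx V265 G266 xx A269
TrkA interface motif: V418 xxx V422 xxx V426 F427 xx L430
membrane: area per lipid 63.2 A^2, thickness 34.8 A (glycerol) / 38.5 A (phosphate)

trka           LogEC50  -9.134 ± 0.058 (truth  -9.219)  EC50 7.35e-10 M
trka_p75wt     LogEC50  -9.451 ± 0.049 (truth  -9.524)  EC50 3.54e-10 M
  vs trka_p75wt: trka_p75aga shifts EC50 7.2-fold (p = 1.1e-08)

control   : 0/5 bins above zero -> no interaction
unliganded: 6/6 bins above zero -> interaction
```

Reading this: the titration fit recovers all three dissociation constants
from 2%-noise peak intensities and finds homo- and heterodimerization of
comparable strength; the relaxation chain sizes the new micellar complex
as a dimer (its τc matches the homodimer, not the monomer); the
trajectory analysis finds the heterodimer forming and persisting in
11/12 runs with p75 docked on one specific TrkA face through the
C257…A269 / V418…L430 interfaces; mutating that interface (AGA→III)
shifts the NGF EC50 about 7-fold; and binned hetero-FRET is positive at
all surface concentrations while the non-interacting control stays at
zero.

A `tmdimer` console command exposes the same stages
(`simulate`, `titration-fit`, `sizing`, `traj-analyze`, `dose-response`,
`fret`); each subcommand logs its configuration and seed and writes a
machine-readable result file.

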
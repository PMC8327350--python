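# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Competing dimer equilibrium (`tmdimer.equilibrium`)

Two transmembrane helices A (isotope-labelled, observed by NMR) and B
(unlabelled titrant) are confined to the hydrophobic phase of detergent
micelles. Concentrations are expressed as hydrophobic-phase mole
fractions: micellar association equilibria depend on the
peptide-per-detergent statistics, which is precisely why the titrations
are run at a constant detergent-to-protein molar ratio (LPR 80, giving a
labelled-chain mole fraction of 1/80 = 0.0125). Molar ↔ mole-fraction
conversion via the LPR and a configurable DPC aggregation number
(default 54) is available but the solver itself is scale-agnostic.

Mass action with dissociation constants `k_AA`, `k_BB`, `k_AB`:

    [AA] = a²/k_AA   [BB] = b²/k_BB   [AB] = a·b/k_AB
    a_tot = a + 2[AA] + [AB]
    b_tot = b + 2[BB] + [AB]

Statistical factors of the heterodimer are absorbed into `k_AB`, making
the fitted constant convention-free. Infinite constants disable a
channel; disulfide-locked wild-type p75 dimers, which do not exchange on
titration, are represented this way rather than as a fourth species.

**Solver.** For fixed `b` the A-equation is a quadratic with a single
positive root (evaluated in the cancellation-free form); substituting it
into the B-equation leaves a residual that is strictly increasing in
`b`, so a bracketed Brent search on `[0, b_tot]` (relative tolerance
1e-15) followed by two Newton polish steps gives the unique solution.
Mass balance is verified to 1e-10 relative on exit; worse residuals
raise. The no-partner limit has the closed form
`a = k_AA(−1 + √(1 + 8 a_tot/k_AA))/4`, used as an internal cross-check.
The same solver with `k_AA = k_BB = ∞` is the two-species 2D
heterodimer model of the FRET analysis.

**Populations from intensities.** Peak intensity is assumed proportional
to state population with one scale factor per residue shared across the
three states (the assumption implicit in dividing intensities directly);
differential relaxation across states is a known caveat, not modelled.
The default reporter residues are I259, V263, G266, A269 and Y270 — the
five whose monomer/homodimer/heterodimer crosspeaks resolve separately.
`dimer_only` mode returns the homodimer share of dimerized chains,
`all_states` the full three-state fractions; zero-denominator residues
are excluded with a warning.

**Fitting.** The three constants are optimised in log10 space
(bounds 1e-8–1e2) by least squares against the observed three-state
fractions at every titration point, with four starts spread over
10⁻³·⁵–10⁻⁰·⁵. The covariance of the log-constants comes from the
Jacobian at the optimum; a fit is flagged non-identifiable when a
constant runs into a bound (e.g. no heterodimer signal drives `k_AB` to
the upper bound) or its log10 standard error exceeds 2.

**Chemical-shift perturbation.** Δδ = √(ΔδH² + (w·ΔδN)²) with the
conventional amide nitrogen weight w = 0.154; residues with Δδ strictly
above the threshold (default 0.1 ppm) are flagged.

## Relaxation-based sizing (`tmdimer.sizing`)

The DD–CSA transverse cross-correlated relaxation rate for isotropic
tumbling is implemented as

    η_xy = (d·c/8) · (3cos²θ − 1) · [4J(0) + 3J(ω_N)],
    J(ω) = (2/5)·τc / (1 + (ωτc)²)

with dipolar constant `d = (μ0/4π)·ħ·γH·γN / r³` and CSA constant
`c = ω_N·|Δσ|/3`. Defaults: N–H distance 1.02 Å, ¹⁵N CSA −160 ppm,
DD–CSA angle 17°, all configurable. Magnitudes are used throughout, so
the rate is positive and strictly increasing in τc for all τc (the
derivative of 4J(0) + 3J(ω_N) is bounded below by a positive constant),
which makes the inversion a bracketed root search on 0.01–500 ns; rates
outside that branch raise. Because no printed rate value anchors the
constant conventions, the expression is validated by round-trip,
monotonicity and dense-grid-scan properties rather than against a
literature number.

Rates across reporter residues are combined by inverse-variance
weighting. The equivalent-sphere radius follows from the rotational
Stokes–Einstein relation; the default viscosity is pure water at the
measurement temperature (0.596 mPa·s at 318.15 K), under which the three
measured correlation times 10.2 / 13.1 / 12.7 ns map to 2.62 / 2.85 /
2.82 nm. Oligomer classification deliberately compares τc (the measured
quantity) rather than the derived radius, so it does not compound the
viscosity assumption; a measurement whose τc interval overlaps both the
monomer and dimer reference intervals is `indeterminate`.

## Trajectory analysis (`tmdimer.trajectory`)

Conventions: Å, right-handed axes, membrane normal +z, frames 0-indexed,
author residue numbering (p75 245–284, TrkA 410–447). All pair distances
use the minimum-image convention in an orthorhombic box (verified
against a 27-image brute force).

- **Dimerization detection**: earliest frame with the W276–K441
  reference-bead distance strictly below the cutoff for at least `dwell`
  consecutive frames. Defaults: 10 Å and 100 frames — the distance
  regime a formed heterodimer occupies, with persistence standing in for
  "does not dissociate".
- **Contacts**: residue-pair occupancy = fraction of frames with any
  inter-bead distance below the cutoff (default 5.5 Å between side-chain
  beads for CG-like systems; 4.5 Å heavy-atom is the full-atom
  convention). Interface motifs list residues with occupancy above
  threshold in sequence order, with skipped residues rendered as `x`
  gaps.
- **Helix geometry**: the axis is the leading eigenvector of the
  backbone-bead covariance, oriented N→C — robust for near-straight TM
  helices. The crossing angle is the 3D angle between the two axes with
  the sign taken from the handedness against the inter-centroid vector.
  The endpoint azimuth of the partner around a target helix is measured
  in the membrane plane, zeroed at the reference residue's in-plane
  direction; because a finite helix's bead centroid sits ~0.1 Å off the
  geometric axis the azimuth carries a sub-degree systematic offset —
  irrelevant for sector classification with 60–120° sectors, which is
  its purpose. Sector residue sets (e.g. the active vs inactive TrkA
  homodimerization faces) are configuration data, not hard-coded.
- **Endpoint clustering**: optimal-superposition pairwise RMSD
  (scipy's `Rotation.align_vectors`, validated against an independent
  SVD Kabsch), single-linkage at a configurable cut, reporting the
  per-cluster average pairwise RMSD alongside the cut so results are
  auditable. Single linkage is a choice, not a necessity; it is reported
  with the result.
- **Membrane descriptors**: area per lipid by periodic 2D Voronoi
  tessellation (the 8 periodic images bound every central cell, so the
  cell areas tile the box exactly); bilayer thickness as the distance
  between leaflet mean planes of a chosen reference bead (glycerol `GL`
  or phosphate `PO4`); electron density as the frame-averaged
  z-histogram of bead electron weights divided by bin volume, whose
  integral times the box area returns the total weight exactly. A
  perfectly colinear lipid set is rejected as degenerate.

## Synthetic generators (`tmdimer.synthetic`)

All generators are deterministic given a seed and attach their ground
truth to the output.

**Titration** (`gen_titration`): solver fractions × per-residue scale
(uniform 0.5–1.5) × multiplicative Gaussian noise truncated at zero
(NMR peak-height noise scales with signal). Defaults are the study
conditions: labelled total 1/80, eight partner ratios 0–4, constants
`k_AA = k_BB = k_AB = 0.01` — the comparable-magnitude regime the
titrations report.

**Two-helix trajectory** (`gen_trajectory`): two rigid ideal α-helices
(1.5 Å rise, 100°/residue, backbone beads at 2.3 Å, side-chain beads at
4.3 Å) built from the construct sequences, axes along the membrane
normal, undergoing overdamped in-plane Brownian translation and rotation
about their own axes (Euler–Maruyama proposals). The attraction is a
two-level flat well on the axis–axis distance — full depth below 8.5 Å,
half depth on a capture shelf to 11.5 Å, hard core at 6 Å — gated on
both helices presenting their interface patch (±40° about the azimuth of
p75 G266 and TrkA V422) to each other; `patch_halfwidth=None` makes the
well isotropic, emulating an interface-scrambled mutant. Because a
discontinuous potential has no gradient, proposals are accepted by
Metropolis, which preserves the Brownian dynamics between boundary
crossings and detailed balance at them. The discrete shelf (rather than
a graded rim) means escape requires rare full-height jumps instead of a
cheap gradual climb. Effective diffusion constants (5 Å²/ns, 0.5
rad²/ns) are coarse-grained-like — CG dynamics run conventionally ~4×
faster than atomistic. The default contact energy is 12 kT: TM helix
dimers in bilayers bind by tens of kJ/mol and, once formed on a CG
trajectory, do not dissociate on the simulated timescale; at 12 kT a
formed dimer survives to the final frame in essentially every run,
mirroring that permanence, while at 8 kT association still forms within
most 5000-frame runs but occasionally dissolves. Lipids are decorative
geometry for the membrane-descriptor operators: an exact hexagonal
lattice (the in-plane box snaps to the commensurate size) at 63.2 Å²
per lipid with glycerol and phosphate reference planes at ±17.4 and
±19.2 Å (the equilibrated-POPC values), optional per-frame Gaussian
jitter, and nominal electron counts per bead. No lipid–helix forces
exist, and the helices never tilt, bend or leave the membrane plane —
so passing tests demonstrate the correctness of the analysis operators
on realistic geometry, not the physics of lipid-mediated association.

**Dose response** (`gen_dose_response`): the three-parameter model at
the log10 molar doses plus additive Gaussian noise; defaults 0, 0.1, 1,
10, 100 ng/ml × 3 replicates at noise SD 0.05, matching the experiment's
dosing scheme and a realistic blot-quantification scatter. ng/ml → molar
uses a configurable agonist mass, default the 26.5 kDa NGF dimer, and
the conversion is always reported, never silent. Zero doses are floored
one decade below the lowest nonzero dose in log space — a log-dose model
has no zero abscissa and the floor sensitivity is testable.

**FRET** (`gen_fret`): donor and acceptor surface concentrations drawn
log-uniformly over 50–3000 /µm² (transfection variability spans decades),
efficiency = intrinsic E (0.4) × donor-bound fraction from the 2D
heterodimer equilibrium (default Kd 300 /µm², a weak membrane
interaction) plus Gaussian noise; control mode is pure noise about zero.
Proximity (random) FRET is excluded — the experimental constructs were
designed not to produce it — but the forward model exposes an
`e_proximity` hook.

## Dose–response fitting (`tmdimer.dose`)

Nonlinear least squares of the printed three-parameter equation with the
Hill slope fixed at 1, multi-started over a LogEC50 grid spanning the
dosed range. Standard errors come from the parameter covariance;
confidence intervals use t quantiles with n − 3 degrees of freedom
because the dose grids are short and normal quantiles undercover (the
Monte-Carlo calibration in the tests shows ~92–95% coverage for nominal
95%). Flat data (top ≈ bottom) is flagged as a failed fit rather than
returning a meaningless EC50. Curve comparison reports
ΔLogEC50 = LogEC50_B − LogEC50_A, its propagated SE, a z statistic and
the fold change 10^Δ; the propagated SE matches a parametric bootstrap
of the shift distribution in the tests.

## FRET analysis (`tmdimer.fret`)

Records are binned by total (donor + acceptor) concentration into
half-open `[lo, hi)` bins; empty bins are absent from the output. Each
bin with at least 3 records is tested one-sided against E = 0 with
t = mean/SEM (df = n − 1); Benjamini–Hochberg controls the FDR across
bins, and the overall positive-interaction call requires a strict
majority of tested bins to reject — a deliberately conservative rule
whose type-I rate on control data is far below nominal.

## Problem sizes

The test suite and the acceptance script use: 100 titration Monte-Carlo
seeds at 2% noise, 12 association runs of 5000 frames (0.2 ns/frame),
200 dose-response seeds for CI coverage and 200 FRET control seeds —
sizes chosen so every stochastic statistic is stable to within its
asserted band while the whole suite stays fast on a single CPU.

## Known limitations

- Peak intensities are treated as strictly population-proportional; no
  lineshape, chemical-exchange or per-micelle Poisson occupancy
  modelling.
- The rate→τc inversion assumes isotropic tumbling with standard amide
  constants; no anisotropic diffusion tensors or micelle-shape
  hydrodynamic corrections.
- The trajectory generator's physics is intentionally minimal (see
  above); engine-grade observables (equilibrated area per lipid,
  cluster RMSDs of real force-field runs) are reproduced here only on
  constructed geometry.
- The FRET forward model is strictly 1:1; higher-order stoichiometries
  are not fit.
- Zero-dose handling and the ng/ml→molar mass are documented choices a
  real dataset might want revisited; both are configurable and reported
  with every fit.
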
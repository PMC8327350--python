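"""Synthetic-data generators with known ground truth.

Every input class of the pipeline can be generated here so all stages are
testable without external data:

* three-state NMR titration intensities at constant detergent-to-protein
  ratio 80 (``gen_titration``),
* diffusive two-helix association trajectories with a defined interface
  patch in a decorative bilayer (``gen_trajectory``),
* sigmoidal phospho-receptor dose responses over 0-100 ng/ml agonist
  (``gen_dose_response``),
* pixel-level FRET efficiency versus surface concentration under a 2D
  heterodimer model, plus a zero-FRET control population (``gen_fret``).

Generators are deterministic given a seed and attach their ground truth to
the output (``truth`` / ``meta``) for closed-loop recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmdimer.dose import logistic3, log_molar_doses, DEFAULT_AGONIST_MASS_KDA
from tmdimer.equilibrium import (EquilibriumParams, SpeciesFractions,
                                 solve_equilibrium, DEFAULT_RESIDUES,
                                 TitrationPoint, TitrationSeries)
from tmdimer.fret import hetero_fret_forward
from tmdimer.helices import (P75_SEQUENCE, P75_START, TRKA_SEQUENCE,
                             TRKA_START, build_ideal_helix, residue_phase)
from tmdimer.trajio import TwoHelixTrajectory, minimum_image

# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------

#: Dissociation constants of comparable magnitude (hydrophobic-phase mole
#: fractions) — the regime the titrations report.
DEFAULT_EQUILIBRIUM = EquilibriumParams(k_aa=0.01, k_bb=0.01, k_ab=0.01)


@dataclass
class TitrationSimSpec:
    """Forward model for a three-state titration at constant LPR.

    ``labeled_total`` is the labelled-chain mole fraction of the
    hydrophobic phase (one peptide per LPR detergents -> 1/80); ratios are
    partner:labelled molar ratios as titrated.
    """

    params: EquilibriumParams = DEFAULT_EQUILIBRIUM
    labeled_total: float = 1.0 / 80.0
    ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
    noise_sd: float = 0.0
    residues: tuple[int, ...] = DEFAULT_RESIDUES
    lpr: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be non-negative")
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_titration(spec: TitrationSimSpec) -> TitrationSeries:
    """Generate per-residue three-state peak intensities along a titration.

    Intensities are species fractions from the equilibrium solver times a
    per-residue scale factor (shared across states) times multiplicative
    Gaussian noise truncated at zero.  The solver ground truth is stored
    in ``series.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    scales = {r: rng.uniform(0.5, 1.5) for r in spec.residues}
    points = []
    truth_fractions: list[SpeciesFractions] = []
    for ratio in spec.ratios:
        frac_a, _ = solve_equilibrium(spec.params, spec.labeled_total,
                                      ratio * spec.labeled_total)
        truth_fractions.append(frac_a)
        intensities = {}
        for res in spec.residues:
            vals = frac_a.as_array() * scales[res]
            if spec.noise_sd > 0:
                vals = vals * (1.0 + spec.noise_sd * rng.standard_normal(3))
            intensities[res] = dict(zip(("monomer", "homodimer", "heterodimer"),
                                        np.maximum(vals, 0.0)))
        points.append(TitrationPoint(ratio, intensities))
    truth = {
        "params": spec.params,
        "fractions": truth_fractions,
        "scales": scales,
    }
    return TitrationSeries(points, lpr=spec.lpr,
                           labeled_total=spec.labeled_total, truth=truth)


# ---------------------------------------------------------------------------
# Two-helix trajectory
# ---------------------------------------------------------------------------

#: Membrane defaults: equilibrated POPC-like geometry — area per lipid
#: 63.2 A^2, glycerol-plane separation 34.8 A, phosphate-plane separation
#: 38.4 A.
DEFAULT_APL = 63.2
DEFAULT_GLYCEROL_Z = 34.8 / 2
DEFAULT_PHOSPHATE_Z = 38.4 / 2
#: Nominal electron counts of the POPC glycerol and phosphate moieties.
ELECTRONS = {"GL": 67.0, "PO4": 47.0}


@dataclass
class TrajectorySimSpec:
    """Brownian two-helix association with a square-well interface patch.

    Both helices are rigid ideal alpha-helices built from the construct
    sequences, axes along the membrane normal.  In-plane translation and
    rotation about the own axis are overdamped Brownian; an attractive
    square well of depth ``well_depth`` (kT) engages when the axes are
    within ``well_range`` and (unless ``patch_halfwidth`` is None) each
    helix presents its interface patch to the other.  Lipids are jittered
    lattice points in two leaflets, decorative geometry for the membrane
    descriptors.
    """

    n_frames: int = 5000
    dt: float = 0.2  # ns per saved frame
    box: float = 90.0  # A, square in-plane, cubic record
    #: Effective in-plane diffusion, coarse-grained-like (CG dynamics are
    #: conventionally ~4x faster than atomistic).
    diffusion_t: float = 5.0  # A^2/ns, translation
    diffusion_r: float = 0.5  # rad^2/ns, rotation about the helix axis
    #: Contact free energy of the bound pair.  Transmembrane helix dimers
    #: in bilayers bind by tens of kJ/mol and, once formed on a
    #: coarse-grained trajectory, do not dissociate on the simulated
    #: timescale; 12 kT reproduces that permanence.  At 8 kT association
    #: still forms within most runs but occasionally dissolves.
    well_depth: float = 12.0  # kT
    well_range: float = 8.5  # A, axis-axis distance of the full-depth bottom
    #: A half-depth capture shelf extends the well outward; the discrete
    #: step (rather than a graded ramp) means escape requires rare
    #: full-height jumps instead of a cheap gradual climb.
    shelf: float = 3.0  # A
    hard_core: float = 6.0  # A, no interpenetration
    #: Interface patch centres, degrees: the azimuthal phase of p75 G266
    #: and TrkA V422 on the ideal helix.
    interface_azimuth_a: float = residue_phase(266, P75_START)
    interface_azimuth_b: float = residue_phase(422, TRKA_START)
    patch_halfwidth: float | None = 40.0  # degrees; None = isotropic well
    start_separation: float = 55.0  # A
    lipid_apl: float = DEFAULT_APL  # A^2, hexagonal lattice cell area
    glycerol_z: float = DEFAULT_GLYCEROL_Z
    phosphate_z: float = DEFAULT_PHOSPHATE_Z
    jitter_sd: float = 0.0  # A, per-frame lipid jitter
    with_lipids: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box <= 2 * self.well_range:
            raise ValueError("box must exceed twice the well range")
        if self.lipid_apl <= 0 or self.n_frames < 1 or self.dt <= 0:
            raise ValueError("invalid trajectory spec")


def hexagonal_lattice(box: float, apl: float) -> tuple[np.ndarray, float, float]:
    """Exact hexagonal lattice with cell area ``apl`` near a target box size.

    Returns (points (N, 2), box_x, box_y): a perfect hexagonal tiling with
    spacing a = sqrt(apl / (sqrt(3)/2)) whose periodic box is the
    commensurate size closest to ``box``.  The caller must use the
    returned box dimensions so each Voronoi cell has area exactly ``apl``.
    """
    a = np.sqrt(apl / (np.sqrt(3) / 2))
    row = a * np.sqrt(3) / 2
    nx = max(int(round(box / a)), 3)
    ny = max(int(round(box / (2 * row))) * 2, 4)  # even row count wraps cleanly
    box_x = nx * a
    box_y = ny * row
    pts = []
    for j in range(ny):
        off = 0.0 if j % 2 == 0 else a / 2
        for i in range(nx):
            pts.append((i * a + off, j * row))
    return np.array(pts), box_x, box_y


def gen_trajectory(spec: TrajectorySimSpec) -> TwoHelixTrajectory:
    """Simulate the two-helix Brownian association and materialize beads.

    Dynamics use Euler-Maruyama Gaussian proposals with Metropolis
    acceptance for the square-well + hard-core energy (exact for a
    discontinuous potential).  Ground truth in ``meta``: the first frame
    of the final bound period, the bound fraction and the simulation
    parameters.
    """
    rng = np.random.default_rng(spec.seed)
    # The in-plane box snaps to the lipid lattice so the hexagonal tiling is
    # exact; without lipids it is the requested square.
    if spec.with_lipids:
        lattice_pts, box_x, box_y = hexagonal_lattice(spec.box, spec.lipid_apl)
    else:
        lattice_pts, box_x, box_y = None, spec.box, spec.box
    box_xy = np.array([box_x, box_y])
    half = spec.start_separation / 2
    centers = np.array([[box_x / 2 - half, box_y / 2],
                        [box_x / 2 + half, box_y / 2]])
    phis = rng.uniform(0, 2 * np.pi, size=2)

    step_t = np.sqrt(2 * spec.diffusion_t * spec.dt)
    step_r = np.sqrt(2 * spec.diffusion_r * spec.dt)
    az_a = np.deg2rad(spec.interface_azimuth_a)
    az_b = np.deg2rad(spec.interface_azimuth_b)
    halfwidth = (np.deg2rad(spec.patch_halfwidth)
                 if spec.patch_halfwidth is not None else None)

    def wrap_pi(x: float) -> float:
        return (x + np.pi) % (2 * np.pi) - np.pi

    capture = spec.well_range + spec.shelf

    def energy(c: np.ndarray, p: np.ndarray) -> float:
        # two-level attractive well (full-depth bottom + half-depth capture
        # shelf), gated on both interface patches facing each other
        d_vec = minimum_image(c[1] - c[0], box_xy)
        d = np.hypot(*d_vec)
        if d < spec.hard_core:
            return np.inf
        if d >= capture:
            return 0.0
        if halfwidth is not None:
            bearing_ab = np.arctan2(d_vec[1], d_vec[0])
            if abs(wrap_pi(bearing_ab - (p[0] + az_a))) > halfwidth:
                return 0.0
            if abs(wrap_pi(bearing_ab + np.pi - (p[1] + az_b))) > halfwidth:
                return 0.0
        if d <= spec.well_range:
            return -spec.well_depth
        return -spec.well_depth / 2.0

    centers_t = np.empty((spec.n_frames, 2, 2))
    phis_t = np.empty((spec.n_frames, 2))
    bound = np.zeros(spec.n_frames, dtype=bool)
    e_cur = energy(centers, phis)
    for t in range(spec.n_frames):
        prop_c = centers + step_t * rng.standard_normal((2, 2))
        prop_p = phis + step_r * rng.standard_normal(2)
        e_new = energy(prop_c, prop_p)
        de = e_new - e_cur
        if de <= 0 or rng.random() < np.exp(-de):
            centers, phis, e_cur = prop_c % box_xy, prop_p % (2 * np.pi), e_new
        centers_t[t] = centers
        phis_t[t] = phis
        # "bound" ground truth = sitting in the flat bottom of the well
        bound[t] = e_cur <= -spec.well_depth + 1e-12

    # materialize bead coordinates
    local_a, resids_a, names_a = build_ideal_helix(P75_SEQUENCE, P75_START)
    local_b, resids_b, names_b = build_ideal_helix(TRKA_SEQUENCE, TRKA_START)

    def place(local: np.ndarray, which: int) -> np.ndarray:
        cosp = np.cos(phis_t[:, which])
        sinp = np.sin(phis_t[:, which])
        x = local[:, 0][None, :] * cosp[:, None] - local[:, 1][None, :] * sinp[:, None]
        y = local[:, 0][None, :] * sinp[:, None] + local[:, 1][None, :] * cosp[:, None]
        out = np.empty((spec.n_frames, local.shape[0], 3))
        out[:, :, 0] = x + centers_t[:, which, 0][:, None]
        out[:, :, 1] = y + centers_t[:, which, 1][:, None]
        out[:, :, 2] = local[:, 2][None, :]
        return out

    coords_a = place(local_a, 0)
    coords_b = place(local_b, 1)

    lipids = lipid_names = leaflet = eweight = None
    if spec.with_lipids:
        pts = lattice_pts
        n_lip = pts.shape[0]
        base = []
        names = []
        leaf = []
        weights = []
        for side, sign in (("upper", 1.0), ("lower", -1.0)):
            for bead, zref in (("GL", spec.glycerol_z), ("PO4", spec.phosphate_z)):
                xyz = np.column_stack([pts, np.full(n_lip, sign * zref)])
                base.append(xyz)
                names.extend([bead] * n_lip)
                leaf.extend([side] * n_lip)
                weights.extend([ELECTRONS[bead]] * n_lip)
        base = np.vstack(base)
        lipid_names = np.array(names)
        leaflet = np.array(leaf)
        eweight = np.array(weights)
        lipids = np.repeat(base[None, :, :], spec.n_frames, axis=0)
        if spec.jitter_sd > 0:
            lipids = lipids + spec.jitter_sd * rng.standard_normal(lipids.shape)

    # ground truth: start of the last unbroken bound stretch reaching the end
    association_frame = None
    if bound[-1]:
        idx = np.flatnonzero(~bound)
        association_frame = int(idx[-1] + 1) if idx.size else 0
    meta = {
        "association_frame": association_frame,
        "bound_fraction": float(bound.mean()),
        "bound": bound,
        "spec": spec,
    }
    return TwoHelixTrajectory(
        coords_a=coords_a, coords_b=coords_b,
        resids_a=resids_a, resids_b=resids_b,
        names_a=names_a, names_b=names_b,
        box=np.tile(np.array([box_x, box_y, spec.box]), (spec.n_frames, 1)),
        lipids=lipids, lipid_names=lipid_names, leaflet=leaflet,
        electron_weight=eweight, dt=spec.dt, meta=meta,
    )


#: Interface residues each construct presents to its partner in the
#: heterodimer model.
P75_INTERFACE = (257, 258, 261, 262, 265, 266, 269)
TRKA_INTERFACE = (418, 422, 426, 427, 430)


def gen_interface_fixture(
    iface_a: tuple[int, ...] = P75_INTERFACE,
    iface_b: tuple[int, ...] = TRKA_INTERFACE,
    gap: float = 4.0,
) -> TwoHelixTrajectory:
    """One-frame dimer constructed with exactly the given residues facing.

    Interface side-chain beads of the two helices sit ``gap`` A apart
    along x; all other beads are retracted far outside any contact
    cutoff.  This is the geometry on which the contact-map and motif
    operators are anchored.
    """
    na, nb = len(P75_SEQUENCE), len(TRKA_SEQUENCE)
    ra = np.arange(P75_START, P75_START + na)
    rb = np.arange(TRKA_START, TRKA_START + nb)
    ca = np.zeros((1, na, 3))
    cb = np.zeros((1, nb, 3))
    ca[0, :, 0] = np.where(np.isin(ra, iface_a), 0.0, -10.0)
    cb[0, :, 0] = np.where(np.isin(rb, iface_b), gap, gap + 10.0)
    return TwoHelixTrajectory(
        ca, cb, ra, rb, np.array(["SC"] * na), np.array(["SC"] * nb),
        box=np.array([[200.0, 200.0, 200.0]]))


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------

#: The dosing scheme used in the activation experiments (ng/ml).
DEFAULT_DOSES_NG_ML = (0.0, 0.1, 1.0, 10.0, 100.0)


def gen_dose_response(
    logec50: float,
    top: float = 1.0,
    bottom: float = 0.0,
    doses_ng_ml=DEFAULT_DOSES_NG_ML,
    reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    condition: str = "synthetic",
    mass_kda: float = DEFAULT_AGONIST_MASS_KDA,
) -> pd.DataFrame:
    """Forward-model a phospho-response titration with Gaussian noise.

    Responses follow the three-parameter log-logistic curve at the log10
    molar doses (zero dose floored one decade below the lowest nonzero
    dose); ground truth is attached as ``df.attrs['truth']``.
    """
    doses = np.asarray(doses_ng_ml, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    x = log_molar_doses(doses, mass_kda)
    rows = []
    for rep in range(reps):
        resp = logistic3(x, bottom, top, logec50)
        if noise_sd > 0:
            resp = resp + noise_sd * rng.standard_normal(x.size)
        for d, xv, rv in zip(doses, x, resp):
            rows.append({"dose_ng_ml": d, "log10_molar": xv, "response": rv,
                         "replicate": rep, "condition": condition})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"logec50": logec50, "top": top, "bottom": bottom,
                         "mass_kda": mass_kda}
    return df


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------


def gen_fret(
    n_regions: int = 300,
    kd_2d: float = 300.0,  # molecules/um^2; a weak membrane interaction
    e_intrinsic: float = 0.4,
    conc_range: tuple[float, float] = (50.0, 3000.0),
    control: bool = False,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Pixel-level FRET records under the 2D heterodimer model.

    Donor and acceptor surface concentrations are drawn log-uniformly over
    ``conc_range`` (independently, mimicking transfection variability).
    Non-control records carry E = e_intrinsic x donor-bound fraction plus
    Gaussian noise; control records are pure noise around zero.  Ground
    truth is attached as ``df.attrs['truth']``.
    """
    if not 0.0 <= e_intrinsic <= 1.0:
        raise ValueError("e_intrinsic must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = conc_range
    donor = np.exp(rng.uniform(np.log(lo), np.log(hi), n_regions))
    acceptor = np.exp(rng.uniform(np.log(lo), np.log(hi), n_regions))
    if control:
        eff = np.zeros(n_regions)
        label = "control"
    else:
        eff = hetero_fret_forward(donor, acceptor, kd_2d, e_intrinsic)
        label = "unliganded"
    eff = eff + noise_sd * rng.standard_normal(n_regions)
    df = pd.DataFrame({"donor_conc": donor, "acceptor_conc": acceptor,
                       "efficiency": eff, "label": label})
    df.attrs["truth"] = {"kd_2d": kd_2d, "e_intrinsic": e_intrinsic,
                         "control": control, "noise_sd": noise_sd}
    return df
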
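"""Geometry, kinetics, interface and membrane analysis of two-helix trajectories.

Operates on :class:`~tmdimer.trajio.TwoHelixTrajectory` objects: time series
of two labelled transmembrane helices plus decorative lipid reference beads
in an orthorhombic periodic box with the membrane normal along +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import Voronoi
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from tmdimer.helices import residue_one_letter
from tmdimer.trajio import TwoHelixTrajectory, minimum_image

#: Contact cutoff between side-chain reference beads of coarse-grained-like
#: systems (A); heavy-atom full-atom-like systems conventionally use 4.5 A.
DEFAULT_CONTACT_CUTOFF = 5.5
#: Dimerization detection defaults: reference-bead distance below 10 A
#: sustained for at least 100 consecutive frames.
DEFAULT_DIMER_CUTOFF = 10.0
DEFAULT_DWELL_FRAMES = 100
#: Default residue pair for the interhelix distance: a tryptophan near the
#: p75 helix C-terminus and a lysine near the TrkA helix C-terminus.
DEFAULT_PAIR = (276, 441)


def _reference_bead_index(resids: np.ndarray, names: np.ndarray, resid: int) -> int:
    idx = np.flatnonzero(resids == resid)
    if idx.size == 0:
        raise ValueError(f"residue {resid} not present")
    bb = idx[names[idx] == "BB"]
    return int(bb[0] if bb.size else idx[0])


def interhelix_distance(
    traj: TwoHelixTrajectory,
    residue_a: int = DEFAULT_PAIR[0],
    residue_b: int = DEFAULT_PAIR[1],
) -> np.ndarray:
    """Minimum-image distance (A) between two reference beads per frame."""
    ia = _reference_bead_index(traj.resids_a, traj.names_a, residue_a)
    ib = _reference_bead_index(traj.resids_b, traj.names_b, residue_b)
    delta = traj.coords_b[:, ib] - traj.coords_a[:, ia]
    delta = minimum_image(delta, traj.box)
    return np.linalg.norm(delta, axis=1)


def detect_dimerization(
    series: np.ndarray,
    cutoff: float = DEFAULT_DIMER_CUTOFF,
    dwell: int = DEFAULT_DWELL_FRAMES,
) -> int | None:
    """First frame of a stable association, or ``None``.

    Stable association = distance strictly below ``cutoff`` for at least
    ``dwell`` consecutive frames; the earliest such frame is returned.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty distance series")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    below = series < cutoff
    run = 0
    for t, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= dwell:
            return t - dwell + 1
    return None


# ---------------------------------------------------------------------------
# Contacts and interface
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Residue-pair contact occupancy over a frame range."""

    occupancy: np.ndarray  # (n_res_a, n_res_b) in [0, 1]
    resids_a: np.ndarray
    resids_b: np.ndarray
    cutoff: float
    frame_range: tuple[int, int]
    seq_a: str = ""
    start_a: int = 0
    seq_b: str = ""
    start_b: int = 0


def contact_occupancy(
    traj: TwoHelixTrajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    frame_range: tuple[int, int] | None = None,
) -> ContactMap:
    """Fraction of frames in which any inter-bead distance falls below ``cutoff``.

    Distances use the minimum-image convention; occupancy is per residue
    pair (minimum over the residues' beads).
    """
    if frame_range is None:
        frame_range = (0, traj.n_frames)
    lo, hi = frame_range
    if hi <= lo or lo < 0 or hi > traj.n_frames:
        raise ValueError(f"empty or invalid frame range {frame_range}")
    res_a = np.unique(traj.resids_a)
    res_b = np.unique(traj.resids_b)
    ia = np.searchsorted(res_a, traj.resids_a)
    ib = np.searchsorted(res_b, traj.resids_b)
    counts = np.zeros((res_a.size, res_b.size))
    for f in range(lo, hi):
        delta = traj.coords_a[f][:, None, :] - traj.coords_b[f][None, :, :]
        delta = minimum_image(delta, traj.box[f])
        d = np.linalg.norm(delta, axis=2)
        contact = np.zeros_like(counts, dtype=bool)
        np.logical_or.at(contact, (ia[:, None], ib[None, :]), d < cutoff)
        counts += contact
    return ContactMap(counts / (hi - lo), res_a, res_b, cutoff, (lo, hi),
                      traj.seq_a, traj.start_a, traj.seq_b, traj.start_b)


@dataclass
class InterfaceProfile:
    """Per-residue interface occupancy and the gap-notation motif string."""

    resids: np.ndarray
    occupancy: np.ndarray  # max over partner residues
    interface_resids: np.ndarray
    motif: str


def interface_profile(cmap: ContactMap, threshold: float = 0.5,
                      helix: str = "a") -> InterfaceProfile:
    """Interface residues (occupancy strictly above ``threshold``) as a motif.

    The motif lists interface residues in sequence order with runs of
    skipped residues rendered as ``x`` gaps, e.g.
    ``C257 S258 xx A261 A262 xx V265 G266 xx A269``.
    """
    if helix == "a":
        occ = cmap.occupancy.max(axis=1) if cmap.occupancy.size else np.array([])
        resids, seq, start = cmap.resids_a, cmap.seq_a, cmap.start_a
    elif helix == "b":
        occ = cmap.occupancy.max(axis=0) if cmap.occupancy.size else np.array([])
        resids, seq, start = cmap.resids_b, cmap.seq_b, cmap.start_b
    else:
        raise ValueError("helix must be 'a' or 'b'")
    mask = occ > threshold
    iface = resids[mask]
    tokens: list[str] = []
    prev = None
    for r in iface:
        if prev is not None and r - prev > 1:
            tokens.append("x" * (r - prev - 1))
        letter = residue_one_letter(seq, start, int(r)) if seq else "?"
        tokens.append(f"{letter}{int(r)}")
        prev = r
    return InterfaceProfile(resids, occ, iface, " ".join(tokens))


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------


def helix_axis(coords: np.ndarray, resids: np.ndarray,
               names: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(unit axis oriented N->C, centroid) from backbone beads of one frame."""
    bb = names == "BB"
    pts = coords[bb] if bb.any() else coords
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 backbone particles to define an axis")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] < 1e-12 or (w[-1] - w[-2]) < 1e-12 * max(w[-1], 1.0):
        raise ValueError("degenerate helix axis")
    axis = v[:, -1]
    if axis @ (pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis, center


def crossing_angle(traj: TwoHelixTrajectory, frame: int = -1) -> float:
    """Signed angle (degrees) between the two helix axes; 0 = parallel.

    Magnitude is the 3D angle between the N->C oriented principal axes;
    the sign follows the handedness of (axis_a x axis_b) against the
    minimum-image inter-centroid vector.
    """
    ax_a, c_a = helix_axis(traj.coords_a[frame], traj.resids_a, traj.names_a)
    ax_b, c_b = helix_axis(traj.coords_b[frame], traj.resids_b, traj.names_b)
    cosang = np.clip(ax_a @ ax_b, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    r12 = minimum_image(c_b - c_a, traj.box[frame])
    sign = np.sign(np.cross(ax_a, ax_b) @ r12)
    return float(angle if sign >= 0 else -angle)


@dataclass
class EndpointPose:
    """Azimuth of the partner helix around the target axis, plus sector."""

    azimuth: float  # degrees in [0, 360)
    sector: str | None


#: Example sector configuration: the two alternative TrkA homodimerization
#: faces plus the remainder.  Actual residue-derived sectors are
#: configuration data (see RunConfig.sector_definitions).
DEFAULT_SECTORS = (
    ("active", (300.0, 360.0)),
    ("inactive", (120.0, 180.0)),
    ("other", (0.0, 0.0)),  # catch-all
)


def sector_label(azimuth: float, sectors) -> str | None:
    catchall = None
    for label, (lo, hi) in sectors:
        if lo == hi:
            catchall = label
            continue
        if lo <= azimuth < hi:
            return label
    return catchall


def endpoint_azimuth(
    traj: TwoHelixTrajectory,
    target: str = "b",
    partner: str = "a",
    reference_residue: int | None = None,
    frame: int = -1,
    sectors=None,
) -> EndpointPose:
    """Azimuth of the partner helix around the target helix at one frame.

    Measured in the membrane (xy) plane, zero at the in-plane direction of
    the reference residue's backbone bead from the target axis, increasing
    counterclockwise.  Raises if the partner sits on the target axis.
    """
    t_coords, t_resids, t_names, _, t_start = traj.helix(target)
    p_coords, p_resids, p_names, _, _ = traj.helix(partner)
    if reference_residue is None:
        reference_residue = int(t_resids[0])
    _, t_center = helix_axis(t_coords[frame], t_resids, t_names)
    _, p_center = helix_axis(p_coords[frame], p_resids, p_names)
    delta = minimum_image(p_center - t_center, traj.box[frame])[:2]
    if np.linalg.norm(delta) < 1e-9:
        raise ValueError("partner helix centred on the target axis")
    iref = _reference_bead_index(t_resids, t_names, reference_residue)
    ref = (t_coords[frame, iref] - t_center)[:2]
    if np.linalg.norm(ref) < 1e-9:
        raise ValueError("reference residue has no in-plane direction")
    cross_z = ref[0] * delta[1] - ref[1] * delta[0]
    az = np.degrees(np.arctan2(cross_z, ref @ delta)) % 360.0
    label = sector_label(az, sectors) if sectors else None
    return EndpointPose(float(az), label)


# ---------------------------------------------------------------------------
# Endpoint clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per model, 1-based
    rmsd_matrix: np.ndarray
    cluster_sizes: dict[int, int]
    cluster_avg_rmsd: dict[int, float]
    cut: float

    @property
    def largest(self) -> int:
        return max(self.cluster_sizes, key=lambda k: self.cluster_sizes[k])


def pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposition RMSD between two (N, 3) conformations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("selection mismatch between models")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(a.shape[0]))


def cluster_endpoints(models, cut: float = 5.0) -> ClusterResult:
    """Single-linkage clustering of conformations on pairwise RMSD.

    ``models`` is a sequence of (N, 3) arrays over an identical atom
    selection; the per-cluster average pairwise RMSD is reported alongside
    the cut so results are auditable.
    """
    models = [np.asarray(m, dtype=float) for m in models]
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_rmsd(models[i], models[j])
    labels = fcluster(linkage(squareform(mat), method="single"), cut,
                      criterion="distance")
    sizes: dict[int, int] = {}
    avg: dict[int, float] = {}
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        sizes[int(cid)] = members.size
        if members.size < 2:
            avg[int(cid)] = 0.0
        else:
            sub = mat[np.ix_(members, members)]
            avg[int(cid)] = float(sub[np.triu_indices(members.size, 1)].mean())
    return ClusterResult(labels, mat, sizes, avg, cut)


# ---------------------------------------------------------------------------
# Membrane descriptors
# ---------------------------------------------------------------------------


def _leaflet_points(traj: TwoHelixTrajectory, frame: int, leaflet: str,
                    name: str | None = None) -> np.ndarray:
    if traj.lipids is None:
        raise ValueError("trajectory has no lipid reference particles")
    mask = traj.leaflet == leaflet
    if name is not None:
        mask &= traj.lipid_names == name
    if not mask.any():
        raise ValueError(f"no lipid particles in leaflet {leaflet!r}"
                         + (f" named {name!r}" if name else ""))
    return traj.lipids[frame][mask]


def voronoi_cell_areas(points_xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Periodic 2D Voronoi cell areas via the 8 periodic images.

    Every cell of a point in the central box is bounded because each point
    is surrounded by images, so the shoelace area of its region is exact;
    the areas tile the box (they sum to the box area).
    """
    points_xy = np.asarray(points_xy, dtype=float)
    n = points_xy.shape[0]
    if n < 3:
        raise ValueError("need at least 3 lipids per leaflet")
    sv = np.linalg.svd(points_xy - points_xy.mean(axis=0),
                       compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate lipid configuration: points are colinear")
    shifts = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       if (i, j) != (0, 0)])
    images = (points_xy[None, :, :] + (shifts[:, None, :] * box_xy)).reshape(-1, 2)
    allpts = np.vstack([points_xy, images])
    try:
        vor = Voronoi(allpts)
    except Exception as exc:  # QhullError on degenerate input
        raise ValueError(f"degenerate lipid configuration: {exc}") from exc
    areas = np.empty(n)
    for k in range(n):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or not region:
            raise ValueError("unbounded Voronoi cell: degenerate configuration")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[k] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def area_per_lipid(traj: TwoHelixTrajectory, frame: int = -1,
                   leaflet: str = "upper", name: str | None = "GL") -> float:
    """Mean periodic Voronoi cell area (A^2) of one leaflet's reference beads."""
    pts = _leaflet_points(traj, frame, leaflet, name)
    box_xy = traj.box[frame][:2]
    pts_xy = pts[:, :2] % box_xy  # wrap into the central box
    return float(voronoi_cell_areas(pts_xy, box_xy).mean())


def bilayer_thickness(traj: TwoHelixTrajectory, frame: int = -1,
                      reference: str = "glycerol") -> float:
    """|mean z(upper) - mean z(lower)| of the chosen reference beads (A)."""
    name = {"glycerol": "GL", "phosphate": "PO4"}.get(reference)
    if name is None:
        raise ValueError("reference must be 'glycerol' or 'phosphate'")
    upper = _leaflet_points(traj, frame, "upper", name)
    lower = _leaflet_points(traj, frame, "lower", name)
    return float(abs(upper[:, 2].mean() - lower[:, 2].mean()))


@dataclass
class DensityProfile:
    z_centers: np.ndarray
    density: np.ndarray  # e- / A^3
    bin_width: float
    area: float


def electron_density_profile(traj: TwoHelixTrajectory, bins: int = 50,
                             frames: slice | None = None) -> DensityProfile:
    """Frame-averaged electron density along the membrane normal.

    Histogram of per-bead electron weight divided by the bin volume
    (bin width x box area).  The profile integral times the box area
    equals the total electron weight exactly (conservation).
    """
    if traj.lipids is None or traj.electron_weight is None:
        raise ValueError("trajectory has no electron-weighted particles")
    if bins < 1:
        raise ValueError("need at least one bin")
    frame_idx = range(traj.n_frames)[frames] if frames else range(traj.n_frames)
    frame_idx = list(frame_idx)
    box = traj.box[frame_idx[0]]
    lz = box[2]
    edges = np.linspace(-lz / 2, lz / 2, bins + 1)
    if edges[1] - edges[0] <= 0:
        raise ValueError("zero-width bins")
    area = box[0] * box[1]
    acc = np.zeros(bins)
    for f in frame_idx:
        z = traj.lipids[f][:, 2]
        z = (z + lz / 2) % lz - lz / 2  # wrap into [-lz/2, lz/2)
        hist, _ = np.histogram(z, bins=edges, weights=traj.electron_weight)
        acc += hist
    width = edges[1] - edges[0]
    density = acc / len(frame_idx) / (width * area)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, width, float(area))
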
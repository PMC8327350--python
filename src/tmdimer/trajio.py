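"""Two-helix trajectory container and coordinate file I/O.

Conventions: coordinates in Angstrom, right-handed axes, membrane normal
along +z, frames 0-indexed, residues keep the construct numbering
(p75 245-284, TrkA 410-447).

Two plain-text formats are supported:

* multi-model PDB: ``MODEL``/``ENDMDL`` per frame, ``CRYST1`` carrying the
  periodic box (repeated before each model, or once for a constant box).
  Chain ``A``/``B`` hold the two helices; chain ``L`` holds lipid reference
  beads with the leaflet encoded in the residue name (``LUP``/``LLO``) and
  the per-bead electron weight in the B-factor column.
* XYZ-per-frame: an atom count line, a comment line ``box a b c [dt ns]``,
  then one record per particle: ``chain name resid x y z [eweight]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tmdimer.helices import P75_SEQUENCE, P75_START, TRKA_SEQUENCE, TRKA_START


class TrajectoryFormatError(ValueError):
    """Raised for malformed coordinate files."""


@dataclass
class TwoHelixTrajectory:
    """Time-ordered coordinates of two labelled helices in a periodic box.

    Lipid reference beads (optional) carry a leaflet label (``upper`` /
    ``lower``), a bead name (``GL`` glycerol, ``PO4`` phosphate) and an
    electron weight used by the density profile.
    """

    coords_a: np.ndarray  # (F, Na, 3) A
    coords_b: np.ndarray  # (F, Nb, 3) A
    resids_a: np.ndarray  # (Na,)
    resids_b: np.ndarray  # (Nb,)
    names_a: np.ndarray  # (Na,)
    names_b: np.ndarray  # (Nb,)
    box: np.ndarray  # (F, 3) A
    lipids: np.ndarray | None = None  # (F, NL, 3)
    lipid_names: np.ndarray | None = None  # (NL,)
    leaflet: np.ndarray | None = None  # (NL,) in {upper, lower}
    electron_weight: np.ndarray | None = None  # (NL,)
    dt: float = 1.0  # ns per frame
    seq_a: str = P75_SEQUENCE
    start_a: int = P75_START
    seq_b: str = TRKA_SEQUENCE
    start_b: int = TRKA_START
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords_a.ndim != 3 or self.coords_b.ndim != 3:
            raise ValueError("helix coordinates must be (frames, atoms, 3)")
        if self.coords_a.shape[0] != self.coords_b.shape[0]:
            raise ValueError("helices must have the same number of frames")
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must be (frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box dimensions must be positive")
        if self.leaflet is not None:
            bad = set(np.unique(self.leaflet)) - {"upper", "lower"}
            if bad:
                raise ValueError(f"unknown leaflet labels: {bad}")

    @property
    def n_frames(self) -> int:
        return self.coords_a.shape[0]

    def helix(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, str, int]:
        """(coords, resids, names, sequence, start) for helix 'a' or 'b'."""
        if which == "a":
            return self.coords_a, self.resids_a, self.names_a, self.seq_a, self.start_a
        if which == "b":
            return self.coords_b, self.resids_b, self.names_b, self.seq_b, self.start_b
        raise ValueError("helix must be 'a' or 'b'")


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) in an orthorhombic box."""
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_LEAFLET_RESNAME = {"upper": "LUP", "lower": "LLO"}
_RESNAME_LEAFLET = {v: k for k, v in _LEAFLET_RESNAME.items()}

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resid: int, xyz: np.ndarray, bfac: float) -> str:
    return (f"ATOM  {serial % 100000:5d} {name:<4.4s}{resname:>4.4s} "
            f"{chain}{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfac:6.2f}\n")


def write_trajectory(traj: TwoHelixTrajectory, path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or XYZ-per-frame."""
    path = Path(path)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _write_pdb(traj: TwoHelixTrajectory, path: Path) -> None:
    lines: list[str] = [f"REMARK   6 DT_NS {traj.dt!r}\n"]
    for f in range(traj.n_frames):
        a, b, c = traj.box[f]
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        lines.append(f"MODEL {f + 1:8d}\n")
        serial = 1
        for which in ("a", "b"):
            coords, resids, names, seq, start = traj.helix(which)
            chain = which.upper()
            for i in range(coords.shape[1]):
                resname = _AA3.get(seq[int(resids[i]) - start], "UNK")
                lines.append(_pdb_atom_line(serial, str(names[i]), resname,
                                            chain, int(resids[i]),
                                            coords[f, i], 0.0))
                serial += 1
        if traj.lipids is not None:
            for i in range(traj.lipids.shape[1]):
                resname = _LEAFLET_RESNAME[str(traj.leaflet[i])]
                w = float(traj.electron_weight[i]) if traj.electron_weight is not None else 0.0
                lines.append(_pdb_atom_line(serial, str(traj.lipid_names[i]),
                                            resname, "L", (i % 9999) + 1,
                                            traj.lipids[f, i], w))
                serial += 1
        lines.append("ENDMDL\n")
    lines.append("END\n")
    path.write_text("".join(lines))


def _write_xyz(traj: TwoHelixTrajectory, path: Path) -> None:
    n_lip = 0 if traj.lipids is None else traj.lipids.shape[1]
    n_atoms = traj.coords_a.shape[1] + traj.coords_b.shape[1] + n_lip
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"{n_atoms}\n")
        a, b, c = (float(v) for v in traj.box[f])
        lines.append(f"box {a!r} {b!r} {c!r} dt {float(traj.dt)!r}\n")
        for which in ("a", "b"):
            coords, resids, names, _, _ = traj.helix(which)
            for i in range(coords.shape[1]):
                x, y, z = (float(v) for v in coords[f, i])
                lines.append(f"{which.upper()} {names[i]} {int(resids[i])} "
                             f"{x!r} {y!r} {z!r}\n")
        for i in range(n_lip):
            x, y, z = (float(v) for v in traj.lipids[f, i])
            tag = "LUP" if traj.leaflet[i] == "upper" else "LLO"
            w = float(traj.electron_weight[i]) if traj.electron_weight is not None else 0.0
            lines.append(f"{tag} {traj.lipid_names[i]} {i + 1} "
                         f"{x!r} {y!r} {z!r} {w!r}\n")
    Path(path).write_text("".join(lines))


def read_trajectory(path, fmt: str | None = None, dt: float | None = None
                    ) -> TwoHelixTrajectory:
    """Read a multi-model PDB or XYZ-per-frame trajectory.

    Frames must have identical atom counts; a missing per-frame box is an
    error because every periodic analysis needs it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "pdb":
        return _read_pdb(path, dt)
    if fmt == "xyz":
        return _read_xyz(path, dt)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _assemble(frames: list[dict], boxes: list, dt: float) -> TwoHelixTrajectory:
    first = frames[0]
    for fi, fr in enumerate(frames):
        for key in ("A", "B", "L"):
            if len(fr[key]["xyz"]) != len(first[key]["xyz"]):
                raise TrajectoryFormatError(
                    f"frame {fi}: atom count mismatch in chain {key} "
                    f"({len(fr[key]['xyz'])} vs {len(first[key]['xyz'])})")
    coords_a = np.array([fr["A"]["xyz"] for fr in frames], dtype=float)
    coords_b = np.array([fr["B"]["xyz"] for fr in frames], dtype=float)
    if coords_a.size == 0 or coords_b.size == 0:
        raise TrajectoryFormatError("both helix chains A and B are required")
    lipids = leaflet = lipid_names = eweight = None
    if len(first["L"]["xyz"]):
        lipids = np.array([fr["L"]["xyz"] for fr in frames], dtype=float)
        leaflet = np.array(first["L"]["leaflet"])
        lipid_names = np.array(first["L"]["names"])
        eweight = np.array(first["L"]["weight"], dtype=float)
    return TwoHelixTrajectory(
        coords_a=coords_a, coords_b=coords_b,
        resids_a=np.array(first["A"]["resids"], dtype=int),
        resids_b=np.array(first["B"]["resids"], dtype=int),
        names_a=np.array(first["A"]["names"]),
        names_b=np.array(first["B"]["names"]),
        box=np.array(boxes, dtype=float),
        lipids=lipids, lipid_names=lipid_names, leaflet=leaflet,
        electron_weight=eweight, dt=dt,
    )


def _new_frame() -> dict:
    return {k: {"xyz": [], "resids": [], "names": [], "leaflet": [],
                "weight": []} for k in ("A", "B", "L")}


def _read_pdb(path: Path, dt: float | None) -> TwoHelixTrajectory:
    frames: list[dict] = []
    boxes: list = []
    box = None
    current = None
    file_dt = 1.0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        rec = line[:6]
        if line.startswith("REMARK   6 DT_NS"):
            file_dt = float(line.split()[-1])
        elif rec == "CRYST1":
            box = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
        elif rec.startswith("MODEL"):
            current = _new_frame()
        elif rec == "ENDMDL":
            if current is None:
                raise TrajectoryFormatError(f"line {lineno}: ENDMDL without MODEL")
            if box is None:
                raise TrajectoryFormatError(
                    f"frame {len(frames)}: no CRYST1 box; periodic analyses require it")
            frames.append(current)
            boxes.append(box)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:  # single-frame PDB without MODEL records
                current = _new_frame()
            chain = line[21]
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                resid = int(line[22:26])
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"frame {len(frames)}, line {lineno}: "
                    f"unparsable ATOM record ({exc})") from exc
            name = line[12:16].strip()
            resname = line[17:21].strip()
            if chain in ("A", "B"):
                current[chain]["xyz"].append(xyz)
                current[chain]["resids"].append(resid)
                current[chain]["names"].append(name)
            elif chain == "L":
                current["L"]["xyz"].append(xyz)
                current["L"]["names"].append(name)
                current["L"]["leaflet"].append(
                    _RESNAME_LEAFLET.get(resname, "upper"))
                current["L"]["weight"].append(bfac)
            else:
                raise TrajectoryFormatError(
                    f"frame {len(frames)}, line {lineno}: "
                    f"unknown chain {chain!r} (expected A, B or L)")
    if current is not None and current["A"]["xyz"]:
        if box is None:
            raise TrajectoryFormatError(
                "no CRYST1 box found; periodic analyses require it")
        frames.append(current)
        boxes.append(box)
    if not frames:
        raise TrajectoryFormatError("no frames found")
    return _assemble(frames, boxes, dt if dt is not None else file_dt)


def _read_xyz(path: Path, dt: float | None) -> TwoHelixTrajectory:
    lines = path.read_text().splitlines()
    frames: list[dict] = []
    boxes: list = []
    file_dt = 1.0
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {len(frames)}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1].split()
        if len(comment) < 4 or comment[0] != "box":
            raise TrajectoryFormatError(
                f"frame {len(frames)}: comment line must start with 'box a b c'")
        boxes.append([float(v) for v in comment[1:4]])
        if "dt" in comment:
            file_dt = float(comment[comment.index("dt") + 1])
        current = _new_frame()
        for j in range(n_atoms):
            if i + 2 + j >= len(lines):
                raise TrajectoryFormatError(
                    f"frame {len(frames)}: truncated (expected {n_atoms} atoms)")
            parts = lines[i + 2 + j].split()
            tag, name, resid = parts[0], parts[1], int(parts[2])
            xyz = [float(v) for v in parts[3:6]]
            if tag in ("A", "B"):
                current[tag]["xyz"].append(xyz)
                current[tag]["resids"].append(resid)
                current[tag]["names"].append(name)
            elif tag in ("LUP", "LLO"):
                current["L"]["xyz"].append(xyz)
                current["L"]["names"].append(name)
                current["L"]["leaflet"].append("upper" if tag == "LUP" else "lower")
                current["L"]["weight"].append(float(parts[6]) if len(parts) > 6 else 0.0)
            else:
                raise TrajectoryFormatError(
                    f"frame {len(frames)}: unknown particle tag {tag!r}")
        frames.append(current)
        i += 2 + n_atoms
    if not frames:
        raise TrajectoryFormatError("no frames found")
    return _assemble(frames, boxes, dt if dt is not None else file_dt)
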
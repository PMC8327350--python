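"""Construct sequences and ideal alpha-helix geometry.

The two transmembrane constructs analysed throughout the package are the
p75 neurotrophin receptor TMD (residues 245-284) and the TrkA TMD
(residues 410-447), numbered as in the full-length receptors.  The leading
expression methionine of each construct is not part of the numbered
sequence and is dropped.
"""

from __future__ import annotations

import numpy as np

P75_SEQUENCE = "TRGTTDNLIPVYCSILAAVVVGLVAYIAFKRWNSSKQNKQ"
P75_START = 245

TRKA_SEQUENCE = "KKDETPFGVSVAVGLAVFACLFLSTLLLVLNKAGRRNK"
TRKA_START = 410

# Ideal alpha-helix parameters
HELIX_RISE = 1.5  # A per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS_BB = 2.3  # A, backbone-bead radius from the axis
HELIX_RADIUS_SC = 4.3  # A, side-chain-bead radius from the axis


def residue_one_letter(sequence: str, start: int, resid: int) -> str:
    """One-letter code of residue ``resid`` in a construct numbered from ``start``."""
    idx = resid - start
    if not 0 <= idx < len(sequence):
        raise ValueError(f"residue {resid} outside construct range "
                         f"{start}-{start + len(sequence) - 1}")
    return sequence[idx]


def residue_phase(resid: int, start: int) -> float:
    """Azimuthal phase (degrees, [0, 360)) of a residue on an ideal helix.

    Phase zero is assigned to the first residue of the construct; each
    following residue advances by the helical twist.
    """
    return ((resid - start) * HELIX_TWIST) % 360.0


def build_ideal_helix(
    sequence: str,
    start: int,
    *,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius_bb: float = HELIX_RADIUS_BB,
    radius_sc: float = HELIX_RADIUS_SC,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a straight ideal helix along +z, centred at the origin.

    Each residue carries two beads: a backbone bead ``BB`` at ``radius_bb``
    from the axis and a side-chain reference bead ``SC`` at ``radius_sc``,
    both at the residue's azimuthal phase.

    Returns
    -------
    coords : (2n, 3) float array, A
    resids : (2n,) int array
    names : (2n,) str array, alternating ``BB``/``SC``
    """
    n = len(sequence)
    resnum = np.arange(n)
    phase = np.deg2rad(resnum * twist)
    z = resnum * rise
    z = z - z.mean()

    coords = np.empty((2 * n, 3))
    for j, radius in enumerate((radius_bb, radius_sc)):
        coords[j::2, 0] = radius * np.cos(phase)
        coords[j::2, 1] = radius * np.sin(phase)
        coords[j::2, 2] = z
    resids = np.repeat(np.arange(start, start + n), 2)
    names = np.tile(np.array(["BB", "SC"]), n)
    return coords, resids, names
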
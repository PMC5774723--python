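"""Base-flipping pseudo-dihedral angle and intra/extra-helical classification.

The flip state of a nucleotide is monitored with a four-point pseudo-
dihedral: (i) centre of mass of the flipping nucleobase heavy atoms,
(ii) COM of the flipping residue's phosphate group {P, OP1, OP2},
(iii) COM of the 3'-neighbour's phosphate group, (iv) COM of the base
heavy atoms of the reference base pairs flanking the analysed nucleotide.
An intra-helical base sits roughly in (-50, +50) deg; a flipped-out base
close to +-180 deg.  Negative angles face the major groove, positive the
minor groove.

Flanking pairs are taken from the declared reference structure (not
re-detected per frame) so the angle stays well defined when neighbours
transiently unpair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constructs import RnaConstruct
from .geometry import BASE_HEAVY_ATOMS
from .trajectory import Topology, Trajectory

__all__ = [
    "ATOMIC_MASSES",
    "FlipGeometry",
    "FlipAngleSeries",
    "flip_geometry",
    "pseudo_dihedral",
    "dihedral",
    "classify_flip",
    "flip_angle_series",
    "flip_timeseries_report",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}

IN_THRESHOLD = 50.0    # |angle| < 50 deg  -> intra-helical
OUT_THRESHOLD = 140.0  # |angle| >= 140 deg -> extra-helical

PHOSPHATE_ATOMS = ("P", "OP1", "OP2")


def _com(frame: np.ndarray, idx: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses[idx]
    return (frame[idx] * w[:, None]).sum(axis=0) / w.sum()


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (deg) of four points, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass(frozen=True)
class FlipGeometry:
    """Atom index sets defining the four pseudo-dihedral points of a residue."""

    residue: str
    base_atoms: np.ndarray
    own_phosphate: np.ndarray
    next_phosphate: np.ndarray
    flank_atoms: np.ndarray


def _phosphate_indices(top: Topology, ridx: int) -> np.ndarray:
    atoms = top.residue_atoms(ridx)
    sel = [a for a in atoms if str(top.names[a]) in PHOSPHATE_ATOMS]
    return np.array(sel, dtype=int)


def _base_indices(top: Topology, ridx: int) -> np.ndarray:
    rname = str(top.res_names[ridx])
    wanted = BASE_HEAVY_ATOMS[rname]
    atoms = top.residue_atoms(ridx)
    return np.array([a for a in atoms if str(top.names[a]) in wanted], dtype=int)


def flip_geometry(
    top: Topology, construct: RnaConstruct, residue: str
) -> FlipGeometry:
    """Resolve the four pseudo-dihedral point definitions for ``residue``.

    The 3'-neighbour is the next position on the residue's own strand; the
    flanking pairs are the nearest reference pairs on either side of the
    residue along its strand.  Raises ``ValueError`` (naming the residue)
    when a phosphate or a flanking pair is missing.
    """
    ridx = top.residue_index(residue)
    chain = str(top.res_chains[ridx])
    strand = construct.strandA if chain == "A" else construct.strandB
    labels = {strand.label(p): p for p in range(1, len(strand) + 1)}
    if residue not in labels:
        raise ValueError(f"residue {residue!r} not on construct strand {chain}")
    pos = labels[residue]
    if pos + 1 > len(strand):
        raise ValueError(f"residue {residue!r} has no 3' neighbour")
    own_p = _phosphate_indices(top, ridx)
    next_label = strand.label(pos + 1)
    next_p = _phosphate_indices(top, top.residue_index(next_label))
    if len(own_p) == 0 or len(next_p) == 0:
        raise ValueError(f"residue {residue!r}: missing phosphate group")

    paired = {("A", i) for i, _ in construct.reference_pairs} | {
        ("B", j) for _, j in construct.reference_pairs
    }
    pair_of_a = dict(construct.reference_pairs)
    pair_of_b = {j: i for i, j in construct.reference_pairs}

    def nearest_pair(direction: int) -> tuple[int, int]:
        p = pos + direction
        while 1 <= p <= len(strand):
            if (chain, p) in paired:
                if chain == "A":
                    return (p, pair_of_a[p])
                return (pair_of_b[p], p)
            p += direction
        raise ValueError(f"residue {residue!r}: no flanking reference pair "
                         f"on the {'3' if direction > 0 else '5'}' side")

    flank = []
    for (i, j) in (nearest_pair(-1), nearest_pair(+1)):
        la = construct.strandA.label(i)
        lb = construct.strandB.label(j)
        flank.extend(_base_indices(top, top.residue_index(la)))
        flank.extend(_base_indices(top, top.residue_index(lb)))
    return FlipGeometry(
        residue=residue,
        base_atoms=_base_indices(top, ridx),
        own_phosphate=own_p,
        next_phosphate=next_p,
        flank_atoms=np.array(flank, dtype=int),
    )


def pseudo_dihedral(
    top: Topology,
    frame: np.ndarray,
    geometry: FlipGeometry,
    masses: np.ndarray | None = None,
) -> float:
    """Pseudo-dihedral flip angle (deg) of one residue in one frame."""
    if masses is None:
        masses = np.array([ATOMIC_MASSES[e] for e in top.elements])
    p0 = _com(frame, geometry.base_atoms, masses)
    p1 = _com(frame, geometry.own_phosphate, masses)
    p2 = _com(frame, geometry.next_phosphate, masses)
    p3 = _com(frame, geometry.flank_atoms, masses)
    return dihedral(p0, p1, p2, p3)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

@dataclass
class FlipAngleSeries:
    residue: str
    angles: np.ndarray            # deg, (-180, 180]
    states: np.ndarray            # "in" / "out" / "intermediate"
    grooves: np.ndarray           # "major" / "minor" / "n/a"

    @property
    def fraction_out(self) -> float:
        return float(np.mean(self.states == "out"))

    @property
    def fraction_in(self) -> float:
        return float(np.mean(self.states == "in"))


def classify_flip(
    angles: np.ndarray,
    in_threshold: float = IN_THRESHOLD,
    out_threshold: float = OUT_THRESHOLD,
    residue: str = "",
) -> FlipAngleSeries:
    """Classify per-frame flip angles into in/intermediate/out states.

    ``in``:  |angle| < in_threshold; ``out``: |angle| >= out_threshold;
    anything else is ``intermediate``.  Groove orientation: angles in
    (-180, 0) face the major groove, (0, 180) the minor groove; it is only
    reported for non-"in" states.
    """
    a = np.asarray(angles, dtype=float)
    states = np.where(
        np.abs(a) < in_threshold,
        "in",
        np.where(np.abs(a) >= out_threshold, "out", "intermediate"),
    )
    grooves = np.where(states == "in", "n/a", np.where(a < 0, "major", "minor"))
    return FlipAngleSeries(residue=residue, angles=a, states=states,
                           grooves=grooves)


def flip_angle_series(
    traj: Trajectory,
    construct: RnaConstruct,
    residue: str,
    in_threshold: float = IN_THRESHOLD,
    out_threshold: float = OUT_THRESHOLD,
) -> FlipAngleSeries:
    """Per-frame flip angle + state classification for one residue."""
    geom = flip_geometry(traj.topology, construct, residue)
    masses = np.array([ATOMIC_MASSES[e] for e in traj.topology.elements])
    angles = np.array(
        [
            pseudo_dihedral(traj.topology, traj.coords[f], geom, masses)
            for f in range(traj.n_frames)
        ]
    )
    return classify_flip(angles, in_threshold, out_threshold, residue=residue)


def flip_timeseries_report(
    traj: Trajectory, construct: RnaConstruct, residues: list[str]
) -> pd.DataFrame:
    """Long-format (frame, residue, angle_deg, state, groove) table."""
    rows = []
    for residue in residues:
        series = flip_angle_series(traj, construct, residue)
        for f in range(traj.n_frames):
            rows.append(
                {
                    "frame": f,
                    "residue": residue,
                    "angle_deg": series.angles[f],
                    "state": series.states[f],
                    "groove": series.grooves[f],
                }
            )
    return pd.DataFrame(rows)
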
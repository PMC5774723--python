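"""Hydrogen-bond detection and base-pair edge classification.

Criteria: donor-acceptor distance <= 3.5 A and acceptor-hydrogen-donor
angle >= 150 deg.  Detected bonds between two nucleotides are mapped onto
the three hydrogen-bonding faces of each base (Watson-Crick, Hoogsteen and
sugar edges, Leontis-Westhof style); a pair in which both partners engage
their Watson-Crick edge is a WC-WC pair regardless of whether it is a
canonical A:U / G:C combination.  When the only bond of a pair runs through
a "corner" atom shared by two edges, the assignment is ambiguous and an
asterisk type (e.g. ``WC*HG``) is reported.

The atom->edge tables are a documented convention (the classification
scheme of trajectory-annotation tools is not standardised); they are
module-level data and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Topology, Trajectory

__all__ = [
    "HBond",
    "BasePairRecord",
    "OccupancyTable",
    "detect_hbonds",
    "hbonds_between",
    "classify_base_pair",
    "classify_frame_pairs",
    "count_wcwc_hbonds",
    "count_nonwcwc_hbonds",
    "hbond_count_series",
    "pair_occupancy",
]

log = logging.getLogger(__name__)

MAX_DA_DISTANCE = 3.5     # A, donor-acceptor
MIN_AHD_ANGLE = 150.0     # deg, acceptor-hydrogen-donor

#: donor heavy atom -> its hydrogens, per residue type ("*" = any type).
DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "U": {"N3": ("H3",)},
    "*": {"O2'": ("HO2'",)},
}

#: acceptor heavy atoms per residue type ("*" = any type; includes backbone).
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("N3", "N7", "O6"),
    "C": ("N3", "O2"),
    "U": ("O2", "O4"),
    "*": ("O2'", "O4'", "O3'", "O5'", "OP1", "OP2"),
}

#: atom -> set of edges it belongs to, per residue type.  Atoms listed under
#: two edges are the "corner" atoms that trigger the asterisk types.
EDGE_TABLE: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N1": ("WC",), "C2": ("WC",), "N6": ("WC", "HG"),
          "N7": ("HG",), "N3": ("Sugar",)},
    "G": {"N1": ("WC",), "O6": ("WC", "HG"), "N2": ("WC", "Sugar"),
          "N7": ("HG",), "N3": ("Sugar",)},
    "C": {"N3": ("WC",), "N4": ("WC", "HG"), "O2": ("WC", "Sugar"),
          "C5": ("HG",)},
    "U": {"N3": ("WC",), "O4": ("WC", "HG"), "O2": ("WC", "Sugar"),
          "C5": ("HG",)},
    "*": {"O2'": ("Sugar",)},
}

_EDGE_ORDER = ("WC", "HG", "Sugar")


@dataclass(frozen=True)
class HBond:
    donor_atom: int        # atom index of the donor heavy atom
    hydrogen_atom: int
    acceptor_atom: int
    donor_residue: int     # residue indices
    acceptor_residue: int
    distance: float        # donor-acceptor, A
    angle: float           # acceptor-hydrogen-donor, deg


@dataclass
class BasePairRecord:
    residue_i: int
    residue_j: int
    label_i: str
    label_j: str
    edge_i: str            # "WC", "HG", "Sugar" or asterisk type "WC*HG"
    edge_j: str
    hbonds: list[HBond] = field(default_factory=list)

    @property
    def is_wcwc(self) -> bool:
        return self.edge_i == "WC" and self.edge_j == "WC"

    @property
    def pair_type(self) -> str:
        return f"{self.edge_i}/{self.edge_j}"

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.residue_i, self.residue_j, self.pair_type)


def _donor_triples(top: Topology) -> list[tuple[int, int, int]]:
    """(donor_atom, hydrogen_atom, residue) triples present in the topology."""
    triples = []
    for ridx in range(top.n_residues):
        atoms = top.residue_atoms(ridx)
        names = {str(top.names[a]): a for a in atoms}
        rname = str(top.res_names[ridx])
        catalogue = {**DONORS.get(rname, {}), **DONORS["*"]}
        for heavy, hydros in catalogue.items():
            if heavy not in names:
                continue
            found = [h for h in hydros if h in names]
            if not found:
                log.warning(
                    "donor %s of residue %s has no hydrogen; skipped",
                    heavy, top.res_labels[ridx],
                )
                continue
            for h in found:
                triples.append((names[heavy], names[h], ridx))
    return triples


def _acceptor_atoms(top: Topology) -> list[tuple[int, int]]:
    out = []
    for ridx in range(top.n_residues):
        atoms = top.residue_atoms(ridx)
        names = {str(top.names[a]): a for a in atoms}
        rname = str(top.res_names[ridx])
        for acc in ACCEPTORS.get(rname, ()) + ACCEPTORS["*"]:
            if acc in names:
                out.append((names[acc], ridx))
    return out


def detect_hbonds(
    topology: Topology,
    frame: np.ndarray,
    max_distance: float = MAX_DA_DISTANCE,
    min_angle: float = MIN_AHD_ANGLE,
) -> list[HBond]:
    """All inter-residue hydrogen bonds of one frame.

    A donor-H...acceptor triple qualifies iff the donor-acceptor distance
    is <= ``max_distance`` and the acceptor-hydrogen-donor angle is
    >= ``min_angle``; intra-residue contacts are excluded.  Donors whose
    hydrogen is absent from the topology are skipped with a warning.
    """
    donors = _donor_triples(topology)
    acceptors = _acceptor_atoms(topology)
    if not donors or not acceptors:
        return []
    acc_idx = np.array([a for a, _ in acceptors])
    acc_res = np.array([r for _, r in acceptors])
    acc_pos = frame[acc_idx]
    bonds: list[HBond] = []
    for d_atom, h_atom, d_res in donors:
        d = frame[d_atom]
        h = frame[h_atom]
        dist = np.linalg.norm(acc_pos - d, axis=1)
        mask = (dist <= max_distance) & (acc_res != d_res)
        for k in np.nonzero(mask)[0]:
            a = acc_pos[k]
            v1 = a - h
            v2 = d - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= min_angle:
                bonds.append(
                    HBond(
                        donor_atom=d_atom,
                        hydrogen_atom=h_atom,
                        acceptor_atom=int(acc_idx[k]),
                        donor_residue=d_res,
                        acceptor_residue=int(acc_res[k]),
                        distance=float(dist[k]),
                        angle=ang,
                    )
                )
    return bonds


def hbonds_between(
    topology: Topology,
    frame: np.ndarray,
    residue_i: int | str,
    residue_j: int | str,
    **kwargs,
) -> list[HBond]:
    """Hydrogen bonds between two specific residues."""
    i = topology.residue_index(residue_i)
    j = topology.residue_index(residue_j)
    return [
        b
        for b in detect_hbonds(topology, frame, **kwargs)
        if {b.donor_residue, b.acceptor_residue} == {i, j}
    ]


# --------------------------------------------------------------------------
# Edge classification
# --------------------------------------------------------------------------

def _edges_of_atom(res_name: str, atom_name: str) -> tuple[str, ...] | None:
    table = EDGE_TABLE.get(res_name, {})
    if atom_name in table:
        return table[atom_name]
    return EDGE_TABLE["*"].get(atom_name)


def _residue_edge(
    bonded: list[tuple[str, str]], n_pair_bonds: int
) -> str | None:
    """Resolve a residue's interacting edge from its bonded (res, atom) list.

    Returns None if no bonded atom maps to an edge (backbone-only contact).
    """
    edge_sets = []
    for res_name, atom_name in bonded:
        edges = _edges_of_atom(res_name, atom_name)
        if edges is not None:
            edge_sets.append(set(edges))
    if not edge_sets:
        return None
    inter = set.intersection(*edge_sets)
    if len(inter) == 1:
        return inter.pop()
    if len(inter) == 2:
        # Corner-atom ambiguity; by convention reported with the asterisk.
        e1, e2 = sorted(inter, key=_EDGE_ORDER.index)
        return f"{e1}*{e2}"
    # Bonds on different edges: majority vote, ties by WC > HG > Sugar.
    votes: dict[str, int] = {}
    for s in edge_sets:
        for e in s:
            votes[e] = votes.get(e, 0) + 1
    return max(votes, key=lambda e: (votes[e], -_EDGE_ORDER.index(e)))


def classify_base_pair(
    topology: Topology,
    frame: np.ndarray,
    residue_i: int | str,
    residue_j: int | str,
    hbonds: list[HBond] | None = None,
) -> BasePairRecord | None:
    """Edge-classified base pair record for residues i, j, or None.

    Only bonds whose two heavy atoms both map to a base edge (base atoms or
    the ribose O2') enter the classification; pairs held together solely by
    backbone phosphate contacts are not base pairs and return None.
    """
    i = topology.residue_index(residue_i)
    j = topology.residue_index(residue_j)
    if i == j:
        raise ValueError("a base pair needs two distinct residues")
    if hbonds is None:
        hbonds = detect_hbonds(topology, frame)
    pair_bonds = [
        b for b in hbonds if {b.donor_residue, b.acceptor_residue} == {i, j}
    ]
    edge_bonds = []
    for b in pair_bonds:
        ends = {}
        for res, atom in (
            (b.donor_residue, b.donor_atom),
            (b.acceptor_residue, b.acceptor_atom),
        ):
            rname = str(topology.res_names[res])
            aname = str(topology.names[atom])
            ends[res] = _edges_of_atom(rname, aname) is not None
        if ends.get(i) and ends.get(j):
            edge_bonds.append(b)
    if not edge_bonds:
        return None
    bonded_i: list[tuple[str, str]] = []
    bonded_j: list[tuple[str, str]] = []
    for b in edge_bonds:
        for res, atom in (
            (b.donor_residue, b.donor_atom),
            (b.acceptor_residue, b.acceptor_atom),
        ):
            entry = (str(topology.res_names[res]), str(topology.names[atom]))
            (bonded_i if res == i else bonded_j).append(entry)
    n = len(edge_bonds)
    edge_i = _residue_edge(bonded_i, n)
    edge_j = _residue_edge(bonded_j, n)
    if edge_i is None or edge_j is None:
        return None
    # The asterisk is only warranted for a genuinely single-bond contact.
    if n > 1:
        edge_i = edge_i.split("*")[0] if "*" in edge_i else edge_i
        edge_j = edge_j.split("*")[0] if "*" in edge_j else edge_j
    return BasePairRecord(
        residue_i=i,
        residue_j=j,
        label_i=str(topology.res_labels[i]),
        label_j=str(topology.res_labels[j]),
        edge_i=edge_i,
        edge_j=edge_j,
        hbonds=edge_bonds,
    )


def classify_frame_pairs(
    topology: Topology, frame: np.ndarray
) -> list[BasePairRecord]:
    """All edge-classified base pairs of one frame (i < j)."""
    hbonds = detect_hbonds(topology, frame)
    pairs = sorted(
        {
            (min(b.donor_residue, b.acceptor_residue),
             max(b.donor_residue, b.acceptor_residue))
            for b in hbonds
        }
    )
    records = []
    for i, j in pairs:
        rec = classify_base_pair(topology, frame, i, j, hbonds=hbonds)
        if rec is not None:
            records.append(rec)
    return records


def count_wcwc_hbonds(
    topology: Topology, frame: np.ndarray,
    pairs: list[BasePairRecord] | None = None,
) -> int:
    """Number of hydrogen bonds in WC-WC pairs of a frame."""
    if pairs is None:
        pairs = classify_frame_pairs(topology, frame)
    return sum(len(p.hbonds) for p in pairs if p.is_wcwc)


def count_nonwcwc_hbonds(
    topology: Topology, frame: np.ndarray,
    pairs: list[BasePairRecord] | None = None,
) -> int:
    """Number of hydrogen bonds in non-WC-WC pairs of a frame."""
    if pairs is None:
        pairs = classify_frame_pairs(topology, frame)
    return sum(len(p.hbonds) for p in pairs if not p.is_wcwc)


def hbond_count_series(traj: Trajectory) -> "pd.DataFrame":
    """Per-frame WC-WC and non-WC-WC hydrogen-bond counts."""
    import pandas as pd

    rows = []
    for f in range(traj.n_frames):
        pairs = classify_frame_pairs(traj.topology, traj.coords[f])
        rows.append(
            {
                "frame": f,
                "wcwc_hbonds": count_wcwc_hbonds(traj.topology, traj.coords[f], pairs),
                "nonwcwc_hbonds": count_nonwcwc_hbonds(
                    traj.topology, traj.coords[f], pairs
                ),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Occupancy
# --------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Fraction of frames in which each (pair, pair-type) classification holds."""

    fractions: dict[tuple[str, str, str], float]   # (label_i, label_j, type)
    n_frames: int
    threshold: float = 0.05

    def reported(self) -> dict[tuple[str, str, str], float]:
        """Entries above the reporting threshold (raw table kept intact)."""
        return {k: v for k, v in self.fractions.items() if v > self.threshold}

    def to_frame(self, reported_only: bool = True) -> "pd.DataFrame":
        import pandas as pd

        data = self.reported() if reported_only else self.fractions
        rows = [
            {
                "residue_i": k[0],
                "residue_j": k[1],
                "pair_type": k[2],
                "occupancy": v,
            }
            for k, v in sorted(data.items())
        ]
        return pd.DataFrame(rows)


def pair_occupancy(traj: Trajectory, threshold: float = 0.05) -> OccupancyTable:
    """Occupancy of every observed (pair, pair-type) over the trajectory."""
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    counts: dict[tuple[str, str, str], int] = {}
    for f in range(traj.n_frames):
        for rec in classify_frame_pairs(traj.topology, traj.coords[f]):
            key = (rec.label_i, rec.label_j, rec.pair_type)
            counts[key] = counts.get(key, 0) + 1
    fractions = {k: v / traj.n_frames for k, v in counts.items()}
    return OccupancyTable(fractions=fractions, n_frames=traj.n_frames,
                          threshold=threshold)
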
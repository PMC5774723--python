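"""Idealized nucleotide geometry and the A-form-like duplex lattice.

The synthetic trajectories analysed by this package are built from rigid
per-nucleotide templates placed on a helical lattice (rise 2.81 A, twist
32.7 deg per step -- A-form-like values).  Base rings are idealized regular
polygons (bond length 1.38 A) with exocyclic heavy atoms and polar
hydrogens at in-plane sp2 positions; the Watson-Crick pairing geometry
(C1'-C1' separation and glycosidic opening angles) was calibrated once so
that every canonical pair satisfies the hydrogen-bond criteria used by the
analysis stage (donor-acceptor <= 3.5 A, acceptor-H-donor angle >= 150 deg)
with the canonical bond count (A:U -> 2, G:C -> 3) and no spurious bonds.

These templates are deliberately *not* a force-field geometry: they are a
deterministic, inspectable scaffold with exactly the structural properties
the trajectory metrics assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable

import numpy as np

from .constructs import RnaConstruct

__all__ = [
    "HelixParams",
    "BASE_TEMPLATES",
    "pair_frame_coords",
    "duplex_layout",
    "build_duplex_atoms",
]

# --------------------------------------------------------------------------
# Tunable geometry constants
# --------------------------------------------------------------------------

#: Ring bond length used for the regular-polygon base rings (A).
RING_BOND = 1.38
#: Glycosidic C1'-N bond length (A).
GLYCOSIDIC_BOND = 1.48

#: Calibrated Watson-Crick pairing geometry: C1'-C1' distance (A), the
#: in-plane opening angle (deg) between the glycosidic bond and the
#: C1'->C1' axis, and an in-plane rotation of the base about its glycosidic
#: nitrogen, separately for purines and pyrimidines.  Calibrated (once, by
#: least squares on the five canonical contacts) so that A:U forms exactly
#: its two and G:C exactly its three hydrogen bonds with donor-acceptor
#: distances of 2.85-2.95 A and acceptor-H-donor angles of 168-174 deg.
C1C1_DISTANCE = 10.2173
LAMBDA_PURINE = 37.0958
LAMBDA_PYRIMIDINE = 95.3678
ROT_PURINE = 19.6561
ROT_PYRIMIDINE = -50.5768

#: Lateral displacement (A) applied to both residues of a non-reference
#: (non canonical) rung so that opposed bases neither clash nor
#: hydrogen-bond in the ideal fixture.
NONCANONICAL_SHIFT = 1.2


@dataclass(frozen=True)
class HelixParams:
    """Helical lattice parameters (defaults are A-form-like)."""

    rise: float = 2.81       # A per step
    twist: float = 32.7      # deg per step


def _rot2(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _ring(n: int, center: np.ndarray, start: np.ndarray, step_deg: float,
          radius: float) -> list[np.ndarray]:
    """Vertices of a regular n-ring starting at ``start`` around ``center``."""
    v0 = start - center
    theta0 = math.degrees(math.atan2(v0[1], v0[0]))
    return [
        center + radius * np.array([
            math.cos(math.radians(theta0 + k * step_deg)),
            math.sin(math.radians(theta0 + k * step_deg)),
        ])
        for k in range(n)
    ]


def _amine_hydrogens(n: np.ndarray, c: np.ndarray, names: tuple[str, str],
                     bond: float = 1.01) -> dict[str, np.ndarray]:
    """Planar NH2 hydrogens at +-60 deg from the C->N extension."""
    u = n - c
    u = u / np.linalg.norm(u)
    return {
        names[0]: n + bond * (_rot2(60.0) @ u),
        names[1]: n + bond * (_rot2(-60.0) @ u),
    }


def _pyrimidine(base: str) -> dict[str, np.ndarray]:
    """Local 2D coordinates: origin at N1, ring center along +x,
    Watson-Crick edge opening toward -y."""
    r = RING_BOND
    center = np.array([r, 0.0])
    n1 = np.array([0.0, 0.0])
    verts = _ring(6, center, n1, 60.0, r)
    atoms = dict(zip(["N1", "C2", "N3", "C4", "C5", "C6"], verts))

    def radial(a: np.ndarray) -> np.ndarray:
        u = a - center
        return u / np.linalg.norm(u)

    atoms["O2"] = atoms["C2"] + 1.23 * radial(atoms["C2"])
    if base == "U":
        atoms["O4"] = atoms["C4"] + 1.23 * radial(atoms["C4"])
        atoms["H3"] = atoms["N3"] + 1.03 * radial(atoms["N3"])
    elif base == "C":
        atoms["N4"] = atoms["C4"] + 1.34 * radial(atoms["C4"])
        atoms.update(_amine_hydrogens(atoms["N4"], atoms["C4"], ("H41", "H42")))
    else:  # pragma: no cover
        raise ValueError(f"not a pyrimidine: {base}")
    return atoms


def _purine(base: str) -> dict[str, np.ndarray]:
    """Local 2D coordinates: origin at N9, five-ring center along +x,
    six-ring (Watson-Crick edge) extending toward -y."""
    r = RING_BOND
    r5 = r / (2.0 * math.sin(math.pi / 5.0))
    center5 = np.array([r5, 0.0])
    n9 = np.array([0.0, 0.0])
    v5 = _ring(5, center5, n9, 72.0, r5)
    atoms = dict(zip(["N9", "C4", "C5", "N7", "C8"], v5))

    # Fuse the six-ring on the C4-C5 edge, extending away from the pentagon.
    mid = 0.5 * (atoms["C4"] + atoms["C5"])
    out = mid - center5
    out = out / np.linalg.norm(out)
    center6 = mid + (r * math.sqrt(3.0) / 2.0) * out
    v0 = atoms["C4"] - center6
    theta0 = math.degrees(math.atan2(v0[1], v0[0]))
    hex_names = ["C4", "C5", "C6", "N1", "C2", "N3"]
    for k, name in enumerate(hex_names):
        ang = math.radians(theta0 - 60.0 * k)
        atoms[name] = center6 + r * np.array([math.cos(ang), math.sin(ang)])

    def radial6(a: np.ndarray) -> np.ndarray:
        u = a - center6
        return u / np.linalg.norm(u)

    if base == "A":
        atoms["N6"] = atoms["C6"] + 1.34 * radial6(atoms["C6"])
        atoms.update(_amine_hydrogens(atoms["N6"], atoms["C6"], ("H61", "H62")))
    elif base == "G":
        atoms["O6"] = atoms["C6"] + 1.23 * radial6(atoms["C6"])
        atoms["N2"] = atoms["C2"] + 1.34 * radial6(atoms["C2"])
        atoms["H1"] = atoms["N1"] + 1.03 * radial6(atoms["N1"])
        atoms.update(_amine_hydrogens(atoms["N2"], atoms["C2"], ("H21", "H22")))
    else:  # pragma: no cover
        raise ValueError(f"not a purine: {base}")
    return atoms


def _rotated(template: dict[str, np.ndarray], deg: float) -> dict[str, np.ndarray]:
    r = _rot2(deg)
    return {k: r @ v for k, v in template.items()}


#: Local in-plane base templates, keyed by residue type (calibration
#: rotation about the glycosidic nitrogen already applied).
BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "A": _rotated(_purine("A"), ROT_PURINE),
    "G": _rotated(_purine("G"), ROT_PURINE),
    "C": _rotated(_pyrimidine("C"), ROT_PYRIMIDINE),
    "U": _rotated(_pyrimidine("U"), ROT_PYRIMIDINE),
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: Base heavy atoms (no hydrogens, no sugar) per residue type.
BASE_HEAVY_ATOMS = {
    b: tuple(n for n in t if not n.startswith("H"))
    for b, t in BASE_TEMPLATES.items()
}

#: Six-membered-ring atoms, used for stacking centroids/normals.
SIX_RING = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


def export_templates(path) -> None:
    """Write the pair-frame template coordinates to a CSV for inspection.

    Columns: base, side, atom, x, y, z (A, pair frame).  The shipped copy
    at ``data/nucleotide_templates.csv`` is regenerated from this function
    and guarded by a test.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["base", "side", "atom", "x", "y", "z"])
        for base in "ACGU":
            for side in (1, 2):
                for atom, xyz in pair_frame_coords(base, side).items():
                    writer.writerow(
                        [base, side, atom] + [f"{v:.6f}" for v in xyz]
                    )


def pair_frame_coords(base: str, side: int) -> dict[str, np.ndarray]:
    """3D coordinates of a nucleobase (+ C1') in the base-pair frame.

    ``side`` 1 is the strand-A side (+y), side 2 the strand-B side (-y);
    side-2 bases are flipped about the pair dyad so that a complementary
    side-1/side-2 pair forms Watson-Crick contacts.  z = 0 for all atoms.
    """
    if side not in (1, 2):
        raise ValueError("side must be 1 or 2")
    lam_deg = LAMBDA_PURINE if base in "AG" else LAMBDA_PYRIMIDINE
    half = C1C1_DISTANCE / 2.0
    sgn = 1.0 if side == 1 else -1.0
    c1 = np.array([0.0, sgn * half, 0.0])
    # In-plane glycosidic direction: partner direction rotated by lambda.
    s, c = math.sin(math.radians(lam_deg)), math.cos(math.radians(lam_deg))
    e1 = np.array([s, -sgn * c, 0.0])
    normal = np.array([0.0, 0.0, sgn * 1.0])
    e2 = np.cross(normal, e1)
    n_pos = c1 + GLYCOSIDIC_BOND * e1
    out = {"C1'": c1}
    for name, (x, y) in ((k, v) for k, v in BASE_TEMPLATES[base].items()):
        out[name] = n_pos + x * e1 + y * e2
    return out


# --------------------------------------------------------------------------
# Duplex layout: rungs of the helical ladder
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Rung:
    """One step of the helical ladder; posA/posB are 1-based strand
    positions (None for a bulge on the other strand)."""

    index: int
    posA: int | None
    posB: int | None
    canonical: bool


def duplex_layout(construct: RnaConstruct) -> list[Rung]:
    """Merge the two strands into an ordered list of helical rungs.

    Walks strand A 5'->3' and strand B 3'->5', anchoring on the declared
    reference pairs; unpaired stretches between anchors are zipped into
    single- or double-residue bulge rungs.
    """
    pairs = sorted(construct.reference_pairs)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            raise ValueError("reference pairs are not a nested antiparallel ladder")
    rungs: list[tuple[int | None, int | None, bool]] = []
    prevA, prevB = 0, len(construct.strandB) + 1

    def fill_gap(gapA: Iterable[int], gapB: Iterable[int]) -> None:
        for a, b in zip_longest(gapA, gapB):
            rungs.append((a, b, False))

    for (i, j) in pairs:
        fill_gap(range(prevA + 1, i), range(prevB - 1, j, -1))
        rungs.append((i, j, True))
        prevA, prevB = i, j
    fill_gap(range(prevA + 1, len(construct.strandA) + 1), range(prevB - 1, 0, -1))
    return [Rung(k, a, b, c) for k, (a, b, c) in enumerate(rungs)]


# --------------------------------------------------------------------------
# Atom building
# --------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _element(atom_name: str) -> str:
    return atom_name.lstrip("0123456789")[0]


@dataclass
class _ResidueAtoms:
    chain: str           # "A" or "B"
    position: int        # 1-based position on its strand
    resname: str
    label: str           # E. coli style label, e.g. "A1493"
    number: int          # numeric residue id for PDB output
    names: list[str]
    coords: list[np.ndarray]


def build_duplex_atoms(
    construct: RnaConstruct,
    helix: HelixParams = HelixParams(),
) -> list[_ResidueAtoms]:
    """Place every nucleotide of the construct on the helical lattice.

    Residues are returned in strand order (all of strand A 5'->3', then all
    of strand B 5'->3').  Each residue carries base heavy atoms, polar
    hydrogens and a pseudo-ribose/phosphate backbone; 5'-terminal residues
    have no phosphate group.
    """
    layout = duplex_layout(construct)
    rung_of: dict[tuple[str, int], Rung] = {}
    for rung in layout:
        if rung.posA is not None:
            rung_of[("A", rung.posA)] = rung
        if rung.posB is not None:
            rung_of[("B", rung.posB)] = rung

    residues: list[_ResidueAtoms] = []
    base_placement: dict[tuple[str, int], dict[str, np.ndarray]] = {}

    for chain, strand in (("A", construct.strandA), ("B", construct.strandB)):
        for pos in range(1, len(strand) + 1):
            rung = rung_of[(chain, pos)]
            base = strand.sequence[pos - 1]
            side = 1 if chain == "A" else 2
            local = pair_frame_coords(base, side)
            shift = np.zeros(3)
            if not rung.canonical and rung.posA is not None and rung.posB is not None:
                sgn = 1.0 if side == 1 else -1.0
                shift = np.array([0.0, sgn * NONCANONICAL_SHIFT, 0.0])
            rot = _rot_z(rung.index * helix.twist)
            trans = np.array([0.0, 0.0, rung.index * helix.rise])
            placed = {
                name: rot @ (xyz + shift) + trans for name, xyz in local.items()
            }
            base_placement[(chain, pos)] = placed
            label = strand.label(pos)
            number = int("".join(ch for ch in label if ch.isdigit()) or pos)
            residues.append(
                _ResidueAtoms(chain, pos, base, label, number, [], [])
            )

    # Backbone pass: needs the C1' of the 5' neighbour for phosphate placement.
    res_by_key = {(r.chain, r.position): r for r in residues}
    for res in residues:
        placed = base_placement[(res.chain, res.position)]
        c1 = placed["C1'"]
        prev_key = (res.chain, res.position - 1)
        backbone = _backbone_atoms(
            c1,
            base_placement[prev_key]["C1'"] if prev_key in res_by_key else None,
            strand_sign=1.0 if res.chain == "A" else -1.0,
        )
        # PDB-conventional ordering: backbone first, then base, then hydrogens.
        heavy_base = [n for n in placed if n != "C1'" and not n.startswith("H")]
        hydro = [n for n in placed if n.startswith("H")]
        for name in backbone["order"]:
            res.names.append(name)
            res.coords.append(backbone[name])
        res.names.append("C1'")
        res.coords.append(c1)
        for name in heavy_base + hydro:
            res.names.append(name)
            res.coords.append(placed[name])
        res.names.append("HO2'")
        res.coords.append(backbone["HO2'"])
    return residues


def _backbone_atoms(
    c1: np.ndarray, c1_prev: np.ndarray | None, strand_sign: float
) -> dict:
    """Pseudo-ribose + phosphate placed in a radial/tangential/axial frame.

    The geometry is schematic: the ribose sits outward of the base, the 2'-OH
    points away from the helix interior, and the phosphate bridges the C1'
    atoms of consecutive residues at a larger radius.  Only connectivity-level
    plausibility is needed by the analyses (phosphate centres of mass for the
    flip pseudo-dihedral, O2' donors for sugar-edge contacts).
    """
    axis_r = np.array([c1[0], c1[1], 0.0])
    u = axis_r / np.linalg.norm(axis_r)          # radial, away from helix axis
    z = np.array([0.0, 0.0, 1.0])
    t = strand_sign * np.cross(z, u)             # tangential, toward 3' side
    d = strand_sign * z                          # local 3' direction

    def frame(ru: float, rt: float, rd: float) -> np.ndarray:
        return ru * u + rt * t + rd * d

    atoms: dict[str, np.ndarray] = {}
    atoms["O4'"] = c1 + frame(1.0, -0.4, 0.9)
    atoms["C2'"] = c1 + frame(1.1, 1.0, 0.2)
    atoms["O2'"] = atoms["C2'"] + frame(1.05, -0.55, -0.75)
    atoms["HO2'"] = atoms["O2'"] + 0.96 * u
    atoms["C3'"] = c1 + frame(2.0, 0.6, 0.9)
    atoms["C4'"] = c1 + frame(2.2, -0.2, 1.5)
    atoms["C5'"] = atoms["C4'"] + 1.52 * _unit(frame(1.0, -0.2, 0.8))
    order = ["O4'", "C2'", "O2'", "C3'", "C4'", "C5'"]
    if c1_prev is not None:
        mid = 0.5 * (c1 + c1_prev)
        mid_r = np.array([mid[0], mid[1], 0.0])
        u_mid = mid_r / np.linalg.norm(mid_r)
        p = mid + 2.8 * u_mid
        atoms["P"] = p
        atoms["OP1"] = p + 1.48 * _unit(u_mid + 0.7 * z)
        atoms["OP2"] = p + 1.48 * _unit(u_mid - 0.7 * z)
        atoms["O5'"] = p + 1.6 * _unit(atoms["C5'"] - p)
        order = ["P", "OP1", "OP2", "O5'"] + order
    else:
        atoms["O5'"] = atoms["C5'"] + 1.42 * _unit(frame(0.6, 0.0, 0.8))
        order = ["O5'"] + order
    atoms["O3'"] = atoms["C3'"] + 1.4 * _unit(frame(0.5, 0.3, 1.0))
    order = order + ["O3'"]
    atoms["order"] = order
    return atoms


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
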
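"""Nucleobase stacking detection and interaction energetics.

Stacking energy between two nucleobases is the sum of the Coulomb and
Lennard-Jones (van der Waals) terms over all heavy atoms of the two bases
(no sugar, no phosphate, no hydrogens, no cutoff):

    E_coul = sum_ij k q_i q_j / r_ij            k = 332.0636 kcal A / (mol e^2)
    E_vdw  = sum_ij eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ]

with Lorentz-Berthelot-style combining, eps_ij = sqrt(eps_i eps_j) and
Rmin_ij = Rmin_i/2 + Rmin_j/2.  Partial charges and LJ parameters ship as
an Amber-94-lineage table (``data/base_charges.csv``) and can be replaced
by the user.

Stacked pairs are detected geometrically (six-membered-ring centroid
distance and interplanar angle); hydrogen-bonded partners of the same
frame are excluded so base pairs are not double-counted as stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import BASE_HEAVY_ATOMS, SIX_RING
from .trajectory import Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "ForceFieldParams",
    "StackEnergy",
    "load_ff_params",
    "detect_stacked",
    "stack_energy",
    "frame_stacking_total",
    "stacking_timeseries",
    "region_average",
]

COULOMB_CONSTANT = 332.0636          # kcal A mol^-1 e^-2
CENTROID_CUTOFF = 4.5                # A
PLANE_ANGLE_CUTOFF = 30.0            # deg


@dataclass(frozen=True)
class ForceFieldParams:
    """(residue type, atom name) -> (charge e, LJ eps kcal/mol, Rmin/2 A)."""

    charges: dict[tuple[str, str], float]
    epsilons: dict[tuple[str, str], float]
    rmin_half: dict[tuple[str, str], float]

    def require(self, restype: str, atom: str) -> tuple[float, float, float]:
        key = (restype, atom)
        if key not in self.charges:
            raise KeyError(
                f"no force-field parameters for atom {atom!r} of residue "
                f"type {restype!r}"
            )
        return self.charges[key], self.epsilons[key], self.rmin_half[key]

    def validate(self) -> None:
        """Every nucleobase heavy atom of A/C/G/U must have an entry."""
        for restype, atoms in BASE_HEAVY_ATOMS.items():
            for atom in atoms:
                self.require(restype, atom)


def load_ff_params(path: str | Path | None = None) -> ForceFieldParams:
    """Load the parameter table (CSV: restype, atom, charge, epsilon, rmin_half)."""
    if path is None:
        source = resources.files("asitekit.data").joinpath("base_charges.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    charges, eps, rmh = {}, {}, {}
    for row in df.itertuples(index=False):
        key = (str(row.restype), str(row.atom))
        charges[key] = float(row.charge)
        eps[key] = float(row.epsilon)
        rmh[key] = float(row.rmin_half)
    params = ForceFieldParams(charges, eps, rmh)
    params.validate()
    return params


@dataclass(frozen=True)
class StackEnergy:
    residue_i: str
    residue_j: str
    coulomb: float       # kcal/mol
    vdw: float           # kcal/mol

    @property
    def total(self) -> float:
        return self.coulomb + self.vdw


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def _ring_geometry(
    top: Topology, frame: np.ndarray, ridx: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the six-membered base ring."""
    rname = str(top.res_names[ridx])
    atoms = top.residue_atoms(ridx)
    names = {str(top.names[a]): a for a in atoms}
    try:
        idx = [names[n] for n in SIX_RING[rname]]
    except KeyError as err:
        raise ValueError(
            f"residue {top.res_labels[ridx]}: ring atom {err} missing"
        )
    pts = frame[idx]
    cen = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - cen)
    return cen, vt[2]


def detect_stacked(
    top: Topology,
    frame: np.ndarray,
    centroid_cutoff: float = CENTROID_CUTOFF,
    plane_angle_cutoff: float = PLANE_ANGLE_CUTOFF,
    exclude_paired: bool = True,
) -> list[tuple[int, int]]:
    """Residue index pairs (i < j) whose bases are stacked in ``frame``.

    Criteria: six-ring centroid distance <= ``centroid_cutoff`` and
    interplanar angle <= ``plane_angle_cutoff``.  With ``exclude_paired``
    (default) residue pairs that form a hydrogen-bonded base pair in this
    frame are excluded.
    """
    n = top.n_residues
    cens = np.empty((n, 3))
    norms = np.empty((n, 3))
    for r in range(n):
        cens[r], norms[r] = _ring_geometry(top, frame, r)
    paired: set[tuple[int, int]] = set()
    if exclude_paired:
        from .hbonds import classify_frame_pairs

        for rec in classify_frame_pairs(top, frame):
            paired.add((rec.residue_i, rec.residue_j))
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in paired:
                continue
            if np.linalg.norm(cens[i] - cens[j]) > centroid_cutoff:
                continue
            cosang = abs(float(np.dot(norms[i], norms[j])))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= plane_angle_cutoff:
                out.append((i, j))
    return out


# --------------------------------------------------------------------------
# Energetics
# --------------------------------------------------------------------------

def pairwise_energy(
    q1: np.ndarray, eps1: np.ndarray, rmin_half1: np.ndarray, x1: np.ndarray,
    q2: np.ndarray, eps2: np.ndarray, rmin_half2: np.ndarray, x2: np.ndarray,
) -> tuple[float, float]:
    """(coulomb, vdw) between two atom groups, no cutoff.

    eps_ij = sqrt(eps_i eps_j); Rmin_ij = Rmin_i/2 + Rmin_j/2; the LJ term
    is eps_ij [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6], minimised (-eps_ij) at
    r = Rmin_ij.
    """
    d = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=-1)
    coulomb = float(COULOMB_CONSTANT * np.sum(np.outer(q1, q2) / d))
    eps = np.sqrt(np.outer(eps1, eps2))
    rmin = rmin_half1[:, None] + rmin_half2[None, :]
    ratio6 = (rmin / d) ** 6
    vdw = float(np.sum(eps * (ratio6**2 - 2.0 * ratio6)))
    return coulomb, vdw


def stack_energy(
    top: Topology,
    frame: np.ndarray,
    pair: tuple[int, int],
    params: ForceFieldParams,
) -> StackEnergy:
    """Coulomb + van der Waals energy over the heavy base atoms of a pair."""
    i, j = pair
    qi, ei, ri, xi = _base_params(top, frame, i, params)
    qj, ej, rj, xj = _base_params(top, frame, j, params)
    coulomb, vdw = pairwise_energy(qi, ei, ri, xi, qj, ej, rj, xj)
    return StackEnergy(
        residue_i=str(top.res_labels[i]),
        residue_j=str(top.res_labels[j]),
        coulomb=coulomb,
        vdw=vdw,
    )


def _base_params(top, frame, ridx, params):
    rname = str(top.res_names[ridx])
    atoms = top.residue_atoms(ridx)
    names = {str(top.names[a]): a for a in atoms}
    q, e, r, x = [], [], [], []
    for atom in BASE_HEAVY_ATOMS[rname]:
        if atom not in names:
            raise KeyError(
                f"residue {top.res_labels[ridx]}: base atom {atom!r} missing"
            )
        qq, ee, rr = params.require(rname, atom)
        q.append(qq)
        e.append(ee)
        r.append(rr)
        x.append(frame[names[atom]])
    return np.array(q), np.array(e), np.array(r), np.array(x)


def frame_stacking_total(
    top: Topology,
    frame: np.ndarray,
    params: ForceFieldParams,
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[float, float]:
    """(coulomb, vdw) summed over all stacked pairs of a frame (each once)."""
    if pairs is None:
        pairs = detect_stacked(top, frame)
    c = v = 0.0
    for pair in pairs:
        e = stack_energy(top, frame, pair, params)
        c += e.coulomb
        v += e.vdw
    return c, v


def stacking_timeseries(
    traj: Trajectory, params: ForceFieldParams, window: int = 1
) -> pd.DataFrame:
    """Windowed means of the per-frame total stacking energy.

    ``window`` = 1 returns the raw per-frame series; larger windows return
    contiguous block averages (the trailing partial window is dropped).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for f in range(traj.n_frames):
        c, v = frame_stacking_total(traj.topology, traj.coords[f], params)
        rows.append((c, v, c + v))
    raw = np.array(rows)
    nwin = traj.n_frames // window
    out = []
    for w in range(nwin):
        block = raw[w * window:(w + 1) * window]
        m = block.mean(axis=0)
        out.append(
            {
                "window": w,
                "frame_start": w * window,
                "coulomb": m[0],
                "vdw": m[1],
                "total": m[2],
            }
        )
    return pd.DataFrame(out)


def region_average(
    traj: Trajectory,
    residues: list[str],
    params: ForceFieldParams,
) -> dict:
    """Average stacking interaction per nucleotide of a region.

    Per frame, each stacked pair's energy is split 50/50 between its two
    residues; the region value is the sum of the attributions of region
    residues divided by the region size.  Pairs with both partners inside
    the region therefore contribute exactly once to the region sum.
    Returns per-region mean and std (over frames) for the Coulomb, vdW and
    total terms, plus the per-residue table.
    """
    top = traj.topology
    ridx = [top.residue_index(r) for r in residues]
    region = set(ridx)
    per_frame = np.zeros((traj.n_frames, 3))
    per_res = {r: np.zeros((traj.n_frames, 3)) for r in residues}
    label_of = {top.residue_index(r): r for r in residues}
    for f in range(traj.n_frames):
        pairs = detect_stacked(top, traj.coords[f])
        for (i, j) in pairs:
            if i not in region and j not in region:
                continue
            e = stack_energy(top, traj.coords[f], (i, j), params)
            vec = 0.5 * np.array([e.coulomb, e.vdw, e.total])
            for r in (i, j):
                if r in region:
                    per_frame[f] += vec
                    per_res[label_of[r]][f] += vec
    per_frame /= len(residues)
    terms = ("coulomb", "vdw", "total")
    return {
        "mean": dict(zip(terms, per_frame.mean(axis=0))),
        "std": dict(zip(terms, per_frame.std(axis=0))),
        "per_residue": {
            r: dict(zip(terms, v.mean(axis=0))) for r, v in per_res.items()
        },
        "n_frames": traj.n_frames,
    }
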
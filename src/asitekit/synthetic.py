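"""Seeded synthetic-data generators for all downstream analyses.

Three generators stand in for the raw data the analyses consume:

* duplex trajectories -- an ideal A-form-like duplex built from rigid
  nucleotide templates, with scheduled intra/extra-helical base flips and
  isotropic Gaussian thermal jitter, written/read as multi-model PDB;
* UV melting curves -- the exact two-state transition with sloping linear
  baselines plus optional Gaussian noise;
* ITC titrations -- the exact 1:1 binding isotherm with displacement
  dilution bookkeeping, a constant dilution heat and optional noise.

Every generator is bit-reproducible for a fixed seed, and the noiseless
outputs satisfy the corresponding analysis contracts exactly (canonical
pairs show their canonical hydrogen bonds, scheduled flips hit the target
pseudo-dihedral exactly, fitters recover the generating parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constructs import RnaConstruct
from .geometry import HelixParams, build_duplex_atoms
from .flipping import flip_geometry, pseudo_dihedral, ATOMIC_MASSES
from .thermo import (
    ItcSeries,
    MeltingCurve,
    itc_injection_heats,
    melting_absorbance,
)
from .trajectory import Topology, Trajectory

__all__ = [
    "FlipSchedule",
    "MeltSimParams",
    "ItcSimParams",
    "generate_duplex_frame",
    "generate_flip_trajectory",
    "generate_melting_curve",
    "generate_itc_series",
]

#: Target |pseudo-dihedral| (deg) for scheduled extra-helical poses.
FLIP_TARGET = 165.0


# --------------------------------------------------------------------------
# Trajectory generators
# --------------------------------------------------------------------------

def generate_duplex_frame(
    construct: RnaConstruct, helix: HelixParams = HelixParams()
) -> Trajectory:
    """Single-frame ideal duplex trajectory for ``construct``.

    Every reference pair satisfies the hydrogen-bond criteria with its
    canonical bond count; bulge residues are placed intra-helically.
    Deterministic: repeated calls give identical coordinates.
    """
    residues = build_duplex_atoms(construct, helix)
    names: list[str] = []
    elements: list[str] = []
    res_index: list[int] = []
    coords: list[np.ndarray] = []
    res_names, res_chains, res_numbers, res_labels = [], [], [], []
    for ridx, res in enumerate(residues):
        res_names.append(res.resname)
        res_chains.append(res.chain)
        res_numbers.append(res.number)
        res_labels.append(res.label)
        for n, c in zip(res.names, res.coords):
            names.append(n)
            elements.append("H" if n.startswith("H") else n.lstrip("0123456789")[0])
            res_index.append(ridx)
            coords.append(c)
    top = Topology(
        names=np.array(names),
        elements=np.array(elements),
        res_index=np.array(res_index),
        res_names=np.array(res_names),
        res_chains=np.array(res_chains),
        res_numbers=np.array(res_numbers),
        res_labels=np.array(res_labels),
    )
    return Trajectory(top, np.array(coords)[None])


@dataclass
class FlipSchedule:
    """Scheduled extra-helical episodes of one residue.

    ``fraction_out`` of the frames (rounded to the nearest frame) are
    generated in the extra-helical state, toward the given groove.  The
    realized per-frame state sequence is drawn (seeded) unless an explicit
    ``states`` sequence is supplied.
    """

    residue: str
    fraction_out: float
    groove: str = "major"            # "major" -> negative angles
    states: np.ndarray | None = None  # optional explicit out-state flags

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_out <= 1.0:
            raise ValueError("fraction_out must be in [0, 1]")
        if self.groove not in ("major", "minor"):
            raise ValueError("groove must be 'major' or 'minor'")

    def realize(self, nframes: int, rng: np.random.Generator) -> np.ndarray:
        if self.states is not None:
            states = np.asarray(self.states, dtype=bool)
            if len(states) != nframes:
                raise ValueError("explicit state sequence length != nframes")
            return states
        n_out = int(round(self.fraction_out * nframes))
        flags = np.zeros(nframes, dtype=bool)
        flags[rng.permutation(nframes)[:n_out]] = True
        return flags


def _rotation_about_axis(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def generate_flip_trajectory(
    construct: RnaConstruct,
    schedules: list[FlipSchedule],
    jitter_sigma: float = 0.0,
    nframes: int = 100,
    seed: int = 0,
    helix: HelixParams = HelixParams(),
) -> Trajectory:
    """Duplex trajectory with scheduled base flips and thermal jitter.

    In scheduled "out" frames the nucleobase (heavy atoms + hydrogens) is
    rotated about the axis through its own and its 3'-neighbour's
    phosphate groups -- the central axis of the flip pseudo-dihedral -- so
    that the angle lands exactly on -165 deg (major groove) or +165 deg
    (minor); isotropic Gaussian jitter of width ``jitter_sigma`` is then
    added to every atom.  Deterministic for a fixed seed.
    """
    if nframes < 1:
        raise ValueError("nframes must be >= 1")
    base = generate_duplex_frame(construct, helix)
    top = base.topology
    frame0 = base.coords[0]
    rng = np.random.default_rng(seed)
    masses = np.array([ATOMIC_MASSES[e] for e in top.elements])

    from .geometry import BASE_TEMPLATES

    flips = []
    for sched in schedules:
        ridx = top.residue_index(sched.residue)  # raises for unknown residues
        geom = flip_geometry(top, construct, sched.residue)
        atoms = top.residue_atoms(ridx)
        rname = str(top.res_names[ridx])
        base_names = set(BASE_TEMPLATES[rname].keys())
        rotate_atoms = np.array(
            [a for a in atoms if str(top.names[a]) in base_names], dtype=int
        )
        target = -FLIP_TARGET if sched.groove == "major" else FLIP_TARGET
        rotated = _rotated_frame(
            frame0, top, geom, rotate_atoms, target, masses
        )
        flips.append((sched.realize(nframes, rng), rotate_atoms, rotated))

    coords = np.repeat(frame0[None], nframes, axis=0)
    for out_flags, rotate_atoms, rotated in flips:
        for f in np.nonzero(out_flags)[0]:
            coords[f, rotate_atoms] = rotated
    if jitter_sigma > 0:
        coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
    return Trajectory(top, coords)


def _rotated_frame(
    frame: np.ndarray,
    top: Topology,
    geom,
    rotate_atoms: np.ndarray,
    target_deg: float,
    masses: np.ndarray,
) -> np.ndarray:
    """Coordinates of the rotated base atoms hitting the target flip angle."""
    p1 = _com(frame, geom.own_phosphate, masses)
    p2 = _com(frame, geom.next_phosphate, masses)
    axis = p2 - p1
    current = pseudo_dihedral(top, frame, geom, masses)
    delta = _wrap(target_deg - current)
    for sign in (1.0, -1.0):
        rot = _rotation_about_axis(axis, sign * delta)
        test = frame.copy()
        test[rotate_atoms] = (frame[rotate_atoms] - p1) @ rot.T + p1
        if abs(_wrap(pseudo_dihedral(top, test, geom, masses) - target_deg)) < 1e-6:
            return test[rotate_atoms]
    raise RuntimeError("flip rotation failed to reach the target angle")


def _com(frame: np.ndarray, idx: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses[idx]
    return (frame[idx] * w[:, None]).sum(axis=0) / w.sum()


def _wrap(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


# --------------------------------------------------------------------------
# Melting-curve generator
# --------------------------------------------------------------------------

@dataclass
class MeltSimParams:
    """Two-state melting-curve simulation parameters.

    Defaults mirror the study conditions: 2 uM per strand, 10-90 degC.
    ``dH`` (kcal/mol) and ``dS`` (kcal/(mol K)) are the duplex-formation
    parameters (both negative); the baselines are (intercept, slope) pairs
    in absorbance units.
    """

    dH: float
    dS: float
    c0: float = 2e-6
    baseline_folded: tuple[float, float] = (0.60, 0.0006)
    baseline_unfolded: tuple[float, float] = (0.70, 0.0010)
    T_min: float = 10.0
    T_max: float = 90.0
    n_points: int = 161
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.T_max <= self.T_min:
            raise ValueError("temperature grid must be increasing")


def generate_melting_curve(p: MeltSimParams) -> MeltingCurve:
    """Absorbance-vs-temperature curve from the exact two-state model."""
    t = np.linspace(p.T_min, p.T_max, p.n_points)
    a = melting_absorbance(
        t, p.dH, p.dS, p.c0, p.baseline_folded, p.baseline_unfolded
    )
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        a = a + rng.normal(0.0, p.noise_sigma, size=a.shape)
    return MeltingCurve(temperature_C=t, absorbance=a, c0=p.c0)


# --------------------------------------------------------------------------
# ITC generator
# --------------------------------------------------------------------------

@dataclass
class ItcSimParams:
    """1:1 titration simulation parameters.

    Defaults mirror the duplex-formation titrations: twenty 2 uL
    injections of 100 uM titrant into a 10 uM cell solution (low-volume
    calorimeter active volume 190 uL).  ``qdil`` is a constant per-
    injection dilution heat in ucal.
    """

    ka: float                      # 1/M
    dH: float                      # kcal/mol
    n: float = 1.0
    cell_conc: float = 10e-6
    syringe_conc: float = 100e-6
    cell_volume: float = 190e-6
    injection_volumes: np.ndarray = field(
        default_factory=lambda: np.full(20, 2e-6)
    )
    qdil: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def generate_itc_series(p: ItcSimParams) -> ItcSeries:
    """Per-injection heats (ucal) from the exact 1:1 binding model."""
    q = itc_injection_heats(
        p.ka, p.dH, p.n, p.cell_conc, p.syringe_conc,
        p.injection_volumes, p.cell_volume,
    )
    q = q + p.qdil
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        q = q + rng.normal(0.0, p.noise_sigma, size=q.shape)
    return ItcSeries(
        heats=q,
        injection_volumes=p.injection_volumes,
        cell_conc=p.cell_conc,
        syringe_conc=p.syringe_conc,
        cell_volume=p.cell_volume,
    )
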
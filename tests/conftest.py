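"""Shared fixtures: registry, ideal duplex frames, custom toy topologies."""

from __future__ import annotations

import numpy as np
import pytest

from asitekit.constructs import build_registry
from asitekit.geometry import BASE_TEMPLATES
from asitekit.stacking import load_ff_params
from asitekit.synthetic import generate_duplex_frame
from asitekit.trajectory import Topology


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def prok(registry):
    return registry["prokaryotic"]


@pytest.fixture(scope="session")
def euk(registry):
    return registry["eukaryotic"]


@pytest.fixture(scope="session")
def prok_traj(prok):
    """Single-frame ideal prokaryotic duplex."""
    return generate_duplex_frame(prok)


@pytest.fixture(scope="session")
def ff_params():
    return load_ff_params()


def base3d(resname: str) -> dict[str, np.ndarray]:
    """In-plane base template lifted to 3D (z = 0)."""
    return {
        k: np.array([v[0], v[1], 0.0]) for k, v in BASE_TEMPLATES[resname].items()
    }


def make_topology(residues) -> tuple[Topology, np.ndarray]:
    """Custom toy topology from a list of (resname, {atom: xyz}) entries."""
    names, elements, res_index, coords = [], [], [], []
    res_names, res_chains, res_numbers = [], [], []
    for ridx, (rname, atoms) in enumerate(residues):
        res_names.append(rname)
        res_chains.append("A")
        res_numbers.append(ridx + 1)
        for n, xyz in atoms.items():
            names.append(n)
            elements.append("H" if n.startswith("H") else n.lstrip("0123456789")[0])
            res_index.append(ridx)
            coords.append(np.asarray(xyz, dtype=float))
    top = Topology(
        names=np.array(names),
        elements=np.array(elements),
        res_index=np.array(res_index),
        res_names=np.array(res_names),
        res_chains=np.array(res_chains),
        res_numbers=np.array(res_numbers),
    )
    return top, np.array(coords)


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random rotation + translation applied to a coordinate set."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return coords @ rot.T + shift


def hoogsteen_au() -> tuple[Topology, np.ndarray]:
    """A:U Hoogsteen pair fixture: U's Watson-Crick edge against A's N7/N6
    face, built from the literature Hoogsteen contacts N3(U)-N7(A) and
    O4(U)-N6(A) at 2.9 A."""
    a = base3d("A")
    u0 = base3d("U")
    theta = np.radians(67.0)   # placement angle found once by scanning
    w = np.array([np.cos(theta), np.sin(theta), 0.0])
    q_n3 = a["N7"] + 2.9 * w
    hdir = a["N7"] - q_n3
    hdir /= np.linalg.norm(hdir)
    q_h3 = q_n3 + np.linalg.norm(u0["H3"] - u0["N3"]) * hdir
    u = _map_plane(u0, u0["N3"], u0["H3"], q_n3, q_h3)
    return make_topology([("A", a), ("U", u)])


def corner_au() -> tuple[Topology, np.ndarray]:
    """Single-bond fixture through corner atoms: A N6-H61...O4 U only."""
    a = base3d("A")
    u0 = base3d("U")
    udir = a["H61"] - a["N6"]
    udir /= np.linalg.norm(udir)
    q1 = a["N6"] + 2.9 * udir
    q2 = q1 + np.linalg.norm(u0["C4"] - u0["O4"]) * udir
    u = _map_plane(u0, u0["O4"], u0["C4"], q1, q2)
    return make_topology([("A", a), ("U", u)])


def _map_plane(atoms, src1, src2, dst1, dst2):
    """In-plane rigid transform mapping the segment (src1,src2)->(dst1,dst2)."""
    vs = (src2 - src1)[:2]
    vd = (dst2 - dst1)[:2]
    ang = np.arctan2(vd[1], vd[0]) - np.arctan2(vs[1], vs[0])
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return {k: rot @ (v - src1) + dst1 for k, v in atoms.items()}
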
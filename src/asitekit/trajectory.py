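"""Trajectory container, multi-model PDB I/O and global structural metrics.

Implements the trajectory-level measures used throughout: optimal
(Kabsch) superposition RMSD, per-residue RMSF, gromos (Daura) RMSD
clustering and block-standard-error convergence curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Topology",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsf",
    "ClusterResult",
    "gromos_cluster",
    "BseCurve",
    "block_standard_error",
    "fit_bse_curve",
]


# --------------------------------------------------------------------------
# Topology / Trajectory
# --------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom annotation of a trajectory (fixed across frames)."""

    names: np.ndarray        # atom names, e.g. "N1", "C1'"
    elements: np.ndarray     # element symbols
    res_index: np.ndarray    # 0-based residue index per atom
    res_names: np.ndarray    # residue type per *residue* ("A","C","G","U")
    res_chains: np.ndarray   # chain id per residue ("A"/"B")
    res_numbers: np.ndarray  # numeric residue id per residue (E. coli number)
    res_labels: np.ndarray = field(default=None)  # e.g. "A1493"

    def __post_init__(self) -> None:
        if self.res_labels is None:
            self.res_labels = np.array(
                [f"{n}{i}" for n, i in zip(self.res_names, self.res_numbers)]
            )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def residue_atoms(self, residue: int | str) -> np.ndarray:
        """Atom indices of a residue given by index or label."""
        ridx = self.residue_index(residue)
        return np.nonzero(self.res_index == ridx)[0]

    def residue_index(self, residue: int | str) -> int:
        if isinstance(residue, (int, np.integer)):
            return int(residue)
        hits = np.nonzero(self.res_labels == residue)[0]
        if len(hits) != 1:
            raise KeyError(f"residue label {residue!r} not found (or ambiguous)")
        return int(hits[0])

    def select(
        self,
        heavy: bool = False,
        chains: Sequence[str] | None = None,
        residues: Sequence[int | str] | None = None,
        atom_names: Sequence[str] | None = None,
        base_only: bool = False,
    ) -> np.ndarray:
        """Atom indices matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if heavy:
            mask &= self.elements != "H"
        if chains is not None:
            chain_per_atom = self.res_chains[self.res_index]
            mask &= np.isin(chain_per_atom, list(chains))
        if residues is not None:
            ridx = [self.residue_index(r) for r in residues]
            mask &= np.isin(self.res_index, ridx)
        if atom_names is not None:
            mask &= np.isin(self.names, list(atom_names))
        if base_only:
            from .geometry import BASE_HEAVY_ATOMS
            base_mask = np.zeros(self.n_atoms, dtype=bool)
            for i in range(self.n_atoms):
                rname = self.res_names[self.res_index[i]]
                base_mask[i] = self.names[i] in BASE_HEAVY_ATOMS.get(rname, ())
            mask &= base_mask
        return np.nonzero(mask)[0]


@dataclass
class Trajectory:
    """Ordered coordinate frames (A) over a fixed topology."""

    topology: Topology
    coords: np.ndarray                 # (n_frames, n_atoms, 3)
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def __getitem__(self, frames) -> "Trajectory":
        if isinstance(frames, (int, np.integer)):
            frames = [int(frames)]
        return Trajectory(self.topology, self.coords[frames], self.frame_interval)


# --------------------------------------------------------------------------
# PDB I/O (multi-model, via biotite)
# --------------------------------------------------------------------------

def _to_atom_array_stack(traj: Trajectory) -> struc.AtomArrayStack:
    top = traj.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord[:] = traj.coords
    stack.atom_name = top.names.astype("U6")
    stack.element = top.elements.astype("U2")
    stack.res_id = top.res_numbers[top.res_index].astype(int)
    stack.res_name = np.array(
        [f"R{r}" if len(r) == 1 else r for r in top.res_names[top.res_index]],
        dtype="U5",
    )
    stack.chain_id = top.res_chains[top.res_index].astype("U4")
    stack.hetero = np.zeros(n, dtype=bool)
    return stack


def _from_atom_array_stack(stack: struc.AtomArrayStack) -> Trajectory:
    names = np.asarray(stack.atom_name)
    elements = np.asarray(stack.element)
    res_starts = struc.get_residue_starts(stack)
    res_index = np.zeros(stack.array_length(), dtype=int)
    for i, start in enumerate(res_starts):
        res_index[start:] = i
    res_names = []
    res_chains = []
    res_numbers = []
    for start in res_starts:
        rn = str(stack.res_name[start])
        res_names.append(rn[1] if rn.startswith("R") and len(rn) == 2 else rn)
        res_chains.append(str(stack.chain_id[start]))
        res_numbers.append(int(stack.res_id[start]))
    if not elements.size or not elements[0]:
        elements = np.array([_infer_element(n) for n in names])
    top = Topology(
        names=names,
        elements=elements,
        res_index=res_index,
        res_names=np.array(res_names),
        res_chains=np.array(res_chains),
        res_numbers=np.array(res_numbers),
    )
    return Trajectory(top, np.asarray(stack.coord, dtype=float))


def _infer_element(name: str) -> str:
    return name.lstrip("0123456789")[0]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    f = pdb.PDBFile()
    pdb.set_structure(f, _to_atom_array_stack(traj))
    f.write(str(path))


def read_trajectory(paths: str | Path | Sequence[str | Path]) -> Trajectory:
    """Read one or more multi-model PDB files into a single trajectory.

    Atom order follows the file; frames follow MODEL order (then file
    order).  Elements missing from the input are inferred from atom names.
    Files with inconsistent atom counts raise a ``ValueError``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    trajs = []
    for p in paths:
        from biotite.file import InvalidFileError

        f = pdb.PDBFile.read(str(p))
        try:
            stack = f.get_structure(model=None)
        except (struc.BadStructureError, InvalidFileError) as err:
            raise ValueError(f"{p}: inconsistent models in multi-model PDB: {err}")
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        trajs.append(_from_atom_array_stack(stack))
    first = trajs[0]
    for t in trajs[1:]:
        if t.n_atoms != first.n_atoms:
            raise ValueError("atom counts differ between trajectory files")
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    return Trajectory(first.topology, coords, first.frame_interval)


# --------------------------------------------------------------------------
# Superposition and RMSD
# --------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids so that (mobile-cm) @ R.T + cr ~ ref.

    Returns (R, centroid_mobile, centroid_ref).
    """
    cm = mobile.mean(axis=0)
    cr = ref.mean(axis=0)
    h = (mobile - cm).T @ (ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    return r, cm, cr


def kabsch_rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """Minimal least-squares RMSD after optimal rigid superposition (A)."""
    a = frame_a if selection is None else frame_a[selection]
    b = frame_b if selection is None else frame_b[selection]
    if a.shape != b.shape:
        raise ValueError("selections map to different atom counts")
    if len(a) == 0:
        raise ValueError("empty selection")
    r, cm, cr = kabsch_rotation(b, a)
    b_fit = (b - cm) @ r.T + cr
    return float(np.sqrt(np.mean(np.sum((a - b_fit) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> np.ndarray:
    """Superposition RMSD of every frame against a reference frame."""
    ref = traj.coords[reference_frame]
    return np.array(
        [kabsch_rmsd(ref, traj.coords[i], selection) for i in range(traj.n_frames)]
    )


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> dict[str, float]:
    """Per-residue RMSF (A), mass-unweighted, over residue heavy atoms.

    Frames are first superposed onto the average structure (one pass:
    average over raw frames, superpose, re-average); the RMSF of a residue
    is the root-mean-square deviation of its selected atoms from their
    time-averaged positions.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    top = traj.topology
    sel = (
        top.select(heavy=True) if selection is None else np.asarray(selection)
    )
    coords = traj.coords[:, sel]
    if superpose:
        mean = coords.mean(axis=0)
        fitted = np.empty_like(coords)
        for i in range(len(coords)):
            r, cm, cr = kabsch_rotation(coords[i], mean)
            fitted[i] = (coords[i] - cm) @ r.T + cr
        coords = fitted
        mean = coords.mean(axis=0)
    else:
        mean = coords.mean(axis=0)
    sq_dev = np.sum((coords - mean) ** 2, axis=-1)   # (frames, atoms)
    out: dict[str, float] = {}
    res_of_sel = top.res_index[sel]
    for ridx in np.unique(res_of_sel):
        atom_mask = res_of_sel == ridx
        out[str(top.res_labels[ridx])] = float(
            np.sqrt(np.mean(sq_dev[:, atom_mask]))
        )
    return out


# --------------------------------------------------------------------------
# gromos (Daura) clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    cutoff: float
    assignments: np.ndarray     # frame -> cluster id (0-based, by extraction order)
    centers: np.ndarray         # cluster id -> frame index
    sizes: np.ndarray
    frame_indices: np.ndarray   # original frame numbers of the strided frames

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(
                traj.coords[i], traj.coords[j], selection
            )
    return mat


def gromos_cluster(
    traj: Trajectory,
    cutoff: float,
    selection: np.ndarray | None = None,
    stride: int = 1,
) -> ClusterResult:
    """RMSD-based gromos (Daura) clustering.

    Repeatedly takes the structure with the most neighbours within
    ``cutoff`` (pairwise superposition RMSD) as a cluster centre, assigns
    the centre and its unassigned neighbours to a new cluster and removes
    them; ties on neighbour count are broken by the lowest frame index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    frame_idx = np.arange(traj.n_frames)[::stride]
    sub = traj[frame_idx] if stride != 1 else traj
    mat = pairwise_rmsd_matrix(sub, selection)
    n = len(frame_idx)
    neighbour = mat <= cutoff
    np.fill_diagonal(neighbour, True)
    unassigned = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    cluster = 0
    while unassigned.any():
        counts = (neighbour & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))          # argmax -> lowest index on ties
        members = np.nonzero(neighbour[center] & unassigned)[0]
        assignments[members] = cluster
        unassigned[members] = False
        centers.append(center)
        sizes.append(len(members))
        cluster += 1
    return ClusterResult(
        cutoff=cutoff,
        assignments=assignments,
        centers=np.array(centers),
        sizes=np.array(sizes),
        frame_indices=frame_idx,
    )


# --------------------------------------------------------------------------
# Block-standard-error convergence analysis
# --------------------------------------------------------------------------

@dataclass
class BseCurve:
    block_sizes: np.ndarray
    bse: np.ndarray
    n: int
    series_std: float


def block_standard_error(series: np.ndarray) -> BseCurve:
    """Blocked standard error of the mean vs block size.

    For each block size m (powers of 2 up to N/4) the series is cut into
    floor(N/m) contiguous blocks and BSE(m) = std(block means)/sqrt(#blocks)
    (sample std, ddof=1).  BSE(1) equals std(series)/sqrt(N); for a
    converged, decorrelated series the curve asymptotes with growing m.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series too short for block analysis (need >= 4)")
    sizes = []
    m = 1
    while m <= n // 4:
        sizes.append(m)
        m *= 2
    bse = []
    for m in sizes:
        nblocks = n // m
        means = x[: nblocks * m].reshape(nblocks, m).mean(axis=1)
        bse.append(means.std(ddof=1) / np.sqrt(nblocks))
    return BseCurve(
        block_sizes=np.array(sizes),
        bse=np.array(bse),
        n=n,
        series_std=float(x.std(ddof=1)),
    )


def fit_bse_curve(curve: BseCurve, n_exp: int = 2) -> dict:
    """Fit the analytic blocked-standard-error model assuming the series
    autocorrelation is a sum of ``n_exp`` exponentials.

    For C(t) = sum_i a_i exp(-t/tau_i) the variance of a length-m block
    mean is sigma^2/m * sum_i a_i g(m/tau_i) with
    g(x) = 2/x * (1 - (1 - e^-x)/x); the BSE follows from the number of
    blocks.  Returns amplitudes, correlation times and the fitted curve.
    """
    from scipy.optimize import least_squares

    m = curve.block_sizes.astype(float)
    nblocks = curve.n // curve.block_sizes
    target = curve.bse

    def g(x):
        x = np.maximum(x, 1e-12)
        return 2.0 / x * (1.0 - (1.0 - np.exp(-x)) / x)

    def model(params):
        taus = np.exp(params[:n_exp])
        raw = np.abs(params[n_exp:])
        a = raw / raw.sum()
        var_block = curve.series_std**2 * sum(
            ai * g(m / ti) for ai, ti in zip(a, taus)
        )
        return np.sqrt(np.maximum(var_block, 0.0) / nblocks)

    def residual(params):
        return model(params) - target

    x0 = np.concatenate([np.linspace(0.0, 2.0, n_exp), np.ones(n_exp)])
    sol = least_squares(residual, x0, max_nfev=5000)
    taus = np.exp(sol.x[:n_exp])
    raw = np.abs(sol.x[n_exp:])
    amps = raw / raw.sum()
    order = np.argsort(taus)
    return {
        "tau": taus[order],
        "amplitude": amps[order],
        "fitted": model(sol.x),
        "cost": float(sol.cost),
    }
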
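"""Stacking detection and Coulomb + Lennard-Jones energetics."""

import numpy as np
import pytest

from asitekit.stacking import (
    COULOMB_CONSTANT,
    ForceFieldParams,
    detect_stacked,
    frame_stacking_total,
    load_ff_params,
    pairwise_energy,
    region_average,
    stack_energy,
    stacking_timeseries,
)
from asitekit.geometry import BASE_HEAVY_ATOMS
from asitekit.trajectory import Trajectory
from conftest import base3d, make_topology, rigid_transform


def brute_force_energy(top, frame, pair, params):
    """Independent double loop over atoms (the oracle)."""
    coulomb = vdw = 0.0
    for i_atom in top.residue_atoms(pair[0]):
        name_i = str(top.names[i_atom])
        res_i = str(top.res_names[pair[0]])
        if name_i not in BASE_HEAVY_ATOMS[res_i]:
            continue
        qi, ei, ri = params.require(res_i, name_i)
        for j_atom in top.residue_atoms(pair[1]):
            name_j = str(top.names[j_atom])
            res_j = str(top.res_names[pair[1]])
            if name_j not in BASE_HEAVY_ATOMS[res_j]:
                continue
            qj, ej, rj = params.require(res_j, name_j)
            r = float(np.linalg.norm(frame[i_atom] - frame[j_atom]))
            coulomb += COULOMB_CONSTANT * qi * qj / r
            eps = np.sqrt(ei * ej)
            rmin = ri + rj
            vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    return coulomb, vdw


class TestParams:
    def test_shipped_table_covers_all_bases(self, ff_params):
        ff_params.validate()

    def test_missing_parameter_named(self):
        p = ForceFieldParams({}, {}, {})
        with pytest.raises(KeyError, match="N1"):
            p.require("A", "N1")

    def test_custom_file_loading(self, tmp_path, ff_params):
        path = tmp_path / "ff.csv"
        rows = ["restype,atom,charge,epsilon,rmin_half"]
        for (rt, at), q in ff_params.charges.items():
            rows.append(f"{rt},{at},{q},{ff_params.epsilons[(rt, at)]},"
                        f"{ff_params.rmin_half[(rt, at)]}")
        path.write_text("\n".join(rows))
        again = load_ff_params(path)
        assert again.charges == ff_params.charges


class TestDetection:
    def test_distant_bases_not_stacked(self):
        a = base3d("A")
        g = {k: v + np.array([50.0, 0.0, 0.0]) for k, v in base3d("G").items()}
        top, frame = make_topology([("A", a), ("G", g)])
        assert detect_stacked(top, frame) == []

    def test_consecutive_helix_bases_stacked(self, prok_traj):
        """Consecutive intra-strand bases of the canonical stem stack
        (same-kind steps: purine runs on strand B, pyrimidine runs on A)."""
        top = prok_traj.topology
        pairs = set(detect_stacked(top, prok_traj.coords[0]))
        for la, lb in (("G1484", "G1485"), ("G1485", "G1486"),
                       ("C1414", "C1415"), ("C1415", "C1416")):
            i, j = top.residue_index(la), top.residue_index(lb)
            assert (min(i, j), max(i, j)) in pairs, (la, lb)

    def test_coplanar_side_by_side_not_stacked(self):
        a = base3d("A")
        # same plane, centroids ~6 A apart, interplanar angle 0
        g = {k: v + np.array([9.0, 0.0, 0.0]) for k, v in base3d("G").items()}
        top, frame = make_topology([("A", a), ("G", g)])
        ring_a = np.mean([frame[i] for i in range(6)], axis=0)
        assert detect_stacked(top, frame, centroid_cutoff=4.5) == []

    def test_hbonded_partners_excluded(self, prok_traj):
        top = prok_traj.topology
        frame = prok_traj.coords[0]
        i = top.residue_index("G1401")
        j = top.residue_index("C1501")
        assert (min(i, j), max(i, j)) not in detect_stacked(top, frame)


class TestEnergy:
    def test_zeroed_charges_zero_coulomb(self, prok_traj, ff_params):
        zeroed = ForceFieldParams(
            {k: 0.0 for k in ff_params.charges},
            ff_params.epsilons, ff_params.rmin_half,
        )
        pair = detect_stacked(prok_traj.topology, prok_traj.coords[0])[0]
        e = stack_energy(prok_traj.topology, prok_traj.coords[0], pair, zeroed)
        assert e.coulomb == 0.0
        assert e.total == e.vdw

    def test_lj_minimum_at_rmin(self):
        """Two single atoms at r = Rmin_ij have vdw exactly -eps_ij."""
        eps1, eps2 = 0.17, 0.21
        r1, r2 = 1.824, 1.6612
        x1 = np.array([[0.0, 0.0, 0.0]])
        x2 = np.array([[r1 + r2, 0.0, 0.0]])
        _, vdw = pairwise_energy(
            np.array([0.0]), np.array([eps1]), np.array([r1]), x1,
            np.array([0.0]), np.array([eps2]), np.array([r2]), x2,
        )
        assert vdw == pytest.approx(-np.sqrt(eps1 * eps2), rel=1e-12)

    def test_matches_brute_force_oracle(self, prok_traj, ff_params):
        """Vectorised energies equal the independent atom-pair double loop
        to 1e-9 for every stacked pair."""
        top = prok_traj.topology
        frame = prok_traj.coords[0]
        for pair in detect_stacked(top, frame):
            e = stack_energy(top, frame, pair, ff_params)
            bc, bv = brute_force_energy(top, frame, pair, ff_params)
            assert e.coulomb == pytest.approx(bc, abs=1e-9)
            assert e.vdw == pytest.approx(bv, abs=1e-9)
            assert e.total == e.coulomb + e.vdw

    def test_symmetric_and_rigid_motion_invariant(self, prok_traj, ff_params):
        top = prok_traj.topology
        frame = prok_traj.coords[0]
        i, j = detect_stacked(top, frame)[0]
        e_ij = stack_energy(top, frame, (i, j), ff_params)
        e_ji = stack_energy(top, frame, (j, i), ff_params)
        assert e_ij.total == pytest.approx(e_ji.total, rel=1e-12)
        moved = rigid_transform(frame, seed=21)
        e_moved = stack_energy(top, moved, (i, j), ff_params)
        assert e_moved.coulomb == pytest.approx(e_ij.coulomb, rel=1e-9)
        assert e_moved.vdw == pytest.approx(e_ij.vdw, rel=1e-9)

    def test_doubling_charges_quadruples_coulomb(self, prok_traj, ff_params):
        doubled = ForceFieldParams(
            {k: 2.0 * v for k, v in ff_params.charges.items()},
            ff_params.epsilons, ff_params.rmin_half,
        )
        pair = detect_stacked(prok_traj.topology, prok_traj.coords[0])[0]
        e1 = stack_energy(prok_traj.topology, prok_traj.coords[0], pair, ff_params)
        e2 = stack_energy(prok_traj.topology, prok_traj.coords[0], pair, doubled)
        assert e2.coulomb == pytest.approx(4.0 * e1.coulomb, rel=1e-12)
        assert e2.vdw == pytest.approx(e1.vdw, rel=1e-12)


@pytest.fixture(scope="module")
def static_traj(prok_traj):
    return Trajectory(prok_traj.topology,
                      np.repeat(prok_traj.coords, 4, axis=0))


class TestAggregation:
    def test_static_fixture_zero_std(self, prok, static_traj, ff_params):
        region = [prok.strandB.label(p) for p in range(6, 16)]
        res = region_average(static_traj, region, ff_params)
        assert res["std"]["total"] == pytest.approx(0.0, abs=1e-9)

    def test_region_bookkeeping_identity(self, prok, static_traj, ff_params):
        """Region per-nucleotide totals equal the pair-sum with interior
        pairs counted once and boundary pairs at half weight."""
        top = static_traj.topology
        frame = static_traj.coords[0]
        region_labels = [prok.strandB.label(p) for p in range(6, 16)]
        region = {top.residue_index(r) for r in region_labels}
        expected = 0.0
        for (i, j) in detect_stacked(top, frame):
            inside = (i in region) + (j in region)
            if inside:
                e = stack_energy(top, frame, (i, j), ff_params)
                expected += e.total * inside / 2.0
        res = region_average(static_traj, region_labels, ff_params)
        assert res["mean"]["total"] == pytest.approx(
            expected / len(region_labels), rel=1e-9
        )

    def test_total_is_sum_of_terms(self, static_traj, prok, ff_params):
        region = [prok.strandB.label(p) for p in range(6, 16)]
        res = region_average(static_traj[0:1], region, ff_params)
        assert res["mean"]["total"] == pytest.approx(
            res["mean"]["coulomb"] + res["mean"]["vdw"], rel=1e-12
        )

    def test_timeseries_windows(self, prok, ff_params):
        from asitekit.synthetic import FlipSchedule, generate_flip_trajectory

        traj = generate_flip_trajectory(
            prok, [FlipSchedule("U1498", 0.5, "major")], 0.0, nframes=6, seed=2
        )
        raw = stacking_timeseries(traj, ff_params, window=1)
        assert len(raw) == 6
        whole = stacking_timeseries(traj, ff_params, window=6)
        assert len(whole) == 1
        assert whole["total"][0] == pytest.approx(raw["total"].mean(), rel=1e-12)
        # windowed means equal an independent recomputation
        w3 = stacking_timeseries(traj, ff_params, window=3)
        assert w3["total"][0] == pytest.approx(raw["total"][:3].mean(), rel=1e-12)
        assert w3["total"][1] == pytest.approx(raw["total"][3:].mean(), rel=1e-12)
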
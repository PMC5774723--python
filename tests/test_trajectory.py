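"""Trajectory I/O, Kabsch RMSD, RMSF, gromos clustering and BSE curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from asitekit.synthetic import FlipSchedule, generate_flip_trajectory
from asitekit.trajectory import (
    Trajectory,
    block_standard_error,
    fit_bse_curve,
    gromos_cluster,
    kabsch_rmsd,
    read_trajectory,
    rmsd_series,
    rmsf,
    write_trajectory,
)
from conftest import make_topology


def toy_trajectory(coords_list):
    n = len(coords_list[0])
    top, _ = make_topology(
        [("A", {f"C{i+1}": coords_list[0][i] for i in range(n)})]
    )
    # keep all atoms in one residue; names C1..Cn, element C
    return Trajectory(top, np.array(coords_list, dtype=float))


class TestPdbIO:
    def test_single_model_file(self, prok_traj, tmp_path):
        path = tmp_path / "one.pdb"
        write_trajectory(prok_traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 1
        assert back.n_atoms == prok_traj.n_atoms

    def test_round_trip_preserves_order_and_coords(self, prok, tmp_path):
        traj = generate_flip_trajectory(
            prok, [FlipSchedule("U1498", 0.5, "major")], 0.1, nframes=5, seed=1
        )
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 5
        assert np.array_equal(back.topology.names, traj.topology.names)
        assert np.array_equal(back.topology.res_labels, traj.topology.res_labels)
        # PDB stores 3 decimals
        assert np.abs(back.coords - traj.coords).max() < 1e-3 + 1e-6

    def test_mismatched_model_sizes_error(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  C1  RA  A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  C2  RA  A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  C1  RA  A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(ValueError):
            read_trajectory(path)

    def test_multiple_files_concatenate(self, prok_traj, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_trajectory(prok_traj, p1)
        write_trajectory(prok_traj, p2)
        back = read_trajectory([p1, p2])
        assert back.n_frames == 2


class TestKabschRmsd:
    def test_identical_frames_zero(self, prok_traj):
        f = prok_traj.coords[0]
        assert kabsch_rmsd(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_is_zero(self, prok_traj):
        f = prok_traj.coords[0]
        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        g = f @ rot.T + np.array([5.0, -3.0, 12.0])
        assert kabsch_rmsd(f, g) == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_grid(self):
        """3-atom toy: optimal superposition RMSD agrees with a brute-force
        search over rotations to 1e-3 A."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        fast = kabsch_rmsd(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        best = np.inf
        # coarse grid + local refinement around the best grid point
        grid = Rotation.create_group("O")  # octahedral rotations as seeds
        seeds = grid.as_rotvec()
        for seed in seeds:
            from scipy.optimize import minimize

            def cost(v):
                r = Rotation.from_rotvec(v).as_matrix()
                return np.sqrt(np.mean(np.sum((ac - bc @ r.T) ** 2, axis=-1)))

            res = minimize(cost, seed, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
            best = min(best, res.fun)
        assert fast == pytest.approx(best, abs=1e-3)

    def test_empty_selection_errors(self, prok_traj):
        f = prok_traj.coords[0]
        with pytest.raises(ValueError):
            kabsch_rmsd(f, f, np.array([], dtype=int))

    def test_count_mismatch_errors(self, prok_traj):
        f = prok_traj.coords[0]
        with pytest.raises(ValueError):
            kabsch_rmsd(f[:10], f[:9])

    def test_agrees_with_mdanalysis(self, prok, tmp_path):
        """Independent cross-check of the superposition RMSD."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        traj = generate_flip_trajectory(
            prok, [FlipSchedule("A1492", 0.5, "minor")], 0.3, nframes=2, seed=3
        )
        ours = kabsch_rmsd(traj.coords[0], traj.coords[1])
        theirs = mda_rmsd(traj.coords[1], traj.coords[0],
                          center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_pseudo_metric_properties(self, seed):
        """Symmetry and triangle inequality on random frame triples."""
        rng = np.random.default_rng(seed)
        frames = rng.normal(scale=5.0, size=(3, 6, 3))
        d01 = kabsch_rmsd(frames[0], frames[1])
        d10 = kabsch_rmsd(frames[1], frames[0])
        d02 = kabsch_rmsd(frames[0], frames[2])
        d12 = kabsch_rmsd(frames[1], frames[2])
        assert d01 == pytest.approx(d10, abs=1e-9)
        assert d02 <= d01 + d12 + 1e-9


class TestRmsf:
    def test_static_trajectory_zero(self, prok_traj):
        traj = Trajectory(
            prok_traj.topology, np.repeat(prok_traj.coords, 3, axis=0)
        )
        values = rmsf(traj)
        assert max(values.values()) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_displacement_closed_form(self):
        """One residue displaced +-d on alternating frames (no global
        motion, no superposition) has RMSF exactly d."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(8, 3))
        top, _ = make_topology(
            [
                ("A", {f"C{i+1}": base[i] for i in range(4)}),
                ("G", {f"N{i+1}": base[4 + i] for i in range(4)}),
            ]
        )
        d = 0.7
        frames = []
        for k in range(6):
            f = base.copy()
            f[4:] += (d if k % 2 == 0 else -d) * np.array([0.0, 0.0, 1.0])
            frames.append(f)
        traj = Trajectory(top, np.array(frames))
        values = rmsf(traj, superpose=False)
        assert values["G2"] == pytest.approx(d, abs=1e-12)
        assert values["A1"] == pytest.approx(0.0, abs=1e-12)

    def test_flipping_residue_has_greatest_rmsf(self, prok):
        traj = generate_flip_trajectory(
            prok, [FlipSchedule("U1498", 0.5, "major")], 0.0, nframes=10, seed=4
        )
        values = rmsf(traj)
        assert max(values, key=values.get) == "U1498"

    def test_single_frame_errors(self, prok_traj):
        with pytest.raises(ValueError):
            rmsf(prok_traj)


class TestGromosClustering:
    def test_single_cluster_when_cutoff_large(self, prok):
        traj = generate_flip_trajectory(prok, [], 0.2, nframes=8, seed=6)
        res = gromos_cluster(traj, cutoff=100.0,
                             selection=traj.topology.select(heavy=True))
        assert res.n_clusters == 1
        assert res.sizes[0] == 8

    def test_two_groups_exact_membership(self, prok):
        """Frames alternating between the intra- and extra-helical pose of
        one residue split into exactly two clusters."""
        states = np.array([0, 1, 0, 1, 1, 0], dtype=bool)
        traj = generate_flip_trajectory(
            prok, [FlipSchedule("U1498", 0.5, "major", states=states)],
            0.0, nframes=6, seed=0,
        )
        sel = traj.topology.select(heavy=True)
        res = gromos_cluster(traj, cutoff=0.3, selection=sel)
        assert res.n_clusters == 2
        groups = {tuple(np.nonzero(res.assignments == c)[0]) for c in (0, 1)}
        assert groups == {tuple(np.nonzero(states)[0]),
                          tuple(np.nonzero(~states)[0])}
        for cid, center in enumerate(res.centers):
            assert res.assignments[center] == cid

    def test_cluster_count_non_increasing_in_cutoff(self, prok):
        traj = generate_flip_trajectory(
            prok,
            [FlipSchedule("U1498", 0.5, "major"),
             FlipSchedule("A1492", 0.3, "minor")],
            0.15, nframes=12, seed=8,
        )
        sel = traj.topology.select(heavy=True)
        counts = [
            gromos_cluster(traj, cutoff, sel).n_clusters
            for cutoff in (0.2, 0.5, 1.5, 2.0, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the ladder is informative

    def test_partition_and_determinism(self, prok):
        traj = generate_flip_trajectory(prok, [], 0.4, nframes=10, seed=3)
        sel = traj.topology.select(heavy=True)
        a = gromos_cluster(traj, 0.5, sel)
        b = gromos_cluster(traj, 0.5, sel)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.sizes.sum() == traj.n_frames
        assert np.all(a.assignments >= 0)

    def test_empty_and_bad_cutoff(self, prok_traj):
        with pytest.raises(ValueError):
            gromos_cluster(prok_traj, cutoff=-1.0)


class TestBlockStandardError:
    def test_constant_series_zero(self):
        curve = block_standard_error(np.full(64, 3.14))
        assert np.allclose(curve.bse, 0.0)

    def test_bse_one_is_std_over_sqrt_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        curve = block_standard_error(x)
        assert curve.block_sizes[0] == 1
        assert curve.bse[0] == pytest.approx(x.std(ddof=1) / 16.0)

    def test_iid_flat_curve(self):
        """iid Gaussian: BSE stays flat at sigma/sqrt(N) for all block sizes
        (within 3x the Monte-Carlo error of the block-mean std)."""
        rng = np.random.default_rng(2)
        sigma, n = 1.3, 4096
        curve = block_standard_error(rng.normal(0.0, sigma, size=n))
        expected = sigma / np.sqrt(n)
        for m, bse in zip(curve.block_sizes, curve.bse):
            nblocks = n // m
            mc_err = expected / np.sqrt(2 * (nblocks - 1))
            assert abs(bse - expected) < 3 * mc_err, (m, bse)

    @staticmethod
    def _ar1(rng, rho, n):
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0] / np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        return x

    def test_ar1_plateau(self):
        """AR(1) with rho=0.9 plateaus near sigma sqrt((1+rho)/(1-rho))/sqrt(N)
        (block sizes well beyond the ~10-frame correlation time, averaged
        over seeded replicates to tame the small-block-count noise)."""
        rho, n, reps = 0.9, 2**14, 6
        sigma = 1.0 / np.sqrt(1 - rho**2)
        expected = sigma * np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        plateaus = []
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            curve = block_standard_error(self._ar1(rng, rho, n))
            sel = (curve.block_sizes >= 512) & (curve.block_sizes <= n // 8)
            plateaus.append(curve.bse[sel].mean())
        assert np.mean(plateaus) == pytest.approx(expected, rel=0.15)

    def test_monotone_in_expectation_for_positive_autocorrelation(self):
        """Averaged over seeded replicates, the BSE curve of an AR(1)
        series is non-decreasing over the well-sampled block sizes
        (those with at least 16 blocks)."""
        rho, n, reps = 0.8, 1024, 40
        curves = []
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            curve = block_standard_error(self._ar1(rng, rho, n))
            sel = curve.block_sizes <= n // 16
            # squared BSE: the block-mean variance estimator is unbiased,
            # so its replicate average is monotone without estimator bias
            curves.append(curve.bse[sel] ** 2)
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) > -1e-6)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            block_standard_error(np.ones(3))

    def test_two_exponential_fit_recovers_correlation_time(self):
        rng = np.random.default_rng(5)
        rho, n = 0.9, 2**14
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0] / np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        curve = block_standard_error(x)
        fit = fit_bse_curve(curve)
        # dominant fitted correlation time ~ -1/ln(rho) ~ 9.5 frames
        tau_dom = fit["tau"][np.argmax(fit["amplitude"])]
        assert 3.0 < tau_dom < 30.0


class TestRmsdSeries:
    def test_reference_frame_zero(self, prok):
        traj = generate_flip_trajectory(prok, [], 0.2, nframes=5, seed=1)
        series = rmsd_series(traj, traj.topology.select(heavy=True))
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(series[1:] > 0)
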
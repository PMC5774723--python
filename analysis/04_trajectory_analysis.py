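#!/usr/bin/env python
"""Structural analysis of synthetic A-site trajectories.

Generates one synthetic trajectory per construct with flip schedules
emulating the reported conformational behaviour -- prokaryotic: A1492
extra-helical essentially throughout, U1498 intra-helical; eukaryotic:
A1492 intra-helical after an early flip-in, U1498 mostly extra-helical
through the major groove -- plus thermal jitter, and runs the full
trajectory pipeline (RMSD/RMSF, hydrogen-bond counts, stacking, flip
angles, pair occupancies, gromos clustering, BSE curves).

Trajectory PDBs go to scratch/ (bulky, regenerable); per-construct
artifact tables go to results/traj_<construct>/.
"""

from pathlib import Path

import pandas as pd

from asitekit.constructs import build_registry
from asitekit.pipeline import RunConfig, run_trajectory_pipeline
from asitekit.synthetic import FlipSchedule, generate_flip_trajectory
from asitekit.trajectory import write_trajectory

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"

N_FRAMES = 40
JITTER = 0.15   # A; keeps classifications unambiguous while exercising noise
SEED = 20260928

SCHEDULES = {
    "prokaryotic": [
        FlipSchedule("A1492", 0.95, "minor"),
        FlipSchedule("U1498", 0.05, "major"),
    ],
    "eukaryotic": [
        FlipSchedule("A1492", 0.05, "minor"),
        FlipSchedule("U1498", 0.85, "major"),
    ],
}

#: Target windows of the three oligomers on strand B (E. coli numbering).
REGIONS = {
    "target_1489": range(1489, 1499),
    "target_1490": range(1490, 1500),
    "target_1491": range(1491, 1501),
}


def region_labels(construct, numbers):
    strand = construct.strandB
    labels = {}
    for pos in range(1, len(strand) + 1):
        label = strand.label(pos)
        labels[int(label[1:])] = label
    return [labels[n] for n in numbers]


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    registry = build_registry()
    summaries = []
    for name, schedules in SCHEDULES.items():
        construct = registry[name]
        traj = generate_flip_trajectory(
            construct, schedules, jitter_sigma=JITTER, nframes=N_FRAMES,
            seed=SEED,
        )
        write_trajectory(traj, SCRATCH / f"{name}_traj.pdb")
        cfg = RunConfig(
            construct=name,
            output_dir=str(OUT / f"traj_{name}"),
            seed=SEED,
            cluster_cutoff=2.0,
            regions={
                rname: region_labels(construct, nums)
                for rname, nums in REGIONS.items()
            },
        )
        report = run_trajectory_pipeline(cfg, traj=traj)
        hb = pd.read_csv(OUT / f"traj_{name}" / "hbond_counts.csv")
        summaries.append(
            {
                "construct": name,
                "n_frames": report["n_frames"],
                "n_clusters_2A": report["n_clusters"],
                "mean_wcwc_hbonds": hb.wcwc_hbonds.mean(),
                "mean_nonwcwc_hbonds": hb.nonwcwc_hbonds.mean(),
            }
        )
    table = pd.DataFrame(summaries)
    table.to_csv(OUT / "trajectory_summary.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nThe eukaryotic construct carries fewer WC-WC hydrogen bonds than "
        "the prokaryotic one (it lacks the C1409:G1491 pair and spends most "
        "frames with U1498 flipped out), mirroring the reported stability "
        "ordering of the two models."
    )


if __name__ == "__main__":
    main()
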
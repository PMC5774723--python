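#!/usr/bin/env python
"""Block-averaging convergence analysis of the trajectory observables.

Reads the RMSD and stacking time series produced by 04_trajectory_analysis
(regenerating them if absent), computes blocked-standard-error curves and
fits the two-exponential autocorrelation model.  A BSE curve that rises
monotonically and levels off indicates statistically independent blocks,
i.e. the series length comfortably exceeds the correlation time.

Writes results/convergence.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from asitekit.trajectory import BseCurve, block_standard_error, fit_bse_curve

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    rows = []
    for name in ("prokaryotic", "eukaryotic"):
        traj_dir = OUT / f"traj_{name}"
        if not (traj_dir / "rmsd.csv").exists():
            subprocess.run(
                [sys.executable, str(ROOT / "analysis" / "04_trajectory_analysis.py")],
                check=True,
            )
        for series_name, fname, column in (
            ("rmsd", "rmsd.csv", "rmsd_A"),
            ("stacking_total", "stacking_timeseries.csv", "total"),
        ):
            series = pd.read_csv(traj_dir / fname)[column].to_numpy()
            curve = block_standard_error(series)
            fit = fit_bse_curve(curve)
            for m, bse, fitted in zip(curve.block_sizes, curve.bse, fit["fitted"]):
                rows.append(
                    {
                        "construct": name,
                        "series": series_name,
                        "block_size": m,
                        "bse": bse,
                        "bse_two_exp_fit": fitted,
                        "series_std": curve.series_std,
                        "tau_dominant": fit["tau"][fit["amplitude"].argmax()],
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "convergence.csv", index=False)
    print(table.round(4).to_string(index=False))
    print(
        "\nBoth observables give essentially flat BSE curves at the level "
        "of std/sqrt(N), and the two-exponential fit finds sub-frame "
        "dominant correlation times: the synthetic trajectories draw their "
        "flip states independently per frame, so successive blocks are "
        "statistically independent from block size 1 onward.  (A real "
        "simulation shows the rising-then-plateauing shape instead; the "
        "rise length estimates its correlation time.)"
    )


if __name__ == "__main__":
    main()
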
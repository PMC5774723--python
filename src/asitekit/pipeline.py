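"""Report pipelines tying the analysis stages into two workflows.

``run_trajectory_pipeline`` runs the structural workflow over a (synthetic
or user-supplied) trajectory: RMSD/RMSF, WC-WC and non-WC-WC hydrogen-bond
counts, stacking time series and region averages, flip-angle series, pair
occupancies, gromos clustering and block-standard-error convergence
curves.  ``run_thermo_pipeline`` runs the solution workflow over melting
and ITC CSV inputs.  Both are deterministic given a config and embed the
config hash in their report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import thermo
from .constructs import RnaConstruct, build_registry
from .flipping import flip_timeseries_report
from .hbonds import hbond_count_series, pair_occupancy
from .stacking import load_ff_params, region_average, stacking_timeseries
from .trajectory import (
    Trajectory,
    block_standard_error,
    gromos_cluster,
    read_trajectory,
    rmsd_series,
    rmsf,
)

__all__ = ["RunConfig", "run_trajectory_pipeline", "run_thermo_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (JSON round-trippable)."""

    trajectory: str | None = None          # multi-model PDB path
    construct: str = "prokaryotic"
    output_dir: str = "results"
    seed: int = 0
    hbond_max_distance: float = 3.5
    hbond_min_angle: float = 150.0
    occupancy_threshold: float = 0.05
    cluster_cutoff: float = 2.0
    cluster_stride: int = 1
    stacking_window: int = 1
    flip_residues: tuple[str, ...] = ("A1492", "A1493", "U1498")
    regions: dict = field(default_factory=dict)   # name -> list of residue labels
    ff_params: str | None = None           # CSV path; None -> shipped table
    melt_inputs: tuple[str, ...] = ()      # melting CSV paths
    itc_inputs: tuple[str, ...] = ()       # ITC CSV paths (+ JSON sidecars)
    melt_c0: float = 2e-6

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("flip_residues", "melt_inputs", "itc_inputs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("flip_residues", "melt_inputs", "itc_inputs"):
            d[key] = list(d[key])
        return json.dumps(d, indent=2, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _resolve_construct(name: str) -> RnaConstruct:
    registry = build_registry()
    obj = registry.get(name)
    if not isinstance(obj, RnaConstruct):
        raise ValueError(f"unknown construct {name!r}")
    return obj


def run_trajectory_pipeline(
    config: RunConfig, traj: Trajectory | None = None
) -> dict:
    """Run the full structural workflow; returns the report bundle dict.

    Writes eight artifact CSVs plus ``report.json`` into the output
    directory.  Any stage failure aborts with an error naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    construct = _resolve_construct(config.construct)
    if traj is None:
        if config.trajectory is None:
            raise ValueError("config.trajectory is required")
        traj = read_trajectory(config.trajectory)
    artifacts: dict[str, str] = {}

    def stage(name: str, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    sel = traj.topology.select(heavy=True)

    def do_rmsd():
        series = rmsd_series(traj, sel)
        df = pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd_A": series})
        df.to_csv(out / "rmsd.csv", index=False)
        artifacts["rmsd"] = "rmsd.csv"
        return series

    rmsd_values = stage("rmsd", do_rmsd)

    def do_rmsf():
        values = rmsf(traj, sel)
        df = pd.DataFrame(
            {"residue": list(values), "rmsf_A": list(values.values())}
        )
        df.to_csv(out / "rmsf.csv", index=False)
        artifacts["rmsf"] = "rmsf.csv"

    stage("rmsf", do_rmsf)

    def do_hbonds():
        df = hbond_count_series(traj)
        df.to_csv(out / "hbond_counts.csv", index=False)
        artifacts["hbond_counts"] = "hbond_counts.csv"

    stage("hbond_counts", do_hbonds)

    params = load_ff_params(config.ff_params)

    def do_stacking():
        df = stacking_timeseries(traj, params, window=config.stacking_window)
        df.to_csv(out / "stacking_timeseries.csv", index=False)
        artifacts["stacking_timeseries"] = "stacking_timeseries.csv"
        return df

    stack_df = stage("stacking_timeseries", do_stacking)

    def do_regions():
        rows = []
        for name, residues in (config.regions or {}).items():
            res = region_average(traj, list(residues), params)
            rows.append(
                {
                    "region": name,
                    "coulomb": res["mean"]["coulomb"],
                    "coulomb_std": res["std"]["coulomb"],
                    "vdw": res["mean"]["vdw"],
                    "vdw_std": res["std"]["vdw"],
                    "total": res["mean"]["total"],
                    "total_std": res["std"]["total"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "stacking_regions.csv", index=False)
        artifacts["stacking_regions"] = "stacking_regions.csv"

    stage("stacking_regions", do_regions)

    def do_flips():
        df = flip_timeseries_report(traj, construct, list(config.flip_residues))
        df.to_csv(out / "flip_angles.csv", index=False)
        artifacts["flip_angles"] = "flip_angles.csv"

    stage("flip_angles", do_flips)

    def do_occupancy():
        table = pair_occupancy(traj, threshold=config.occupancy_threshold)
        table.to_frame(reported_only=True).to_csv(
            out / "pair_occupancy.csv", index=False
        )
        artifacts["pair_occupancy"] = "pair_occupancy.csv"

    stage("pair_occupancy", do_occupancy)

    def do_cluster():
        res = gromos_cluster(
            traj, config.cluster_cutoff, sel, stride=config.cluster_stride
        )
        df = pd.DataFrame(
            {
                "frame": res.frame_indices,
                "cluster": res.assignments,
            }
        )
        df.to_csv(out / "clusters.csv", index=False)
        artifacts["clusters"] = "clusters.csv"
        return res

    cluster_res = stage("clustering", do_cluster)

    def do_bse():
        frames_bse = block_standard_error(rmsd_values)
        rows = [
            {"series": "rmsd", "block_size": m, "bse": b}
            for m, b in zip(frames_bse.block_sizes, frames_bse.bse)
        ]
        if len(stack_df) >= 4:
            sbse = block_standard_error(stack_df["total"].to_numpy())
            rows += [
                {"series": "stacking_total", "block_size": m, "bse": b}
                for m, b in zip(sbse.block_sizes, sbse.bse)
            ]
        pd.DataFrame(rows).to_csv(out / "bse.csv", index=False)
        artifacts["bse"] = "bse.csv"

    stage("bse", do_bse)

    report = {
        "config_hash": config.hash,
        "seed": config.seed,
        "construct": config.construct,
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "n_clusters": int(cluster_res.n_clusters),
        "artifacts": artifacts,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_thermo_pipeline(config: RunConfig) -> dict:
    """Fit every melting/ITC input; per-dataset failures do not abort.

    Returns the report bundle with one fit row per dataset (layout of the
    solution-thermodynamics tables: dH, TdS, dG at 294.15 K, Tm / Ka, n)
    and a cross-method consistency column dG_from_Ka for ITC fits.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    errors: dict[str, str] = {}
    for path in config.melt_inputs:
        try:
            df = pd.read_csv(path)
            curve = thermo.MeltingCurve(
                df["temperature_C"].to_numpy(),
                df["absorbance"].to_numpy(),
                c0=config.melt_c0,
            )
            fit = thermo.fit_two_state(curve)
            rows.append(
                {
                    "dataset": Path(path).stem,
                    "method": "UV melting",
                    "dH_kcal_mol": fit.dH,
                    "TdS_kcal_mol": fit.TdS,
                    "dG_kcal_mol": fit.dG,
                    "Tm_C": fit.Tm_C,
                    "Ka_1_M": np.nan,
                    "n": np.nan,
                    "success": fit.success,
                    "message": fit.message,
                }
            )
        except Exception as err:
            errors[str(path)] = str(err)
    for path in config.itc_inputs:
        try:
            df = pd.read_csv(path)
            sidecar = Path(path).with_suffix(".json")
            meta = json.loads(sidecar.read_text())
            series = thermo.ItcSeries(
                heats=df["heat_ucal"].to_numpy(),
                injection_volumes=df["volume_uL"].to_numpy() * 1e-6,
                cell_conc=meta["cell_conc"],
                syringe_conc=meta["syringe_conc"],
                cell_volume=meta["cell_volume"],
            )
            fit = thermo.fit_itc(series)
            rows.append(
                {
                    "dataset": Path(path).stem,
                    "method": "ITC",
                    "dH_kcal_mol": fit.dH,
                    "TdS_kcal_mol": fit.TdS,
                    "dG_kcal_mol": fit.dG,
                    "Tm_C": np.nan,
                    "Ka_1_M": fit.ka,
                    "n": fit.n,
                    "success": fit.success,
                    "message": fit.message,
                }
            )
        except Exception as err:
            errors[str(path)] = str(err)
    table = pd.DataFrame(rows)
    table.to_csv(out / "thermo_fits.csv", index=False)
    report = {
        "config_hash": config.hash,
        "seed": config.seed,
        "n_datasets": len(rows),
        "errors": errors,
        "artifacts": {"thermo_fits": "thermo_fits.csv"},
    }
    (out / "thermo_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    return report
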
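"""Pipeline configuration, run manifests and report assembly.

``run_pipeline`` ties the analysis stages together for a set of runs
declared in a JSON manifest, producing per-run and aggregate tables
(permeation counts/rates/conductance, G-loop passage summaries, CTD
rotation end states, PMF profile) as CSV/JSON in an output directory.
Every threshold used is logged into the report header so each number can
be reproduced by calling the underlying operation with the same
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, permeation, pmf, sf_mechanism, solvation
from .align import superpose
from .io import read_frames, read_topology
from .model import LabeledTrajectory, PoreAxisModel, Role, Selection

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

#: defaults for every tunable threshold; all are overridable from the
#: config file and all are echoed into the report header
DEFAULTS = {
    "committed_margin_A": 2.0,
    "hydration_cutoff_A": 3.5,
    "gloop_cylinder_radius_A": 4.0,
    "gloop_cylinder_height_A": 4.0,
    "gloop_gate_residues": [318, 319],
    "gloop_pair_residues": [316, 320],
    "sf_residues": [154, 158],
    "pmf_bin_width_A": 0.5,
    "sf_radius_A": 4.0,
    "tmd_residues": [95, 200],
    "ctd_residues": [201, 380],
    "wetting_threshold": 5,
}


@dataclass
class PipelineConfig:
    pore: PoreAxisModel
    thresholds: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        missing = [k for k in ("pore",) if k not in raw]
        if missing:
            raise ValueError(f"config is missing required fields: {missing}")
        p = raw["pore"]
        needed = ["z_intracellular_entrance", "z_gloop", "z_hbc", "z_site_boundaries"]
        absent = [k for k in needed if k not in p]
        if absent:
            raise ValueError(f"config pore section is missing fields: {absent}")
        pore = PoreAxisModel(
            z_intracellular_entrance=float(p["z_intracellular_entrance"]),
            z_gloop=float(p["z_gloop"]),
            z_hbc=float(p["z_hbc"]),
            z_site_boundaries=np.asarray(p["z_site_boundaries"], dtype=float),
            pore_radius=float(p.get("pore_radius", 8.0)),
            axis_direction=p.get("axis_direction", "+z"),
        )
        thresholds = dict(DEFAULTS)
        thresholds.update(raw.get("thresholds", {}))
        return cls(pore, thresholds)


@dataclass
class RunManifest:
    """One analysis run: where its frames live and how it was driven."""

    run_id: str
    topology: Path
    frames: Path
    duration_us: float
    voltage_mV: float | None = None
    restrained: bool = False
    seed: int | None = None

    @classmethod
    def load(cls, path: str | Path) -> list["RunManifest"]:
        entries = json.loads(Path(path).read_text())
        base = Path(path).parent
        runs = []
        seen = set()
        for e in entries:
            if e["run_id"] in seen:
                raise ValueError(f"duplicate run id {e['run_id']!r}")
            seen.add(e["run_id"])
            if float(e["duration_us"]) <= 0:
                raise ValueError(f"run {e['run_id']}: duration must be positive")
            runs.append(
                cls(
                    run_id=e["run_id"],
                    topology=base / e["topology"],
                    frames=base / e["frames"],
                    duration_us=float(e["duration_us"]),
                    voltage_mV=e.get("voltage_mV"),
                    restrained=bool(e.get("restrained", False)),
                    seed=e.get("seed"),
                )
            )
        return runs


def _sf_selection(th: dict) -> Selection:
    lo, hi = th["sf_residues"]
    return Selection(role=Role.PROTEIN, residue_number=range(lo, hi + 1), atom_name="CA")


def analyse_run(
    traj: LabeledTrajectory, cfg: PipelineConfig, run: RunManifest
) -> dict:
    """All per-run quantities of the report bundle, from one trajectory."""
    th = cfg.thresholds
    pore = cfg.pore
    sf_sel = _sf_selection(th)
    if traj.select(sf_sel).size >= 3:
        traj = superpose(traj, sf_sel)

    traces = permeation.ion_traces(traj, pore)
    events = []
    for tr in traces:
        events.extend(
            permeation.detect_events(
                tr, "SF_full", pore, th["committed_margin_A"],
                periodic_box_z=float(traj.box[0, 2]),
            )
        )
    outward = [e for e in events if e.direction == "outward"]

    lo, hi = th["gloop_pair_residues"]
    try:
        gloop = solvation.gloop_pass_snapshots(
            traj,
            cylinder_radius=th["gloop_cylinder_radius_A"],
            cylinder_height=th["gloop_cylinder_height_A"],
            gate_residues=tuple(th["gloop_gate_residues"]),
            pair_residues=range(lo, hi + 1),
            hydration_cutoff=th["hydration_cutoff_A"],
        )
    except ValueError:
        gloop = None

    rotation_deg = np.nan
    tmd = Selection(role=Role.PROTEIN, residue_number=range(th["tmd_residues"][0], th["tmd_residues"][1] + 1))
    ctd = Selection(role=Role.PROTEIN, residue_number=range(th["ctd_residues"][0], th["ctd_residues"][1] + 1))
    tmd_a = Selection(role=Role.PROTEIN, subunit="A", residue_number=range(th["tmd_residues"][0], th["tmd_residues"][1] + 1))
    ctd_a = Selection(role=Role.PROTEIN, subunit="A", residue_number=range(th["ctd_residues"][0], th["ctd_residues"][1] + 1))
    if all(traj.select(s).size for s in (tmd, ctd, tmd_a, ctd_a)):
        series = geometry.ctd_rotation(traj, tmd, ctd, tmd_a, ctd_a)
        rotation_deg = float(series.values[-1])  # end-state convention

    centers, n = pmf.occupancy_profile(traj, pore, th["pmf_bin_width_A"])
    profile = None
    if np.any(n > 0):
        profile = pmf.boltzmann_invert(centers, n)

    states = sf_mechanism.assign_sites(traj, pore, th["sf_radius_A"])
    coperm, _ = sf_mechanism.water_copermeation(traj, pore, outward,
                                               committed_margin=th["committed_margin_A"])
    calls = sf_mechanism.classify_mechanism(states, outward, coperm)

    return {
        "events": outward,
        "n_events": len(outward),
        "gloop": gloop,
        "rotation_deg": rotation_deg,
        "pmf": profile,
        "mechanisms": {
            m: sum(1 for c in calls if c.mechanism == m)
            for m in ("direct_knock_on", "water_mediated", "mixed")
        },
    }


def run_pipeline(
    config_path: str | Path, manifest_path: str | Path, out_dir: str | Path
) -> dict:
    """Execute the full analysis over a manifest and write the report bundle."""
    cfg = PipelineConfig.from_yaml(config_path)
    runs = RunManifest.load(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_run = {}
    for run in runs:
        if not run.frames.exists():
            raise FileNotFoundError(f"run {run.run_id}: frames file {run.frames} not found")
        system = read_topology(run.topology)
        traj = read_frames(run.frames, system)
        per_run[run.run_id] = analyse_run(traj, cfg, run)

    counts = {r.run_id: per_run[r.run_id]["n_events"] for r in runs}
    durations = {r.run_id: r.duration_us for r in runs}
    voltages = {r.run_id: r.voltage_mV for r in runs}
    restrained = {r.run_id: r.restrained for r in runs}
    rates = permeation.count_and_rates(counts, durations, voltages, restrained)

    events_rows = rates.per_run.copy()
    events_rows.to_csv(out / "events.csv", index=False)
    rates.group_stats.to_csv(out / "rates_summary.csv", index=False)

    gloop_rows = []
    for r in runs:
        g = per_run[r.run_id]["gloop"]
        gloop_rows.append(
            {
                "run": r.run_id,
                "mean_distance_A": g.mean_narrower_pair_distance if g and g.defined else np.nan,
                "mean_waters": g.mean_hydration if g and g.defined else np.nan,
                "n_snapshots": len(g.snapshots) if g else 0,
            }
        )
    pd.DataFrame(gloop_rows).to_csv(out / "gloop_passage.csv", index=False)

    pd.DataFrame(
        [{"run": r.run_id, "angle_deg": per_run[r.run_id]["rotation_deg"]} for r in runs]
    ).to_csv(out / "ctd_rotation.csv", index=False)

    profiles = [p["pmf"] for p in per_run.values() if p["pmf"] is not None]
    if len(profiles) >= 2:
        agg = pmf.aggregate_runs(profiles)
        pd.DataFrame(
            {
                "z_center": agg.z_centers,
                "n": agg.n,
                "G_kcal_mol": agg.G,
                "sd": agg.sd,
                "masked": agg.mask,
            }
        ).to_csv(out / "pmf.csv", index=False)

    mech = {rid: p["mechanisms"] for rid, p in per_run.items()}
    (out / "mechanism.json").write_text(json.dumps(mech, indent=1))

    header = ["# analysis report", "# thresholds used:"]
    header += [f"#   {k} = {v}" for k, v in sorted(cfg.thresholds.items())]
    header += [f"# runs: {', '.join(r.run_id for r in runs)}",
               f"# total outward filter events: {rates.total_events}"]
    (out / "report_header.txt").write_text("\n".join(header) + "\n")

    return {
        "rates": rates,
        "per_run": per_run,
        "total_events": rates.total_events,
    }
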
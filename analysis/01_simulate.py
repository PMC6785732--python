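"""Materialize the synthetic pore runs used by the downstream analyses.

Writes, under scratch/synthetic/ (regenerable, excluded from version
control): three scheduled-flux runs (planted permeation rates 8, 15 and 22
events/us, 0.15 us each at 100-ps frames) as topology PDB + columnar
frames + ground-truth JSON, plus a run manifest for the file-based
pipeline driver.  The later scripts regenerate the same runs in memory
from analysis/common.py, so this step is optional; it exists to make the
raw trajectories inspectable and to exercise the I/O path end to end.
"""

import json

from permeon.io import write_frames, write_topology
from permeon.synthetic import generate

from common import FLUX_RATES, SCRATCH, flux_config


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rate in enumerate(FLUX_RATES):
        cfg = flux_config(i)
        traj, truth = generate(cfg)
        stem = SCRATCH / f"flux_run{i}"
        write_topology(traj.particles, traj.coords[0], traj.box[0], stem.with_suffix(".pdb"))
        write_frames(traj, stem.with_suffix(".frames"))
        truth.to_json(stem.with_suffix(".truth.json"))
        duration_us = cfg.n_frames * cfg.stride_ps / 1e6
        manifest.append({
            "run_id": f"flux_run{i}",
            "topology": stem.with_suffix(".pdb").name,
            "frames": stem.with_suffix(".frames").name,
            "duration_us": duration_us,
            "voltage_mV": 580.0,
            "restrained": i == 2,
            "seed": cfg.seed,
        })
        print(f"flux_run{i}: planted rate {rate}/us -> "
              f"{len(truth.planted_events)} events in {duration_us} us, "
              f"{traj.n_particles} particles x {traj.n_frames} frames")
    (SCRATCH / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"manifest written to {SCRATCH / 'manifest.json'}")


if __name__ == "__main__":
    main()
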
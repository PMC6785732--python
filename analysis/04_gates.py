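"""Gate geometry, wetting, and G-loop passage statistics.

On a free-diffusion run with flickering gates: minimum-distance series of
the opposing G-loop and HBC gate subunits (narrower-pair convention),
distance histograms with the fraction of frames wider than the mean
passage diameter, cavity water counts with the wet fraction, and the
G-loop pass-cylinder summary (mean narrower-pair distance and ion
hydration while an ion sits in the gate).  The bundled reference tables
(per-run passage distances and end-state CTD rotations) are summarized
alongside.

Outputs under results/tables/: gate_histograms.csv, gate_summary.csv,
reference_gloop.csv, reference_rotation.csv.
"""

import numpy as np
import pandas as pd

from permeon import geometry, solvation
from permeon.datasets import ctd_rotation_end_states, gloop_passage
from permeon.model import Role, Selection
from permeon.synthetic import default_pore, generate

from common import RESULTS, gated_config


def gate_series(traj, resids):
    pair_ac = (Selection(role=Role.PROTEIN, subunit="A", residue_number=resids),
               Selection(role=Role.PROTEIN, subunit="C", residue_number=resids))
    pair_bd = (Selection(role=Role.PROTEIN, subunit="B", residue_number=resids),
               Selection(role=Role.PROTEIN, subunit="D", residue_number=resids))
    return geometry.narrower_pair_series(traj, pair_ac, pair_bd)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    pore = default_pore()
    cfg = gated_config()
    traj, truth = generate(cfg)

    gloop = gate_series(traj, range(316, 321))
    hbc = gate_series(traj, [192])
    rows = []
    for name, series in (("gloop", gloop), ("hbc", hbc)):
        h = geometry.histogram(series, 0.5, threshold=6.4)
        for edge, count in zip(h.bin_left_edges, h.counts):
            rows.append({"gate": name, "bin_left_A": edge, "count": int(count)})
        print(f"{name} gate: mean narrower-pair distance {np.mean(series.values):.2f} A, "
              f"{100 * h.fraction_above:.1f}% of frames wider than 6.4 A")
    pd.DataFrame(rows).to_csv(RESULTS / "gate_histograms.csv", index=False)

    cavity = solvation.cavity_water_count(traj, pore.z_hbc, pore.sf_lower,
                                          pore.pore_radius)
    _, wet_frac = solvation.wetting_state(cavity, threshold=20)
    passes = solvation.gloop_pass_snapshots(traj)
    summary = {
        "gloop_mean_distance_A": float(np.mean(gloop.values)),
        "gloop_open_fraction_truth": truth.gate_open_fraction.get("gloop", np.nan),
        "hbc_open_fraction_truth": truth.gate_open_fraction.get("hbc", np.nan),
        "cavity_mean_waters": float(cavity.values.mean()),
        "cavity_wet_fraction": wet_frac,
        "gloop_pass_snapshots": len(passes.snapshots),
        "gloop_pass_mean_distance_A": passes.mean_narrower_pair_distance,
        "gloop_pass_mean_hydration": passes.mean_hydration,
    }
    pd.DataFrame([summary]).to_csv(RESULTS / "gate_summary.csv", index=False)
    print(f"cavity: {summary['cavity_mean_waters']:.0f} waters on average, "
          f"wet fraction {wet_frac:.2f}")
    if passes.defined:
        print(f"G-loop passes: {len(passes.snapshots)} snapshots, mean distance "
              f"{passes.mean_narrower_pair_distance:.2f} A, mean hydration "
              f"{passes.mean_hydration:.2f} waters")

    gl = gloop_passage()
    gl.to_csv(RESULTS / "reference_gloop.csv", index=False)
    rot = ctd_rotation_end_states()
    rot.to_csv(RESULTS / "reference_rotation.csv", index=False)
    print(f"reference tables: unrestrained passage mean "
          f"{gl.loc[~gl['restrained'], 'mean_distance_A'].mean():.1f} A; "
          f"largest CTD rotation {rot['angle_deg'].abs().max():.1f} deg "
          f"(all counterclockwise)")


if __name__ == "__main__":
    main()
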
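"""Permeation counts, rates and conductance.

Part A recomputes the summary statistics of the bundled reference run
table (fourteen 1-us GIRK2 field simulations): per-run rates, restrained
vs unrestrained group means with sample SDs, and single-channel
conductances g = N e / (t V).  Part B detects committed filter crossings
on the synthetic scheduled-flux runs and compares them with the planted
ground truth.

Outputs: results/tables/reference_rates.csv, reference_rate_groups.csv,
synthetic_rates.csv.
"""

import numpy as np
import pandas as pd

from permeon import permeation
from permeon.datasets import md_field_runs
from permeon.synthetic import default_pore, generate

from common import FLUX_RATES, RESULTS, flux_config


def reference_rates() -> None:
    runs = md_field_runs()
    summary = permeation.count_and_rates(
        dict(zip(runs["run"], runs["events"])),
        dict(zip(runs["run"], runs["duration_us"])),
        dict(zip(runs["run"], runs["voltage_mV"])),
        dict(zip(runs["run"], runs["restrained"])),
    )
    summary.per_run.to_csv(RESULTS / "reference_rates.csv", index=False)
    summary.group_stats.to_csv(RESULTS / "reference_rate_groups.csv", index=False)
    stats = summary.group_stats.set_index("group")
    print(f"reference runs: {summary.total_events} filter permeations in "
          f"{runs['duration_us'].sum():.0f} us")
    print(f"  unrestrained: {stats.loc['unrestrained', 'mean_rate_per_us']:.1f} "
          f"+/- {stats.loc['unrestrained', 'sd_rate_per_us']:.1f} events/us")
    print(f"  restrained:   {stats.loc['restrained', 'mean_rate_per_us']:.0f} "
          f"+/- {stats.loc['restrained', 'sd_rate_per_us']:.0f} events/us")
    print(f"  conductance:  up to {summary.per_run['conductance_pS'].max():.1f} pS")


def synthetic_rates() -> None:
    pore = default_pore()
    rows = []
    for i, rate in enumerate(FLUX_RATES):
        cfg = flux_config(i)
        traj, truth = generate(cfg)
        detected = 0
        for tr in permeation.ion_traces(traj, pore):
            detected += sum(
                e.direction == "outward"
                for e in permeation.detect_events(
                    tr, "SF_full", pore, periodic_box_z=float(traj.box[0, 2]))
            )
        duration_us = cfg.n_frames * cfg.stride_ps / 1e6
        rows.append({
            "run": f"flux_run{i}",
            "configured_rate_per_us": rate,
            "planted_events": len(truth.planted_events),
            "detected_events": detected,
            "detected_rate_per_us": detected / duration_us,
            "poisson_3sigma": 3 * np.sqrt(rate * duration_us),
        })
        print(f"flux_run{i}: configured {rate}/us, planted "
              f"{rows[-1]['planted_events']}, detected {detected}")
    pd.DataFrame(rows).to_csv(RESULTS / "synthetic_rates.csv", index=False)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    reference_rates()
    synthetic_rates()


if __name__ == "__main__":
    main()
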
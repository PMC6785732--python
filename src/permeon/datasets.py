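"""Bundled reference summaries of a microsecond MD study of GIRK2 (Kir3.2).

These small tables are the per-run summary statistics of a published set of
molecular-dynamics simulations of the PIP2-bound GIRK2 channel under an
applied transmembrane field: permeation-event counts per run, G-loop gate
geometry/hydration during ion passage, and end-state rotation of the
cytoplasmic domain.  They serve as reference inputs for the rate,
conductance and gate-statistics calculations, and as fixtures for worked
examples.  Five of the fourteen 1-microsecond runs had the G-loop gate
residues (G318/M319) harmonically restrained in an open conformation.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["md_field_runs", "md_equilibration_runs", "gloop_passage", "ctd_rotation_end_states"]


def md_field_runs() -> pd.DataFrame:
    """The fourteen 1-us runs with applied field: events, voltage, restraints.

    ``events`` counts full selectivity-filter permeations; ``voltage_mV``
    is the transmembrane potential implied by the applied field over the
    box (20 or 40 mV/nm across ~14.5 nm).
    """
    rows = [
        ("1us_run1", 1.0, 580, False, 30, "S1,S2,S4"),
        ("1us_run2", 1.0, 580, False, 9, "S1,S2,S4"),
        ("1us_run3", 1.0, 580, False, 0, "S1,S2,S4"),
        ("1us_run4", 1.0, 580, False, 8, "S2,S3"),
        ("1us_run5", 1.0, 580, False, 27, "S2,S3"),
        ("1us_run6", 1.0, 580, False, 20, "S2,S3"),
        ("1us_run7", 1.0, 580, False, 15, "S2,S3"),
        ("1us_run8", 1.0, 580, True, 24, "S2,S3"),
        ("1us_run9", 1.0, 580, True, 19, "S2,S3"),
        ("1us_run10", 1.0, 580, True, 27, "S2,S3"),
        ("1us_run11", 1.0, 290, False, 0, "S2,S3"),
        ("1us_run12", 1.0, 290, False, 19, "S2,S3"),
        ("1us_run13", 1.0, 290, True, 27, "S2,S3"),
        ("1us_run14", 1.0, 290, True, 3, "S2,S3"),
    ]
    return pd.DataFrame(
        rows,
        columns=["run", "duration_us", "voltage_mV", "restrained", "events", "start_sites"],
    )


def md_equilibration_runs() -> pd.DataFrame:
    """The ten 200-ns unbiased runs and their HBC-gate permeation counts."""
    rows = [(f"200ns_run{i}", 0.2, None, False, n) for i, n in enumerate(
        [0, 0, 0, 0, 0, 1, 1, 1, 0, 0], start=1
    )]
    return pd.DataFrame(
        rows, columns=["run", "duration_us", "voltage_mV", "restrained", "hbc_events"]
    )


def gloop_passage() -> pd.DataFrame:
    """Mean G-loop narrower-pair distance and ion hydration during passage, per run."""
    rows = [
        ("1us_run1", 5.90, 4.73, False),
        ("1us_run2", 6.47, 5.66, False),
        ("1us_run3", 6.75, 5.64, False),
        ("1us_run4", 6.65, 5.54, False),
        ("1us_run5", 6.40, 5.34, False),
        ("1us_run6", 6.37, 5.24, False),
        ("1us_run7", 6.84, 5.71, False),
        ("1us_run8", 7.19, 5.69, True),
        ("1us_run9", 7.13, 5.88, True),
        ("1us_run10", 7.18, 5.77, True),
        ("1us_run11", 6.05, 4.68, False),
        ("1us_run12", 6.05, 5.47, False),
        ("1us_run13", 7.10, 5.93, True),
        ("1us_run14", 7.14, 5.78, True),
    ]
    return pd.DataFrame(
        rows, columns=["run", "mean_distance_A", "mean_waters", "restrained"]
    )


def ctd_rotation_end_states() -> pd.DataFrame:
    """End-state CTD rotation angle per run, degrees (counterclockwise negative)."""
    rows = [
        ("1us_run1", -3.89, False),
        ("1us_run2", -3.90, False),
        ("1us_run3", -0.09, False),
        ("1us_run4", -4.31, False),
        ("1us_run5", -4.46, False),
        ("1us_run6", -2.88, False),
        ("1us_run7", -4.46, False),
        ("1us_run8", -2.21, True),
        ("1us_run9", -4.66, True),
        ("1us_run10", -4.32, True),
        ("1us_run11", -2.91, False),
        ("1us_run12", -4.29, False),
        ("1us_run13", -5.60, True),
        ("1us_run14", -1.90, True),
    ]
    return pd.DataFrame(rows, columns=["run", "angle_deg", "restrained"])
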
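"""Shared run definitions for the analysis scripts.

The numbered scripts regenerate these desk-scale synthetic runs in memory
(generation takes seconds and is fully seeded), so each script is
self-contained; 01_simulate.py additionally materializes them to scratch/
for inspection and for exercising the file-based pipeline driver.
"""

from pathlib import Path

import numpy as np

from permeon.synthetic import SyntheticPoreConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "tables"
SCRATCH = ROOT / "scratch" / "synthetic"

Z_LIMITS = (-40.0, 31.0)

#: scheduled-flux runs: planted permeation rates in events/us; the third
#: run plays the role of a "restrained" run in the report tables
FLUX_RATES = (8.0, 15.0, 22.0)


def flux_config(i: int) -> SyntheticPoreConfig:
    return SyntheticPoreConfig(seed=100 + i, n_frames=4000, stride_ps=100.0,
                               n_ions=4, n_waters=40, scaffold=True,
                               target_rate_events_per_us=FLUX_RATES[i])


def planted_potential() -> tuple[np.ndarray, np.ndarray]:
    """Double-well test potential: barriers of 2.0 and 1.5 kcal/mol."""
    zg = np.linspace(*Z_LIMITS, 285)
    U = 2.0 * np.exp(-0.5 * ((zg + 12.0) / 3.0) ** 2) \
        + 1.5 * np.exp(-0.5 * ((zg - 13.0) / 2.5) ** 2)
    return zg, U


def equilibrium_config(seed: int = 11, n_frames: int = 50_000) -> SyntheticPoreConfig:
    zg, U = planted_potential()
    return SyntheticPoreConfig(seed=seed, n_frames=n_frames, potential=(zg, U),
                               voltage_mV=0.0, n_ions=4, ion_diffusion=0.5,
                               n_waters=0, gate_flicker={}, sf_single_occupancy=False,
                               scaffold=False, boundary="reflecting", z_limits=Z_LIMITS)


def gated_config(seed: int = 31, n_frames: int = 3000) -> SyntheticPoreConfig:
    """Free diffusion under field with flickering gates and waters."""
    return SyntheticPoreConfig(seed=seed, n_frames=n_frames, stride_ps=20.0,
                               voltage_mV=580.0, n_ions=8, n_waters=480,
                               scaffold=True, boundary="periodic",
                               z_limits=Z_LIMITS)
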
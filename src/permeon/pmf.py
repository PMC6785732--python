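"""Effective-biased potential of mean force by Boltzmann inversion.

The free-energy profile along the pore is obtained directly from the
time-averaged ion occupancy n(z) of 0.5-Angstrom slices between the
intracellular entrance and the extracellular end of the selectivity
filter:  G(z) = -kT ln n(z), shifted so its minimum is zero.  Because the
occupancy is sampled under an applied field, the profile includes the bias
by construction ("effective-biased"); no reweighting is attempted.
Zero-count bins are masked rather than pseudo-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import LabeledTrajectory, PoreAxisModel, Role
from .solvation import occupancy_map
from .units import TEMPERATURE_K, kT

__all__ = ["PMFProfile", "occupancy_profile", "boltzmann_invert", "aggregate_runs"]

DEFAULT_BIN_WIDTH = 0.5


@dataclass
class PMFProfile:
    """Free-energy profile on a fixed z grid.

    ``mask`` flags bins with zero occupancy, which carry no G value.
    ``sd`` is filled by :func:`aggregate_runs` (across-run spread).
    """

    z_centers: np.ndarray
    n: np.ndarray  # mean ion count per slice
    G: np.ndarray  # kcal/mol, min-shifted; NaN where masked
    mask: np.ndarray  # True where the bin is unsampled
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.z_centers) == len(self.n) == len(self.G) == len(self.mask)):
            raise ValueError("profile arrays must share one grid")


def occupancy_profile(
    traj: LabeledTrajectory,
    pore: PoreAxisModel,
    bin_width: float = DEFAULT_BIN_WIDTH,
    z_range: tuple[float, float] | None = None,
    radius: float | None = None,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged ion count per z-slice of the pore.

    The trajectory should already be superposed on the selectivity filter
    so the slices track the channel.  Returns (bin centers, n).
    """
    if z_range is None:
        z_range = (
            float(pore._orient(pore.z_intracellular_entrance)),
            pore.sf_upper,
        )
    m = occupancy_map(traj, pore, Role.ION, z_range, bin_width, radius=radius, **kwargs)
    return m.bin_centers, m.mean_counts


def boltzmann_invert(
    z_centers: np.ndarray,
    n: np.ndarray,
    temperature: float = TEMPERATURE_K,
) -> PMFProfile:
    """G(z) = -kT ln n(z), min-shifted; kT = 0.616 kcal/mol at 310 K."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("occupancies must be non-negative")
    mask = n <= 0
    if mask.all():
        raise ValueError("all bins have zero occupancy; nothing to invert")
    G = np.full_like(n, np.nan)
    G[~mask] = -kT(temperature) * np.log(n[~mask])
    G[~mask] -= np.nanmin(G)
    return PMFProfile(np.asarray(z_centers, dtype=float), n, G, mask)


def aggregate_runs(profiles: list[PMFProfile]) -> PMFProfile:
    """Per-bin mean and sample SD of G across runs.

    Bins are aggregated only where unmasked in at least two runs; the mean
    profile is re-shifted to a zero minimum afterwards.
    """
    if len(profiles) < 2:
        raise ValueError("aggregate_runs needs at least two runs")
    grid = profiles[0].z_centers
    for p in profiles[1:]:
        if len(p.z_centers) != len(grid) or not np.allclose(p.z_centers, grid):
            raise ValueError("profiles are not on identical bin grids")
    G = np.stack([p.G for p in profiles])  # NaN where masked
    n_ok = np.sum(~np.isnan(G), axis=0)
    mask = n_ok < 2
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, np.nan, np.nanmean(G, axis=0))
        sd = np.where(mask, np.nan, np.nanstd(G, axis=0, ddof=1))
    if np.isfinite(mean).any():
        mean -= np.nanmin(mean)
    n_mean = np.stack([p.n for p in profiles]).mean(axis=0)
    return PMFProfile(grid, n_mean, mean, mask, sd=sd)
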
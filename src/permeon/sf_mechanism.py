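"""Selectivity-filter site occupancy and knock-on mechanism classification.

Each frame is summarized as a five-letter string over the sites S4..S0
(intracellular to extracellular) with alphabet K (ion), W (water oxygen)
and 0 (empty); an ion wins over a co-resident water.  An event is called
direct knock-on when no water symbol ever separates two ions during the
transition frames and no water co-permeates; it is water mediated when
every ion-ion gap holds a water; anything else is mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import unwrap_z
from .model import LabeledTrajectory, PoreAxisModel, Role, Selection, SITES
from .permeation import IonTrace, PermeationEvent, detect_events
from .solvation import pore_axis_xy

__all__ = [
    "SiteOccupancyStates",
    "MechanismCall",
    "assign_sites",
    "water_copermeation",
    "classify_mechanism",
    "site_ion_occupancy_profile",
]

#: radial cutoff for a particle to be considered inside the filter, Angstrom
SF_RADIUS_DEFAULT = 4.0

#: tolerance around an event window when pairing co-permeating waters, ps
COPERMEATION_TOLERANCE_PS = 1000.0


@dataclass
class SiteOccupancyStates:
    """Per-frame site symbols; ``states[f, i]`` is site S4+i at frame f."""

    times: np.ndarray
    symbols: np.ndarray  # (n_frames, 5) of 'K' | 'W' | '0'
    multi_occupancy: np.ndarray  # (n_frames,) bool: any site held >1 particle

    def strings(self) -> list[str]:
        """One 'KWK00'-style string per frame, ordered S4..S0."""
        return ["".join(row) for row in self.symbols]


def assign_sites(
    traj: LabeledTrajectory,
    pore: PoreAxisModel,
    sf_radius: float = SF_RADIUS_DEFAULT,
    sf_sel: Selection | str | None = None,
) -> SiteOccupancyStates:
    """Assign ions and water oxygens to the five filter sites per frame.

    Site windows are left-closed (a particle at a boundary belongs to the
    lower site).  Ions take priority over waters within a site.
    """
    windows = pore.site_windows()
    lows = np.array([windows[s][0] for s in SITES])
    highs = np.array([windows[s][1] for s in SITES])
    if np.any(lows[1:] < highs[:-1] - 1e-9):
        raise ValueError("site windows overlap")

    axis = pore_axis_xy(traj, sf_sel)
    symbols = np.full((traj.n_frames, 5), "0", dtype="<U1")
    occupants = np.zeros((traj.n_frames, 5), dtype=int)
    for role, sym in ((Role.WATER_OXYGEN, "W"), (Role.ION, "K")):
        cols = traj.select(Selection(role=role))
        if cols.size == 0:
            continue
        d = traj.coords[:, cols, :2] - axis[:, None, :]
        r2 = np.einsum("fij,fij->fi", d, d)
        z = np.asarray(pore._orient(traj.coords[:, cols, 2]))
        inside = r2 <= sf_radius**2
        for i in range(5):
            in_site = inside & (z >= lows[i]) & (z < highs[i])
            n = in_site.sum(axis=1)
            occupants[:, i] += n
            symbols[n > 0, i] = sym  # ions assigned last, so K overrides W
    return SiteOccupancyStates(traj.times.copy(), symbols, occupants.max(axis=1) > 1)


def water_copermeation(
    traj: LabeledTrajectory,
    pore: PoreAxisModel,
    events: list[PermeationEvent],
    tolerance_ps: float = COPERMEATION_TOLERANCE_PS,
    committed_margin: float = 2.0,
) -> tuple[list[int], dict[int, np.ndarray]]:
    """Waters whose own traces commit across the filter during each event.

    Returns per-event co-permeating water counts plus the z-traces of all
    waters that ever enter the filter window (for trace plots).
    """
    cols = traj.select(Selection(role=Role.WATER_OXYGEN))
    water_events = []
    sf_traces: dict[int, np.ndarray] = {}
    lo, hi = pore.sf_lower, pore.sf_upper
    for c in cols:
        z = unwrap_z(traj.coords[:, c, 2], traj.box[:, 2])
        zo = pore._orient(z)
        if np.any((zo >= lo) & (zo <= hi)):
            sf_traces[traj.particles[c].id] = z
        trace = IonTrace(traj.particles[c].id, traj.times, z, np.empty(len(z), dtype=object))
        water_events.extend(detect_events(trace, "SF_full", pore, committed_margin))
    counts = []
    for ev in events:
        lo_t, hi_t = ev.entry_time - tolerance_ps, ev.exit_time + tolerance_ps
        n = sum(1 for w in water_events if w.exit_time >= lo_t and w.entry_time <= hi_t)
        counts.append(n)
    return counts, sf_traces


@dataclass
class MechanismCall:
    event: PermeationEvent
    mechanism: str  # direct_knock_on | water_mediated | mixed
    copermeating_waters: int


def _gaps_with_water(state_row: np.ndarray) -> tuple[int, int]:
    """(number of ion-ion gaps, gaps containing at least one W) in one frame."""
    ks = np.flatnonzero(state_row == "K")
    gaps = wet = 0
    for a, b in zip(ks[:-1], ks[1:]):
        gaps += 1
        if np.any(state_row[a + 1 : b] == "W"):
            wet += 1
    return gaps, wet


def classify_mechanism(
    states: SiteOccupancyStates,
    events: list[PermeationEvent],
    copermeation_counts: list[int] | None = None,
) -> list[MechanismCall]:
    """Call the conduction mechanism of each filter permeation event."""
    if copermeation_counts is None:
        copermeation_counts = [0] * len(events)
    calls = []
    for ev, n_wat in zip(events, copermeation_counts):
        f0 = max(ev.entry_frame, 0)
        f1 = min(ev.exit_frame, states.symbols.shape[0] - 1)
        total_gaps = wet_gaps = 0
        for f in range(f0, f1 + 1):
            g, w = _gaps_with_water(states.symbols[f])
            total_gaps += g
            wet_gaps += w
        if wet_gaps == 0 and n_wat == 0:
            mech = "direct_knock_on"
        elif total_gaps > 0 and wet_gaps == total_gaps:
            mech = "water_mediated"
        else:
            mech = "mixed"
        calls.append(MechanismCall(ev, mech, n_wat))
    return calls


def site_ion_occupancy_profile(states: SiteOccupancyStates) -> dict[str, float]:
    """Fraction of frames each site holds an ion."""
    if states.symbols.shape[0] == 0:
        raise ValueError("empty state series")
    return {
        site: float(np.mean(states.symbols[:, i] == "K")) for i, site in enumerate(SITES)
    }
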
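"""Water occupancy, wetting, ion hydration and G-loop passage extraction.

The pore axis for radial tests follows the instantaneous x-y center of the
selectivity-filter atoms when such a selection is available (so slow channel
drift is tracked); otherwise it falls back to the box center.  Distance
boundaries are closed: a particle at exactly the cutoff counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FrameSeries, narrower_pair_series
from .model import LabeledTrajectory, PoreAxisModel, Role, Selection

__all__ = [
    "pore_axis_xy",
    "OccupancyMap",
    "water_occupancy_map",
    "cavity_water_count",
    "hydration_number",
    "GloopPassSnapshot",
    "GloopPassSummary",
    "gloop_pass_snapshots",
    "wetting_state",
]

SF_SELECTION_DEFAULT = Selection(role=Role.PROTEIN, residue_number=range(154, 159))


def pore_axis_xy(traj: LabeledTrajectory, sf_sel: Selection | str | None = None) -> np.ndarray:
    """Per-frame (x, y) of the pore axis.

    Uses the x-y centroid of the selectivity-filter selection when it
    resolves; otherwise the box center.
    """
    if sf_sel is None:
        sf_sel = SF_SELECTION_DEFAULT
    idx = traj.select(sf_sel) if sf_sel is not None else np.array([], dtype=int)
    if idx.size:
        return traj.coords[:, idx, :2].mean(axis=1)
    return traj.box[:, :2] / 2.0


def _radial2(traj: LabeledTrajectory, cols: np.ndarray, axis_xy: np.ndarray) -> np.ndarray:
    d = traj.coords[:, cols, :2] - axis_xy[:, None, :]
    return np.einsum("fij,fij->fi", d, d)


@dataclass
class OccupancyMap:
    """Time-resolved particle counts in z-slices of the pore cylinder."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    per_frame_counts: np.ndarray  # (n_frames, n_bins)
    role: Role
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_counts(self) -> np.ndarray:
        """Time-averaged count per bin."""
        return self.per_frame_counts.mean(axis=0)

    @property
    def mean_per_angstrom(self) -> np.ndarray:
        """Time-averaged count per 1 Angstrom of pore axis."""
        return self.mean_counts / self.bin_width


def occupancy_map(
    traj: LabeledTrajectory,
    pore: PoreAxisModel,
    role: Role,
    z_range: tuple[float, float],
    bin_width: float,
    radius: float | None = None,
    axis_xy: np.ndarray | None = None,
    sf_sel: Selection | str | None = None,
) -> OccupancyMap:
    """Count particles of ``role`` inside the pore cylinder, binned along z."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z_lo, z_hi = z_range
    if z_lo >= z_hi:
        raise ValueError("empty z range")
    radius = pore.pore_radius if radius is None else radius
    cols = traj.select(Selection(role=role))
    n_bins = int(np.ceil((z_hi - z_lo) / bin_width - 1e-9))
    edges = z_lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((traj.n_frames, n_bins), dtype=np.int32)
    if cols.size and radius > 0:
        if axis_xy is None:
            axis_xy = pore_axis_xy(traj, sf_sel)
        r2 = _radial2(traj, cols, axis_xy)
        z = np.asarray(pore._orient(traj.coords[:, cols, 2]))
        inside = r2 <= radius**2
        bins = np.floor((z - z_lo) / bin_width).astype(int)
        ok = inside & (bins >= 0) & (bins < n_bins)
        for f in range(traj.n_frames):
            counts[f] = np.bincount(bins[f][ok[f]], minlength=n_bins)
    return OccupancyMap(edges, counts, role, bin_width)


def water_occupancy_map(
    traj: LabeledTrajectory,
    pore: PoreAxisModel,
    z_range: tuple[float, float],
    bin_width: float = 1.0,
    **kwargs,
) -> OccupancyMap:
    """Water-oxygen occupancy along the pore (1-Angstrom bins by default)."""
    return occupancy_map(traj, pore, Role.WATER_OXYGEN, z_range, bin_width, **kwargs)


def cavity_water_count(
    traj: LabeledTrajectory,
    z_low: float,
    z_high: float,
    pore_radius: float,
    axis_xy: np.ndarray | None = None,
    sf_sel: Selection | str | None = None,
) -> FrameSeries:
    """Number of water oxygens in a cylinder slice, per frame."""
    if z_low >= z_high:
        raise ValueError("z_low must be below z_high")
    cols = traj.select(Selection(role=Role.WATER_OXYGEN))
    if cols.size == 0:
        return FrameSeries(traj.times, np.zeros(traj.n_frames, dtype=int), "cavity_waters")
    if axis_xy is None:
        axis_xy = pore_axis_xy(traj, sf_sel)
    r2 = _radial2(traj, cols, axis_xy)
    z = traj.coords[:, cols, 2]
    inside = (r2 <= pore_radius**2) & (z >= z_low) & (z <= z_high)
    return FrameSeries(traj.times, inside.sum(axis=1), "cavity_waters")


def hydration_number(traj: LabeledTrajectory, ion_id: int, cutoff: float = 3.5) -> FrameSeries:
    """Water oxygens within ``cutoff`` of the ion (closed boundary, minimum image)."""
    col = traj.index_of(ion_id)
    wat = traj.select(Selection(role=Role.WATER_OXYGEN))
    counts = np.zeros(traj.n_frames, dtype=int)
    if wat.size:
        d = traj.coords[:, wat, :] - traj.coords[:, col, None, :]
        d -= traj.box[:, None, :] * np.round(d / traj.box[:, None, :])
        dist2 = np.einsum("fij,fij->fi", d, d)
        counts = (dist2 <= cutoff**2).sum(axis=1)
    return FrameSeries(traj.times, counts, f"hydration_{ion_id}")


@dataclass
class GloopPassSnapshot:
    frame: int
    ion_id: int
    narrower_pair_distance: float
    hydration_count: int


@dataclass
class GloopPassSummary:
    snapshots: list[GloopPassSnapshot]
    mean_narrower_pair_distance: float
    mean_hydration: float
    defined: bool


def gloop_pass_snapshots(
    traj: LabeledTrajectory,
    cylinder_radius: float = 4.0,
    cylinder_height: float = 4.0,
    gate_residues: tuple[int, ...] = (318, 319),
    pair_residues: range = range(316, 321),
    hydration_cutoff: float = 3.5,
) -> GloopPassSummary:
    """Extract snapshots with an ion inside the G-loop gate cylinder.

    The cylinder (default 4-Angstrom radius, 4-Angstrom height) is centered
    each frame on the center of mass of the gate-forming residues (G318 and
    M319 analogs) over all four subunits.  For every (frame, ion) inside,
    the narrower opposing-pair minimum distance (computed over residues
    A316-T320 of the (A,C) vs (B,D) pairs) and the ion hydration count are
    recorded; summary means run over all snapshots.
    """
    gate_idx = traj.select(Selection(role=Role.PROTEIN, residue_number=gate_residues))
    if gate_idx.size == 0:
        raise ValueError("gate residue selection matches no particles")
    center = traj.coords[:, gate_idx, :].mean(axis=1)  # (F, 3)

    pair_ac = (
        Selection(role=Role.PROTEIN, subunit="A", residue_number=pair_residues),
        Selection(role=Role.PROTEIN, subunit="C", residue_number=pair_residues),
    )
    pair_bd = (
        Selection(role=Role.PROTEIN, subunit="B", residue_number=pair_residues),
        Selection(role=Role.PROTEIN, subunit="D", residue_number=pair_residues),
    )
    narrow = narrower_pair_series(traj, pair_ac, pair_bd).values

    ion_cols = traj.select(Selection(role=Role.ION))
    snapshots: list[GloopPassSnapshot] = []
    hydration_cache: dict[int, np.ndarray] = {}
    for c in ion_cols:
        d = traj.coords[:, c, :] - center
        inside = (d[:, 0] ** 2 + d[:, 1] ** 2 <= cylinder_radius**2) & (
            np.abs(d[:, 2]) <= cylinder_height / 2.0
        )
        frames = np.nonzero(inside)[0]
        if frames.size == 0:
            continue
        pid = traj.particles[c].id
        if c not in hydration_cache:
            hydration_cache[c] = hydration_number(traj, pid, hydration_cutoff).values
        for f in frames:
            snapshots.append(
                GloopPassSnapshot(int(f), pid, float(narrow[f]), int(hydration_cache[c][f]))
            )
    if snapshots:
        return GloopPassSummary(
            snapshots,
            float(np.mean([s.narrower_pair_distance for s in snapshots])),
            float(np.mean([s.hydration_count for s in snapshots])),
            True,
        )
    return GloopPassSummary([], float("nan"), float("nan"), False)


def wetting_state(counts: FrameSeries | np.ndarray, threshold: int) -> tuple[np.ndarray, float]:
    """Label each frame wet/dry by a water-count threshold; return the wet fraction."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    values = np.asarray(counts)
    wet = values >= threshold
    labels = np.where(wet, "wet", "dry")
    return labels, float(wet.mean())
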
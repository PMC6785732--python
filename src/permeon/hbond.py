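"""Hydrogen-bond detection and occupancy statistics.

A bond is present in a frame when the donor-acceptor distance is within
3.5 Angstrom and the hydrogen-donor-acceptor angle is within 30 degrees
(the convention of the common MD tools).  When the system carries no
hydrogens the detector runs in implicit-hydrogen mode: the distance gate
alone decides, the angle test is skipped and the records are flagged.
Salt bridges are reported through the same machinery using N/O heavy-atom
distances in implicit mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FrameSeries
from .model import LabeledTrajectory, Role, Selection

__all__ = ["HBondRecord", "detect_hbonds", "pairwise_occupancy_table"]

DISTANCE_CUTOFF = 3.5  # Angstrom, donor-acceptor
ANGLE_CUTOFF = 30.0  # degrees, hydrogen-donor-acceptor
_DH_BOND_MAX = 1.25  # Angstrom: a hydrogen this close to a donor is attached


@dataclass
class HBondRecord:
    donor_id: int
    acceptor_id: int
    hydrogen_id: int | None
    present: np.ndarray  # (n_frames,) bool
    implicit: bool = False

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.present))


def _attached_hydrogens(traj: LabeledTrajectory, donor_cols: np.ndarray) -> dict[int, np.ndarray]:
    """Hydrogen columns within bonding distance of each donor at frame 0."""
    h_cols = np.array(
        [
            i
            for i, p in enumerate(traj.particles)
            if p.element.upper() == "H" or p.role == Role.WATER_HYDROGEN
        ],
        dtype=int,
    )
    out: dict[int, np.ndarray] = {}
    if h_cols.size == 0:
        return out
    c0 = traj.coords[0]
    for d in donor_cols:
        dist = np.linalg.norm(c0[h_cols] - c0[d], axis=1)
        out[d] = h_cols[dist <= _DH_BOND_MAX]
    return out


def detect_hbonds(
    traj: LabeledTrajectory,
    donors: Selection | str,
    acceptors: Selection | str,
    d_cut: float = DISTANCE_CUTOFF,
    angle_cut: float = ANGLE_CUTOFF,
) -> list[HBondRecord]:
    """All donor/acceptor pairs that are hydrogen bonded in at least one frame."""
    don = traj.select(donors)
    acc = traj.select(acceptors)
    if don.size == 0 or acc.size == 0:
        raise ValueError("donor and acceptor selections must both be non-empty")
    hydrogens = _attached_hydrogens(traj, don)
    implicit_mode = all(len(hydrogens.get(d, ())) == 0 for d in don)

    records: list[HBondRecord] = []
    coords = traj.coords
    for d in don:
        for a in acc:
            if d == a:
                continue
            dist = np.linalg.norm(coords[:, a] - coords[:, d], axis=1)
            within = dist <= d_cut
            if not within.any():
                continue
            if implicit_mode or len(hydrogens.get(d, ())) == 0:
                records.append(
                    HBondRecord(
                        traj.particles[d].id, traj.particles[a].id, None, within, implicit=True
                    )
                )
                continue
            best_present = None
            best_h = None
            for h in hydrogens[d]:
                dh = coords[:, h] - coords[:, d]
                da = coords[:, a] - coords[:, d]
                cosang = np.sum(dh * da, axis=1) / (
                    np.linalg.norm(dh, axis=1) * np.linalg.norm(da, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                present = within & (ang <= angle_cut)
                if best_present is None or present.sum() > best_present.sum():
                    best_present, best_h = present, h
            if best_present.any():
                records.append(
                    HBondRecord(
                        traj.particles[d].id,
                        traj.particles[a].id,
                        traj.particles[best_h].id,
                        best_present,
                    )
                )
    return records


def pairwise_occupancy_table(
    traj: LabeledTrajectory,
    pairs: list[tuple[str, Selection | str, Selection | str]],
    d_cut: float = DISTANCE_CUTOFF,
    angle_cut: float = ANGLE_CUTOFF,
) -> pd.DataFrame:
    """Bond occupancy for labeled selection pairs (max over atom pairs per frame).

    Each entry of ``pairs`` is (label, donor selection, acceptor selection);
    a pair counts as bonded in a frame when any of its atom pairs is.
    """
    rows = []
    for label, don_sel, acc_sel in pairs:
        don = traj.select(don_sel)
        acc = traj.select(acc_sel)
        if don.size == 0 or acc.size == 0:
            raise ValueError(f"pair {label!r}: selection resolves to no atoms")
        records = detect_hbonds(traj, don_sel, acc_sel, d_cut, angle_cut)
        present = np.zeros(traj.n_frames, dtype=bool)
        for r in records:
            present |= r.present
        rows.append(
            {
                "pair": label,
                "occupancy": float(present.mean()),
                "n_bonds": len(records),
                "implicit": bool(records and all(r.implicit for r in records)),
            }
        )
    return pd.DataFrame(rows)
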
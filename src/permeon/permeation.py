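"""Ion traces, permeation-event detection, rates and conductance.

Event detection uses a committed-crossing rule: an event is scored only
when a trace passes from below the lower interval boundary minus a margin
to above the upper boundary plus the margin (or the reverse), so that gate
flicker and recrossings inside the interval are never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .align import unwrap_z
from .geometry import FrameSeries
from .model import LabeledTrajectory, PoreAxisModel, Role, Selection
from .units import ELEMENTARY_CHARGE_C

__all__ = [
    "IonTrace",
    "PermeationEvent",
    "RateSummary",
    "ion_traces",
    "detect_events",
    "count_and_rates",
    "residence_times",
    "cumulative_flux",
    "field_to_voltage",
]

#: default committed margin beyond each interval boundary, Angstrom
DEFAULT_MARGIN = 2.0


@dataclass
class IonTrace:
    """One ion's unwrapped z-trace with pathway compartment labels."""

    ion_id: int
    times: np.ndarray  # ps
    z: np.ndarray  # Angstrom, unwrapped along the pore axis
    compartments: np.ndarray  # str labels from PoreAxisModel

    @property
    def stride_ps(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class PermeationEvent:
    ion_id: int
    interval: str  # HBC | Gloop | SF_full
    entry_frame: int
    exit_frame: int
    entry_time: float  # ps
    exit_time: float  # ps
    direction: str  # outward | inward


def ion_traces(traj: LabeledTrajectory, pore: PoreAxisModel) -> list[IonTrace]:
    """Unwrapped z-trace plus compartment labels for every ion."""
    cols = traj.select(Selection(role=Role.ION))
    if cols.size == 0:
        raise ValueError("trajectory contains no ions")
    traces = []
    for c in cols:
        z = unwrap_z(traj.coords[:, c, 2], traj.box[:, 2])
        traces.append(
            IonTrace(
                ion_id=traj.particles[c].id,
                times=traj.times.copy(),
                z=z,
                compartments=pore.compartments(z),
            )
        )
    return traces


def detect_events(
    trace: IonTrace,
    interval: str,
    pore: PoreAxisModel,
    committed_margin: float = DEFAULT_MARGIN,
    periodic_box_z: float | None = None,
) -> list[PermeationEvent]:
    """Committed crossings of a landmark interval, both directions.

    The trace must travel from beyond one committed plane (boundary -/+
    margin) to beyond the other; excursions that re-enter the interval and
    retreat do not count, and recrossings inside the interval never create
    extra events.

    ``periodic_box_z`` handles recycled (unwrapped periodic) traces: an ion
    whose unwrapped z climbs k box lengths has permeated k times, so
    committed crossings are counted against every periodic image of the
    interval that the trace spans.
    """
    if committed_margin < 0:
        raise ValueError("committed_margin must be >= 0")
    z_lo, z_hi = pore.interval(interval)
    z = np.asarray(pore._orient(trace.z), dtype=float)
    if periodic_box_z is not None:
        if periodic_box_z <= 0:
            raise ValueError("periodic_box_z must be positive")
        L = periodic_box_z
        k_min = int(np.floor((z.min() - z_hi) / L))
        k_max = int(np.ceil((z.max() - z_lo) / L))
        events: list[PermeationEvent] = []
        for k in range(k_min, k_max + 1):
            events.extend(
                _detect_single_window(
                    trace, z, interval, z_lo + k * L, z_hi + k * L, committed_margin
                )
            )
        events.sort(key=lambda e: e.exit_frame)
        return events
    return _detect_single_window(trace, z, interval, z_lo, z_hi, committed_margin)


def _detect_single_window(
    trace: IonTrace,
    z: np.ndarray,
    interval: str,
    z_lo: float,
    z_hi: float,
    committed_margin: float,
) -> list[PermeationEvent]:
    lo = z_lo - committed_margin
    hi = z_hi + committed_margin

    events: list[PermeationEvent] = []
    state = 0  # -1 committed below, +1 committed above, 0 unknown
    anchor = 0  # frame of the most recent commitment
    for f in range(len(z)):
        if z[f] < lo:
            if state != -1:
                state = -1
            anchor = f
        elif z[f] > hi:
            if state == -1:
                events.append(
                    PermeationEvent(
                        ion_id=trace.ion_id,
                        interval=interval,
                        entry_frame=anchor,
                        exit_frame=f,
                        entry_time=float(trace.times[anchor]),
                        exit_time=float(trace.times[f]),
                        direction="outward",
                    )
                )
            state = 1
            anchor = f
        # inside the interval: keep the current commitment
    # second pass for inward events (scan handled above only records
    # outward; rerun mirrored to keep the logic symmetric and simple)
    state = 0
    anchor = 0
    for f in range(len(z)):
        if z[f] > hi:
            state = 1
            anchor = f
        elif z[f] < lo:
            if state == 1:
                events.append(
                    PermeationEvent(
                        ion_id=trace.ion_id,
                        interval=interval,
                        entry_frame=anchor,
                        exit_frame=f,
                        entry_time=float(trace.times[anchor]),
                        exit_time=float(trace.times[f]),
                        direction="inward",
                    )
                )
            state = -1
            anchor = f
    events.sort(key=lambda e: e.exit_frame)
    return events


@dataclass
class RateSummary:
    """Per-run permeation bookkeeping with group statistics.

    ``per_run`` has one row per run: event count, rate in events/us and,
    when a voltage is given, the single-channel conductance
    g = N e / (t V) in pS.  Group means use the sample (n-1) standard
    deviation.
    """

    per_run: pd.DataFrame
    total_events: int
    group_stats: pd.DataFrame


def count_and_rates(
    counts: dict[str, int],
    durations_us: dict[str, float],
    voltages_mV: dict[str, float] | None = None,
    restrained: dict[str, bool] | None = None,
) -> RateSummary:
    """Event counts per run -> rates, conductances and group statistics."""
    runs = list(counts)
    rows = []
    for run in runs:
        t = durations_us[run]
        if t <= 0:
            raise ValueError(f"run {run}: duration must be positive")
        n = counts[run]
        v = None if voltages_mV is None else voltages_mV.get(run)
        if v is not None and v != 0:
            g_pS = n * ELEMENTARY_CHARGE_C / (t * 1e-6 * v * 1e-3) * 1e12
        else:
            g_pS = np.nan  # undefined at zero/absent voltage
        rows.append(
            {
                "run": run,
                "events": n,
                "duration_us": t,
                "rate_per_us": n / t,
                "voltage_mV": v,
                "conductance_pS": g_pS,
                "restrained": bool(restrained[run]) if restrained else False,
            }
        )
    per_run = pd.DataFrame(rows)
    groups = []
    for label, sub in per_run.groupby("restrained"):
        rates = sub["rate_per_us"].to_numpy(dtype=float)
        groups.append(
            {
                "group": "restrained" if label else "unrestrained",
                "n_runs": len(sub),
                "mean_rate_per_us": float(np.mean(rates)),
                "sd_rate_per_us": float(np.std(rates, ddof=1)) if len(rates) > 1 else np.nan,
                "total_events": int(sub["events"].sum()),
            }
        )
    return RateSummary(per_run, int(per_run["events"].sum()), pd.DataFrame(groups))


def residence_times(trace: IonTrace, site: str) -> np.ndarray:
    """Dwell durations (ns) of maximal contiguous spans in one compartment."""
    valid = {"S0", "S1", "S2", "S3", "S4", "Gloop", "cavity", "CTD", "bulk_in", "bulk_out"}
    if site not in valid:
        raise ValueError(f"unknown site {site!r}")
    mask = trace.compartments == site
    if not mask.any():
        return np.array([])
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    stride_ns = trace.stride_ps / 1000.0
    return (ends - starts) * stride_ns


def cumulative_flux(events: list[PermeationEvent], t_end_ps: float) -> tuple[np.ndarray, np.ndarray]:
    """Step function of cumulative event count against time.

    Returns (times_ps, counts); counts are non-decreasing and end at the
    total number of events.
    """
    times = np.sort([e.exit_time for e in events])
    t = np.concatenate([[0.0], times, [t_end_ps]])
    n = np.concatenate([[0], np.arange(1, len(times) + 1), [len(times)]])
    return t, n


def field_to_voltage(field_mV_per_nm: float, box_z_nm: float) -> float:
    """Transmembrane voltage (mV) from a uniform applied field over the box."""
    if field_mV_per_nm < 0 or box_z_nm <= 0:
        raise ValueError("field and box length must be positive")
    return field_mV_per_nm * box_z_nm
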
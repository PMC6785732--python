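"""Rigid-body superposition and periodic unwrapping."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .model import LabeledTrajectory, Selection

__all__ = ["kabsch", "superpose", "rmsd", "unwrap_z"]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the convention ``fitted = mobile @ R.T + t``.
    Reflections are forbidden (determinant of R is +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 particles (rotation underdetermined)")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t, float(rssd / np.sqrt(mobile.shape[0]))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(traj: LabeledTrajectory, reference_selection: Selection | str) -> LabeledTrajectory:
    """Least-squares fit every frame onto frame 0 using the given selection.

    The rotation/translation minimizing the selection RMSD is applied to
    *all* particles of the frame, mirroring trajectory alignment on the
    selectivity-filter backbone before pore-axis analyses.
    """
    idx = traj.select(reference_selection)
    if idx.size == 0:
        raise ValueError("reference selection matches no particles")
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected particles")
    ref = traj.coords[0, idx]
    out = traj.coords.copy()
    for f in range(1, traj.n_frames):
        R, t, _ = kabsch(traj.coords[f, idx], ref)
        out[f] = traj.coords[f] @ R.T + t
    return LabeledTrajectory(traj.particles, out, traj.times.copy(), traj.box.copy())


def unwrap_z(z: np.ndarray, box_z: np.ndarray | float) -> np.ndarray:
    """Remove periodic jumps from a z-trace (minimum image on successive frames).

    Any step larger than half the box is treated as a wrap.  Permeation
    counting presumes continuous traces, so ion z-series are unwrapped
    before event detection.
    """
    z = np.asarray(z, dtype=float)
    box_z = np.broadcast_to(np.asarray(box_z, dtype=float), z.shape)
    dz = np.diff(z)
    half = box_z[1:] / 2.0
    shift = np.where(dz > half, -box_z[1:], np.where(dz < -half, box_z[1:], 0.0))
    return np.concatenate([[z[0]], z[0] + np.cumsum(dz + shift)])
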
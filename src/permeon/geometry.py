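"""Per-frame geometric observables: distances, dihedrals, RMSD, domain rotation.

All operators return a :class:`FrameSeries` (times in ps plus one value per
frame).  Distance reductions follow the conventions of the standard MD
tools: ``min_distance`` scans all inter-selection atom pairs, while
``calpha_distance`` uses the single Calpha of a residue on each of two
opposing subunits of the tetramer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .align import kabsch, rmsd as _plain_rmsd
from .model import LabeledTrajectory, Selection

__all__ = [
    "FrameSeries",
    "min_distance",
    "narrower_pair_series",
    "calpha_distance",
    "histogram",
    "backbone_rmsd",
    "dihedral_series",
    "ctd_rotation",
    "cation_pi_geometry",
]


@dataclass
class FrameSeries:
    """One scalar observable per frame."""

    times: np.ndarray  # ps
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None):
        return np.asarray(self.values, dtype=dtype)


def _resolve(traj: LabeledTrajectory, sel: Selection | str, what: str) -> np.ndarray:
    idx = traj.select(sel)
    if idx.size == 0:
        raise ValueError(f"{what}: selection matches no particles")
    return idx


def min_distance(
    traj: LabeledTrajectory, sel_a: Selection | str, sel_b: Selection | str, name: str = "mindist"
) -> FrameSeries:
    """Per-frame minimum over all inter-selection atom-pair distances."""
    ia = _resolve(traj, sel_a, "min_distance")
    ib = _resolve(traj, sel_b, "min_distance")
    if set(ia) == set(ib):
        raise ValueError("min_distance: identical selections (self-pairing is ambiguous)")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        vals[f] = cdist(traj.coords[f, ia], traj.coords[f, ib]).min()
    return FrameSeries(traj.times, vals, name)


def narrower_pair_series(
    traj: LabeledTrajectory,
    pair1: tuple[Selection | str, Selection | str],
    pair2: tuple[Selection | str, Selection | str],
    name: str = "narrower_pair",
) -> FrameSeries:
    """Frame-wise minimum of the two opposing-subunit pair distances.

    In a four-fold channel the gate aperture is gauged by the narrower of
    the (A,C) and (B,D) cross-pore distances at each snapshot.
    """
    d1 = min_distance(traj, *pair1)
    d2 = min_distance(traj, *pair2)
    return FrameSeries(traj.times, np.minimum(d1.values, d2.values), name)


def calpha_distance(
    traj: LabeledTrajectory,
    residue_number: int,
    pair: tuple[str, str] = ("A", "C"),
    name: str | None = None,
) -> FrameSeries:
    """Distance between the opposing Calpha atoms of one residue."""
    cols = []
    for subunit in pair:
        idx = traj.select(Selection(subunit=subunit, residue_number=residue_number, atom_name="CA"))
        if idx.size != 1:
            raise ValueError(
                f"calpha_distance: subunit {subunit} residue {residue_number} has "
                f"{idx.size} CA atoms (expected exactly 1)"
            )
        cols.append(idx[0])
    d = np.linalg.norm(traj.coords[:, cols[0]] - traj.coords[:, cols[1]], axis=1)
    return FrameSeries(traj.times, d, name or f"ca_dist_{residue_number}")


@dataclass
class Histogram:
    bin_left_edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    fraction_above: float | None = None
    fraction_below: float | None = None
    threshold: float | None = None


def histogram(series: FrameSeries | np.ndarray, bin_width: float, threshold: float | None = None) -> Histogram:
    """Left-closed right-open bins anchored at 0, plus a threshold split.

    ``fraction_above`` is the fraction of raw values strictly greater than
    ``threshold`` (computed on the unbinned series, so it is exact).
    """
    values = np.asarray(series)
    if values.size == 0:
        raise ValueError("histogram: empty series")
    if bin_width <= 0:
        raise ValueError("histogram: bin_width must be positive")
    idx = np.floor(values / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = (np.arange(lo, hi + 1)) * bin_width
    frac_above = frac_below = None
    if threshold is not None:
        frac_above = float(np.mean(values > threshold))
        frac_below = float(np.mean(values <= threshold))
    return Histogram(edges, counts, bin_width, frac_above, frac_below, threshold)


def backbone_rmsd(
    traj: LabeledTrajectory,
    sel: Selection | str,
    fit: bool = True,
    name: str = "rmsd",
) -> FrameSeries:
    """RMSD of a selection to frame 0, after optimal superposition by default."""
    idx = _resolve(traj, sel, "backbone_rmsd")
    if idx.size < 3:
        raise ValueError("backbone_rmsd needs at least 3 atoms")
    ref = traj.coords[0, idx]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, idx]
        if fit:
            R, t, vals[f] = kabsch(mob, ref)
        else:
            vals[f] = _plain_rmsd(mob, ref)
    return FrameSeries(traj.times, vals, name)


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral in degrees, IUPAC convention, range (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral_series(
    traj: LabeledTrajectory,
    sel_1: Selection | str,
    sel_2: Selection | str,
    sel_3: Selection | str,
    sel_4: Selection | str,
    name: str = "dihedral",
) -> FrameSeries:
    """Standard signed dihedral over four single-atom selections.

    For a backbone psi angle pass N(i), CA(i), C(i), N(i+1).
    """
    cols = []
    for s in (sel_1, sel_2, sel_3, sel_4):
        idx = traj.select(s)
        if idx.size != 1:
            raise ValueError(f"dihedral_series: selection {s!r} resolves to {idx.size} atoms, need 1")
        cols.append(idx[0])
    p = traj.coords[:, cols, :]
    vals = _dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    return FrameSeries(traj.times, vals, name)


def _wrap_deg(a):
    a = (np.asarray(a) + 180.0) % 360.0 - 180.0
    return np.where(a <= -180.0, a + 360.0, a)


def _com(coords: np.ndarray, idx: np.ndarray, masses: np.ndarray | None) -> np.ndarray:
    pts = coords[..., idx, :]
    if masses is None:
        return pts.mean(axis=-2)
    w = masses[idx]
    return (pts * w[:, None]).sum(axis=-2) / w.sum()


def ctd_rotation(
    traj: LabeledTrajectory,
    tmd_sel: Selection | str,
    ctd_sel: Selection | str,
    tmd_subunit_sel: Selection | str,
    ctd_subunit_sel: Selection | str,
    reference: LabeledTrajectory | np.ndarray | None = None,
    masses: np.ndarray | None = None,
    name: str = "ctd_rotation",
) -> FrameSeries:
    """Rotation of the cytoplasmic domain relative to the transmembrane domain.

    The angle is the torsion between the planes (TMD-COM, CTD-COM,
    TMD-subunit-COM) and (TMD-COM, CTD-COM, CTD-subunit-COM), referenced to
    the same torsion in ``reference`` (frame 0 when not given).  Sign
    convention: a counterclockwise rotation of the CTD viewed from the
    extracellular (top, +z) side is *negative*.  Centers of mass use unit
    masses unless a per-particle mass array is supplied.  Frames where the
    four points are collinear are flagged as NaN.
    """
    sels = [tmd_sel, ctd_sel, tmd_subunit_sel, ctd_subunit_sel]
    idxs = [_resolve(traj, s, "ctd_rotation") for s in sels]

    def torsion(coords: np.ndarray) -> np.ndarray:
        p1, p2, p3, p4 = (_com(coords, i, masses) for i in idxs)
        # torsion about the p1-p2 axis = dihedral p3-p1-p2-p4, signed so
        # that counterclockwise-from-top comes out negative
        ang = _dihedral(p3, p1, p2, p4)
        b = p2 - p1
        deg1 = np.linalg.norm(np.cross(p3 - p1, b), axis=-1)
        deg2 = np.linalg.norm(np.cross(p4 - p1, b), axis=-1)
        scale = np.linalg.norm(b, axis=-1)
        bad = (deg1 < 1e-9 * scale) | (deg2 < 1e-9 * scale)
        return np.where(bad, np.nan, ang)

    if reference is None:
        ref_coords = traj.coords[0]
    elif isinstance(reference, LabeledTrajectory):
        ref_coords = reference.coords[0]
    else:
        ref_coords = np.asarray(reference, dtype=float)
    ref_angle = torsion(ref_coords[None, ...])[0]
    vals = _wrap_deg(torsion(traj.coords) - ref_angle)
    return FrameSeries(traj.times, vals, name)


def cation_pi_geometry(
    traj: LabeledTrajectory,
    ring_sel: Selection | str,
    ion_id: int,
    name: str = "cation_pi",
) -> tuple[FrameSeries, FrameSeries]:
    """Centroid distance and axial angle between an aromatic ring and an ion.

    The ring normal is taken from the best-fit (SVD) plane of the ring
    atoms; the angle between the normal and the centroid->ion vector is
    folded to [0, 90] degrees, so 0 means the ion sits on the ring axis.
    """
    idx = _resolve(traj, ring_sel, "cation_pi_geometry")
    if idx.size < 3:
        raise ValueError("cation_pi_geometry: ring selection needs at least 3 atoms")
    col = traj.index_of(ion_id)
    dist = np.empty(traj.n_frames)
    angle = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ring = traj.coords[f, idx]
        centroid = ring.mean(axis=0)
        _, _, vh = np.linalg.svd(ring - centroid)
        normal = vh[2]
        v = traj.coords[f, col] - centroid
        dist[f] = np.linalg.norm(v)
        if dist[f] < 1e-12:
            angle[f] = 0.0
        else:
            cosang = abs(np.dot(normal, v) / dist[f])
            angle[f] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (
        FrameSeries(traj.times, dist, f"{name}_distance"),
        FrameSeries(traj.times, angle, f"{name}_angle"),
    )
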
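"""Trajectory and topology readers/writers.

Two on-disk forms are supported: PDB (single-model topology, multi-model
frames; parsing/writing delegated to biotite) and a plain-text columnar
frame format with header ``frame time_ps id x y z box_x box_y box_z``,
whitespace separated, one row per particle per frame.  The columnar format
round-trips coordinates losslessly; PDB is limited to 3 decimals.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import Frame, LabeledTrajectory, Particle, Role

__all__ = ["read_topology", "read_frames", "write_frames", "write_topology"]

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}
_ION_NAMES = {"K", "K+", "POT", "NA", "NA+", "SOD", "CL", "CL-", "CLA"}
_WATER_NAMES = {"HOH", "SOL", "WAT", "TIP", "TIP3", "TIP4", "SPC", "T3P"}
_LIPID_NAMES = {"POPC", "POPE", "POPG", "POP", "PIP", "PIP2", "PI2", "DPPC", "DOPC"}


def _role_for(res_name: str, element: str) -> Role:
    name = res_name.strip().upper()
    if name in _ION_NAMES:
        return Role.ION
    if name in _WATER_NAMES:
        return Role.WATER_HYDROGEN if element.upper() == "H" else Role.WATER_OXYGEN
    if name in _AMINO_ACIDS:
        return Role.PROTEIN
    if name in _LIPID_NAMES:
        return Role.LIPID
    warnings.warn(f"unknown residue name {res_name!r}: assigning role 'other'", stacklevel=3)
    return Role.OTHER


def _check_pdb_records(path: Path) -> None:
    # cheap pre-scan so parse failures name the offending line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}:{lineno}: truncated ATOM/HETATM record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: malformed coordinates in ATOM/HETATM record"
                    ) from None


def _particles_from_atoms(atoms: struc.AtomArray) -> list[Particle]:
    particles = []
    for i in range(atoms.array_length()):
        res_name = str(atoms.res_name[i])
        element = str(atoms.element[i])
        role = _role_for(res_name, element)
        subunit = str(atoms.chain_id[i]).strip() or None
        particles.append(
            Particle(
                id=i + 1,
                role=role,
                subunit=subunit if role == Role.PROTEIN else subunit,
                residue_number=int(atoms.res_id[i]),
                residue_name=res_name,
                atom_name=str(atoms.atom_name[i]),
                element=element,
            )
        )
    return particles


def read_topology(path: str | Path) -> list[Particle]:
    """Read a single-model PDB and label its particles.

    Roles follow residue-name rules (K/POT -> ion, HOH/SOL/TIP -> water,
    standard amino acids -> protein); the chain id becomes the subunit.
    Unknown residues are kept with role ``other`` and a warning.
    """
    path = Path(path)
    _check_pdb_records(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return _particles_from_atoms(atoms)


def read_frames(
    path: str | Path,
    system: Sequence[Particle],
    dt_ps: float = 20.0,
) -> LabeledTrajectory:
    """Read frames (multi-model PDB or columnar file) onto a known system.

    Multi-model PDBs carry no explicit time; model *m* is assigned
    ``(m - 1) * dt_ps``.  Columnar files carry their own times.  Frames are
    sorted by time; particle ids must match the system exactly.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return _read_pdb_frames(path, system, dt_ps)
    return _read_columnar(path, system)


def _read_pdb_frames(path: Path, system: Sequence[Particle], dt_ps: float) -> LabeledTrajectory:
    _check_pdb_records(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    n_models = stack.stack_depth()
    if n_models == 0:
        raise ValueError(f"{path}: no frames found")
    if stack.array_length() != len(system):
        raise ValueError(
            f"{path}: frame has {stack.array_length()} particles, system has {len(system)}"
        )
    coords = np.asarray(stack.coord, dtype=float)
    times = np.arange(n_models) * dt_ps
    box = _box_from_stack(stack, coords)
    return LabeledTrajectory(system, coords, times, box)


def _box_from_stack(stack, coords) -> np.ndarray:
    if stack.box is not None:
        b = np.asarray(stack.box)
        return np.stack([np.diag(b[i]) for i in range(b.shape[0])])
    # no CRYST1: synthesize a box generously containing the coordinates
    span = coords.reshape(-1, 3).max(axis=0) - coords.reshape(-1, 3).min(axis=0)
    return np.broadcast_to(np.maximum(span + 20.0, 1.0), (coords.shape[0], 3)).copy()


_COLUMNS = ["frame", "time_ps", "id", "x", "y", "z", "box_x", "box_y", "box_z"]


def _read_columnar(path: Path, system: Sequence[Particle]) -> LabeledTrajectory:
    with open(path) as fh:
        header = fh.readline().split()
        has_rows = bool(fh.readline().strip())
    if header != _COLUMNS:
        raise ValueError(f"{path}: expected header {' '.join(_COLUMNS)!r}")
    if not has_rows:
        raise ValueError(f"{path}: no frames found")
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    sys_ids = np.array([p.id for p in system])
    frame_idx = data[:, 0].astype(int)
    order = np.argsort(frame_idx, kind="stable")
    data = data[order]
    frame_idx = frame_idx[order]
    uniq, starts = np.unique(frame_idx, return_index=True)
    n_frames = len(uniq)
    coords = np.empty((n_frames, len(system), 3))
    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    id_to_col = {pid: i for i, pid in enumerate(sys_ids)}
    bounds = list(starts) + [len(data)]
    for f in range(n_frames):
        rows = data[bounds[f]:bounds[f + 1]]
        ids = rows[:, 2].astype(int)
        missing = set(sys_ids) - set(ids)
        if missing or len(ids) != len(sys_ids):
            raise ValueError(
                f"{path}: frame {uniq[f]} particle ids do not match system"
                + (f" (missing ids {sorted(missing)[:10]})" if missing else "")
            )
        cols = np.array([id_to_col[i] for i in ids])
        coords[f, cols] = rows[:, 3:6]
        times[f] = rows[0, 1]
        box[f] = rows[0, 6:9]
    order = np.argsort(times)
    times = times[order]
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: frame times are not strictly increasing")
    return LabeledTrajectory(system, coords[order], times, box[order])


def write_frames(traj: LabeledTrajectory, path: str | Path, format: str = "columnar") -> Path:
    """Write a trajectory; ``format`` is ``"columnar"`` or ``"pdb"``."""
    path = Path(path)
    if format == "columnar":
        ids = np.array([p.id for p in traj.particles])
        with open(path, "w") as fh:
            fh.write(" ".join(_COLUMNS) + "\n")
            for f in range(traj.n_frames):
                t = traj.times[f]
                bx, by, bz = traj.box[f]
                for c, pid in enumerate(ids):
                    x, y, z = traj.coords[f, c]
                    fh.write(
                        f"{f} {t:.17g} {pid} {x:.17g} {y:.17g} {z:.17g} "
                        f"{bx:.17g} {by:.17g} {bz:.17g}\n"
                    )
        return path
    if format == "pdb":
        stack = _to_atom_stack(traj)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
        return path
    raise ValueError(f"unsupported trajectory format {format!r}")


def write_topology(
    particles: Sequence[Particle],
    coordinates: np.ndarray,
    box: np.ndarray,
    path: str | Path,
) -> Path:
    """Write a single-model PDB topology with the given reference coordinates."""
    traj = LabeledTrajectory(
        particles,
        np.asarray(coordinates)[None, :, :],
        np.array([0.0]),
        np.asarray(box, dtype=float)[None, :],
    )
    atoms = _to_atom_stack(traj)[0]
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(Path(path)))
    return Path(path)


def _to_atom_stack(traj: LabeledTrajectory) -> struc.AtomArrayStack:
    n = traj.n_particles
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.chain_id = np.array([(p.subunit or "X")[:4] for p in traj.particles])
    stack.res_id = np.array([p.residue_number if p.residue_number is not None else 1 for p in traj.particles])
    stack.res_name = np.array([(p.residue_name or "UNK")[:5] for p in traj.particles])
    stack.atom_name = np.array([(p.atom_name or p.element or "X")[:6] for p in traj.particles])
    stack.element = np.array([(p.element or "C")[:2] for p in traj.particles])
    stack.hetero = np.array([p.role != Role.PROTEIN for p in traj.particles])
    boxes = np.stack([np.diag(traj.box[f]) for f in range(traj.n_frames)])
    stack.box = boxes
    return stack
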
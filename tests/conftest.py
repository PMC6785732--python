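"""Shared fixtures and small trajectory builders."""

from __future__ import annotations

import numpy as np
import pytest

from permeon.model import LabeledTrajectory, Particle, PoreAxisModel, Role
from permeon.synthetic import default_pore

BOX = (80.0, 80.0, 145.0)


@pytest.fixture
def pore() -> PoreAxisModel:
    return default_pore()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_traj(particles, coords, stride_ps: float = 20.0, box=BOX) -> LabeledTrajectory:
    """Trajectory from a particle list and an (F, N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    times = np.arange(coords.shape[0]) * stride_ps
    return LabeledTrajectory(particles, coords, times, np.asarray(box, dtype=float))


def ion(pid: int) -> Particle:
    return Particle(id=pid, role=Role.ION, residue_name="K", atom_name="K", element="K")


def water(pid: int) -> Particle:
    return Particle(id=pid, role=Role.WATER_OXYGEN, residue_name="HOH", atom_name="O",
                    element="O")


def protein_atom(pid: int, subunit: str, resid: int, resname: str = "ALA",
                 atom: str = "CA", element: str = "C") -> Particle:
    return Particle(id=pid, role=Role.PROTEIN, subunit=subunit, residue_number=resid,
                    residue_name=resname, atom_name=atom, element=element)
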
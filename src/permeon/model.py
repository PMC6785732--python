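"""Domain types shared by every analysis stage.

A trajectory here is a time-ordered stack of frames over a fixed, labeled
particle set.  Particles carry the labels the analyses select on (role,
subunit, residue, atom name); coordinates live in a single dense array so
that per-frame slicing is cheap.  Units are Angstrom, picosecond and
kcal/mol throughout; converters for nm/kJ inputs live in :mod:`permeon.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Role",
    "Particle",
    "Frame",
    "LabeledTrajectory",
    "PoreAxisModel",
    "Selection",
    "COMPARTMENTS",
]


class Role(str, Enum):
    """What a particle is, as far as the analyses care."""

    PROTEIN = "protein"
    ION = "ion"
    WATER_OXYGEN = "water_oxygen"
    WATER_HYDROGEN = "water_hydrogen"
    LIPID = "lipid"
    OTHER = "other"


@dataclass(frozen=True)
class Particle:
    """One labeled particle of the system.

    Protein particles carry ``subunit`` (A-D in a tetramer) and residue
    fields; ions and waters need not.
    """

    id: int
    role: Role
    subunit: str | None = None
    residue_number: int | None = None
    residue_name: str = ""
    atom_name: str = ""
    element: str = ""


@dataclass
class Frame:
    """A single snapshot: time, box lengths and one coordinate per particle."""

    time: float  # ps
    box: np.ndarray  # (3,) box lengths, Angstrom
    coordinates: np.ndarray  # (n_particles, 3) Angstrom

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_particles, 3)")


class Selection:
    """A deterministic predicate over particle labels.

    Any field left as ``None`` matches everything.  ``residue_number`` may be
    a single integer or any iterable of integers (e.g. ``range(316, 321)``).
    Selections can be parsed from compact strings such as
    ``"role:protein subunit:A resid:319 name:CA"``.
    """

    def __init__(
        self,
        role: Role | str | None = None,
        subunit: str | Sequence[str] | None = None,
        residue_number: int | Iterable[int] | None = None,
        residue_name: str | Sequence[str] | None = None,
        atom_name: str | Sequence[str] | None = None,
        element: str | None = None,
    ):
        self.role = Role(role) if role is not None else None
        self.subunit = _as_set(subunit)
        if residue_number is None:
            self.residue_number = None
        elif isinstance(residue_number, int):
            self.residue_number = {residue_number}
        else:
            self.residue_number = set(residue_number)
        self.residue_name = _as_set(residue_name)
        self.atom_name = _as_set(atom_name)
        self.element = element

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``"role:ion"`` / ``"subunit:A resid:316-320 name:CA"`` style strings."""
        kw: dict = {}
        for token in text.split():
            key, _, value = token.partition(":")
            if not value:
                raise ValueError(f"malformed selection token {token!r}")
            if key == "role":
                kw["role"] = value
            elif key == "subunit":
                kw["subunit"] = value.split(",")
            elif key == "resid":
                nums: set[int] = set()
                for part in value.split(","):
                    if "-" in part:
                        lo, hi = part.split("-")
                        nums.update(range(int(lo), int(hi) + 1))
                    else:
                        nums.add(int(part))
                kw["residue_number"] = nums
            elif key == "resname":
                kw["residue_name"] = value.split(",")
            elif key == "name":
                kw["atom_name"] = value.split(",")
            elif key == "element":
                kw["element"] = value
            else:
                raise ValueError(f"unknown selection key {key!r}")
        return cls(**kw)

    def matches(self, p: Particle) -> bool:
        if self.role is not None and p.role != self.role:
            return False
        if self.subunit is not None and p.subunit not in self.subunit:
            return False
        if self.residue_number is not None and p.residue_number not in self.residue_number:
            return False
        if self.residue_name is not None and p.residue_name not in self.residue_name:
            return False
        if self.atom_name is not None and p.atom_name not in self.atom_name:
            return False
        if self.element is not None and p.element != self.element:
            return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = []
        for k in ("role", "subunit", "residue_number", "residue_name", "atom_name", "element"):
            v = getattr(self, k)
            if v is not None:
                parts.append(f"{k}={v!r}")
        return f"Selection({', '.join(parts)})"


def _as_set(value) -> set | None:
    if value is None:
        return None
    if isinstance(value, str):
        return {value}
    return set(value)


#: compartment labels along the permeation pathway, intracellular to
#: extracellular: bulk -> cytoplasmic domain -> G-loop region -> inner
#: cavity -> selectivity-filter sites S4..S0 -> extracellular bulk
COMPARTMENTS = (
    "bulk_in",
    "CTD",
    "Gloop",
    "cavity",
    "S4",
    "S3",
    "S2",
    "S1",
    "S0",
    "bulk_out",
)

SITES = ("S4", "S3", "S2", "S1", "S0")


@dataclass
class PoreAxisModel:
    """Pore landmarks along z (Angstrom), intracellular to extracellular.

    ``z_site_boundaries`` holds six increasing z values delimiting the five
    canonical K+ binding sites S4 (intracellular) through S0 (extracellular).
    With ``axis_direction='-z'`` all landmark comparisons are flipped; the
    coordinates themselves are never transformed.
    """

    z_intracellular_entrance: float
    z_gloop: float
    z_hbc: float
    z_site_boundaries: np.ndarray  # (6,)
    pore_radius: float = 8.0
    axis_direction: str = "+z"

    def __post_init__(self) -> None:
        self.z_site_boundaries = np.asarray(self.z_site_boundaries, dtype=float)
        if self.z_site_boundaries.shape != (6,):
            raise ValueError("z_site_boundaries must hold exactly 6 values (5 sites)")
        if self.axis_direction not in ("+z", "-z"):
            raise ValueError("axis_direction must be '+z' or '-z'")
        lm = np.concatenate(
            [[self.z_intracellular_entrance, self.z_gloop, self.z_hbc], self.z_site_boundaries]
        )
        ordered = lm if self.axis_direction == "+z" else -lm
        if not np.all(np.diff(ordered) > 0):
            raise ValueError("pore landmarks must be strictly ordered along the permeation axis")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")

    # All comparisons below operate on the oriented coordinate s = +/- z so
    # that "up" always means toward the extracellular side.
    def _orient(self, z):
        return np.asarray(z, dtype=float) if self.axis_direction == "+z" else -np.asarray(z, dtype=float)

    @property
    def sf_lower(self) -> float:
        """Oriented coordinate of the intracellular edge of site S4."""
        return float(self._orient(self.z_site_boundaries[0]))

    @property
    def sf_upper(self) -> float:
        """Oriented coordinate of the extracellular edge of site S0."""
        return float(self._orient(self.z_site_boundaries[-1]))

    def site_windows(self) -> dict[str, tuple[float, float]]:
        """Oriented (lower, upper) window of each site, S4..S0."""
        b = np.sort(self._orient(self.z_site_boundaries))
        return {name: (float(b[i]), float(b[i + 1])) for i, name in enumerate(SITES)}

    def interval(self, name: str) -> tuple[float, float]:
        """Oriented boundary pair for an event-detection interval."""
        if name == "HBC":
            z = float(self._orient(self.z_hbc))
            return (z, z)
        if name == "Gloop":
            z = float(self._orient(self.z_gloop))
            return (z, z)
        if name == "SF_full":
            return (self.sf_lower, self.sf_upper)
        raise ValueError(f"unknown interval {name!r}")

    def compartments(self, z) -> np.ndarray:
        """Label each oriented-z value with its pathway compartment."""
        s = self._orient(z)
        edges = np.concatenate(
            [
                [self._orient(self.z_intracellular_entrance)],
                [self._orient(self.z_gloop)],
                [self._orient(self.z_hbc)],
                np.sort(self._orient(self.z_site_boundaries)),
            ]
        )
        idx = np.searchsorted(edges, s, side="right")
        labels = np.array(COMPARTMENTS, dtype=object)
        return labels[idx]


class LabeledTrajectory:
    """Time-ordered frames over a fixed labeled particle set.

    Coordinates are stored as one ``(n_frames, n_particles, 3)`` array;
    :meth:`frame` returns lightweight views.
    """

    def __init__(
        self,
        particles: Sequence[Particle],
        coords: np.ndarray,
        times: np.ndarray,
        box: np.ndarray,
    ):
        self.particles = list(particles)
        self.coords = np.asarray(coords, dtype=float)
        self.times = np.asarray(times, dtype=float)
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (len(self.times), 3)).copy()
        self.box = box
        ids = [p.id for p in self.particles]
        if len(set(ids)) != len(ids):
            raise ValueError("particle ids must be unique")
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.particles) or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_particles, 3)")
        if self.coords.shape[0] != len(self.times) or self.box.shape != (len(self.times), 3):
            raise ValueError("times/box length must match number of frames")
        if len(self.times) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        self._id_index = {p.id: i for i, p in enumerate(self.particles)}

    # -- basic queries -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def stride(self) -> float:
        """Time between stored frames in ps (from the first two frames)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.box[i], coordinates=self.coords[i])

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def index_of(self, particle_id: int) -> int:
        try:
            return self._id_index[particle_id]
        except KeyError:
            raise KeyError(f"unknown particle id {particle_id}") from None

    def select(self, selection: Selection | str) -> np.ndarray:
        """Column indices of the particles matching ``selection``."""
        if isinstance(selection, str):
            selection = Selection.parse(selection)
        return np.array(
            [i for i, p in enumerate(self.particles) if selection.matches(p)], dtype=int
        )

    def ids_of(self, selection: Selection | str) -> list[int]:
        return [self.particles[i].id for i in self.select(selection)]

    def copy(self) -> "LabeledTrajectory":
        return LabeledTrajectory(self.particles, self.coords.copy(), self.times.copy(), self.box.copy())
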
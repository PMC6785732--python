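"""Synthetic pore trajectories with known ground truth.

A four-fold pseudo-channel aligned with +z emulates the statistical
structure of K+ channel MD data at desk scale: ions perform overdamped
field-biased diffusion on a configurable potential U(z) inside a soft
cylinder; two gates (a G-loop M319-like and an HBC F192-like constriction)
flicker between open and closed states with first-order kinetics; the five
selectivity-filter sites enforce single occupancy with an upward
knock-on displacement rule; waters diffuse as tracers with a region
dependent density and are re-seeded to maintain ion solvation shells
outside the filter.  A static 4 x N bead scaffold (gate markers, filter
carbonyl planes, TMD/CTD clouds) is emitted so the geometry analyses run
unmodified.

Two generation modes exist: free diffusion (``generate`` with
``target_rate_events_per_us=None``) and a scheduled-flux mode in which
permeation events are planted as a Poisson process at a configured rate,
giving exact ground truth for rate-recovery tests.  ``script_scenario``
builds small frame-exact trajectories with analytically known outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import LabeledTrajectory, Particle, PoreAxisModel, Role, SITES
from .permeation import PermeationEvent
from .units import kT, voltage_force_kcal_per_mol_A

__all__ = [
    "GateKinetics",
    "SyntheticPoreConfig",
    "GroundTruth",
    "default_pore",
    "generate",
    "script_scenario",
]

#: bulk water number density, molecules per cubic Angstrom
WATER_DENSITY_BULK = 0.0334

#: azimuths of the four subunits; (A, C) and (B, D) are the opposing pairs
SUBUNIT_AZIMUTH = {"A": 45.0, "B": 135.0, "C": 225.0, "D": 315.0}


def default_pore() -> PoreAxisModel:
    """Landmarks of the toy channel (Angstrom, +z toward extracellular)."""
    return PoreAxisModel(
        z_intracellular_entrance=-30.0,
        z_gloop=-20.0,
        z_hbc=-5.0,
        z_site_boundaries=np.arange(6.0, 22.1, 3.0)[:6],
        pore_radius=8.0,
    )


@dataclass
class GateKinetics:
    """First-order open/close flicker of one gate constriction."""

    z: float  # gate plane, Angstrom
    open_rate_per_ns: float
    close_rate_per_ns: float
    open_radius: float  # Angstrom
    closed_radius: float
    closed_barrier_kcal: float = 6.0  # steric block applied when closed
    barrier_width: float = 1.5  # Gaussian sigma, Angstrom

    def __post_init__(self) -> None:
        if self.open_rate_per_ns < 0 or self.close_rate_per_ns < 0:
            raise ValueError("gate rates must be non-negative")
        if self.open_radius <= self.closed_radius:
            raise ValueError("open radius must exceed closed radius")

    @property
    def equilibrium_open_fraction(self) -> float:
        k = self.open_rate_per_ns + self.close_rate_per_ns
        return self.open_rate_per_ns / k if k > 0 else 1.0


def _default_gates(pore: PoreAxisModel) -> dict[str, GateKinetics]:
    # G-loop: flickers on the ns scale, open slightly more often than not;
    # HBC: predominantly open once the channel has relaxed
    return {
        "gloop": GateKinetics(pore.z_gloop, 1.1, 0.9, 3.5, 1.2),
        "hbc": GateKinetics(pore.z_hbc, 5.0, 0.5, 5.0, 1.5),
    }


@dataclass
class SyntheticPoreConfig:
    """Full parameterization of the toy channel.

    Defaults mirror the conditions of the microsecond field simulations the
    analyses were designed for: frames every 20 ps, 310 K, 580 mV over a
    145-Angstrom box, K+ diffusion 0.2 A^2/ps.  ``n_frames`` is the run
    length in stored frames (50,000 = 1 us at the default stride); tests
    and examples pass smaller values.
    """

    seed: int = 0
    n_frames: int = 50_000
    stride_ps: float = 20.0
    box: tuple[float, float, float] = (80.0, 80.0, 145.0)
    pore: PoreAxisModel = field(default_factory=default_pore)
    potential: tuple[np.ndarray, np.ndarray] | None = None  # (z grid, U kcal/mol)
    voltage_mV: float = 580.0
    n_ions: int = 12
    ion_diffusion: float = 0.2  # A^2/ps
    n_waters: int = 480
    water_density_profile: tuple[np.ndarray, np.ndarray] | None = None  # relative
    water_diffusion: float = 0.3
    gate_flicker: dict[str, GateKinetics] | None = None  # None -> defaults, {} -> no gates
    sf_single_occupancy: bool = True
    solvation_shell: int = 6
    substeps: int = 10
    scaffold: bool = True
    boundary: str = "reflecting"  # or "periodic"
    z_limits: tuple[float, float] | None = None
    sf_radius: float = 1.5  # single-file confinement radius inside the filter
    temperature_K: float = 310.0
    # scheduled-flux mode
    target_rate_events_per_us: float | None = None
    transit_time_ns: float = 10.0

    def resolved_gates(self) -> dict[str, GateKinetics]:
        return _default_gates(self.pore) if self.gate_flicker is None else self.gate_flicker

    def resolved_z_limits(self) -> tuple[float, float]:
        if self.z_limits is not None:
            return self.z_limits
        return (self.pore.z_intracellular_entrance - 10.0, self.pore.sf_upper + 10.0)


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the analyses."""

    expected_permeation_rate: float  # events per us (bookkeeping, not detection)
    true_pmf: tuple[np.ndarray, np.ndarray] | None
    gate_open_fraction: dict[str, float]
    planted_events: list[PermeationEvent]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_permeation_rate": self.expected_permeation_rate,
            "true_pmf": None
            if self.true_pmf is None
            else {"z": list(map(float, self.true_pmf[0])), "U": list(map(float, self.true_pmf[1]))},
            "gate_open_fraction": self.gate_open_fraction,
            "planted_events": [asdict(e) for e in self.planted_events],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def _ring_atoms(center: np.ndarray, normal_azimuth_deg: float, radius: float = 1.39):
    """Six phenyl carbons in a vertical plane whose normal points at the axis."""
    phi = np.radians(normal_azimuth_deg)
    # in-plane basis: tangential and z
    t = np.array([-np.sin(phi), np.cos(phi), 0.0])
    u = np.array([0.0, 0.0, 1.0])
    return [
        center + radius * (np.cos(a) * t + np.sin(a) * u)
        for a in np.radians(np.arange(0, 360, 60))
    ]


def _build_scaffold(pore: PoreAxisModel, center_xy: np.ndarray):
    """Bead scaffold particles + template coordinates + dynamic gate bead map.

    Returns (particles, coords, gate_beads) where gate_beads maps gate name
    to a list of (atom index, unit radial direction) whose radial distance
    follows the gate state.
    """
    particles: list[Particle] = []
    coords: list[np.ndarray] = []
    gate_beads: dict[str, list[tuple[int, np.ndarray]]] = {"gloop": [], "hbc": []}
    b = np.sort(np.asarray(pore.z_site_boundaries, dtype=float))
    sf_res = [(154, "THR"), (155, "ILE"), (156, "GLY"), (157, "TYR"), (158, "GLY")]

    def add(subunit, resnum, resname, atom, element, xyz):
        particles.append(
            Particle(
                id=len(particles) + 1,
                role=Role.PROTEIN,
                subunit=subunit,
                residue_number=resnum,
                residue_name=resname,
                atom_name=atom,
                element=element,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))
        return len(particles) - 1

    for su, az in SUBUNIT_AZIMUTH.items():
        phi = np.radians(az)
        u = np.array([np.cos(phi), np.sin(phi), 0.0])  # radial unit vector

        def at(r, z):
            return np.array([center_xy[0], center_xy[1], 0.0]) + r * u + np.array([0.0, 0.0, z])

        # HBC gate: F192 with a phenyl ring at the (dynamic) gate radius
        add(su, 188, "VAL", "CA", "C", at(9.0, pore.z_hbc + 5.5))
        add(su, 192, "PHE", "CA", "C", at(9.0, pore.z_hbc))
        ring_center = at(3.0, pore.z_hbc)
        for name, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                             _ring_atoms(ring_center, az)):
            i = add(su, 192, "PHE", name, "C", xyz)
            gate_beads["hbc"].append((i, u))
        # G-loop gate: G318 carbonyl and M319 side chain at the gate radius
        i = add(su, 318, "GLY", "CA", "C", at(6.5, pore.z_gloop - 0.8))
        i = add(su, 318, "GLY", "O", "O", at(2.0, pore.z_gloop))
        gate_beads["gloop"].append((i, u))
        add(su, 319, "MET", "CA", "C", at(6.5, pore.z_gloop + 0.8))
        i = add(su, 319, "MET", "SD", "S", at(2.0, pore.z_gloop))
        gate_beads["gloop"].append((i, u))
        # selectivity filter: CA ladder + carbonyl-oxygen planes at the
        # six site boundaries (T154 OG1 below the backbone carbonyls)
        for (resnum, resname), z in zip(sf_res, b[1:]):
            add(su, resnum, resname, "CA", "C", at(6.0, z))
        add(su, 154, "THR", "OG1", "O", at(1.4, b[0]))
        for (resnum, resname), z in zip(sf_res, b[1:]):
            add(su, resnum, resname, "O", "O", at(1.4, z))
        # CTD / TMD bead clouds (slightly staggered so the rotation
        # analysis has a non-degenerate per-subunit center of mass)
        for k, z in enumerate(np.linspace(pore.z_intracellular_entrance + 1, pore.z_gloop - 2, 5)):
            phik = np.radians(az + 6.0 * (k - 2))
            uk = np.array([np.cos(phik), np.sin(phik), 0.0])
            add(su, 230 + k, "ALA", "CA", "C",
                np.array([center_xy[0], center_xy[1], 0.0]) + 14.0 * uk + np.array([0, 0, z]))
        for k, z in enumerate(np.linspace(pore.z_hbc + 2, pore.sf_upper + 3, 5)):
            phik = np.radians(az + 6.0 * (k - 2))
            uk = np.array([np.cos(phik), np.sin(phik), 0.0])
            add(su, 95 + k, "LEU", "CA", "C",
                np.array([center_xy[0], center_xy[1], 0.0]) + 14.0 * uk + np.array([0, 0, z]))
    return particles, np.array(coords), gate_beads


def _ion_particles(n: int, start_id: int) -> list[Particle]:
    return [
        Particle(id=start_id + i, role=Role.ION, residue_name="K", atom_name="K", element="K")
        for i in range(n)
    ]


def _water_particles(n: int, start_id: int) -> list[Particle]:
    return [
        Particle(
            id=start_id + i, role=Role.WATER_OXYGEN, residue_name="HOH", atom_name="O", element="O"
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# gate state sampling
# ---------------------------------------------------------------------------

def _sample_gate_states(gate: GateKinetics, n_frames: int, dt_ns: float, rng) -> np.ndarray:
    """Telegraph process at frame resolution; True = open."""
    p_close = min(gate.close_rate_per_ns * dt_ns, 1.0)
    p_open = min(gate.open_rate_per_ns * dt_ns, 1.0)
    states = np.empty(n_frames, dtype=bool)
    state = rng.random() < gate.equilibrium_open_fraction
    for f in range(n_frames):
        u = rng.random()
        if state and u < p_close:
            state = False
        elif not state and u < p_open:
            state = True
        states[f] = state
    return states


# ---------------------------------------------------------------------------
# free-diffusion mode
# ---------------------------------------------------------------------------

def _water_profile(cfg: SyntheticPoreConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg.water_density_profile is not None:
        zg, rel = cfg.water_density_profile
        return np.asarray(zg, dtype=float), np.asarray(rel, dtype=float)
    z_lo, z_hi = cfg.resolved_z_limits()
    zg = np.linspace(z_lo, z_hi, 161)
    rel = np.ones_like(zg)
    # gates are drier than bulk; the filter holds no bulk-like water
    for g in cfg.resolved_gates().values():
        rel *= 1.0 - 0.7 * np.exp(-0.5 * ((zg - g.z) / 2.0) ** 2)
    if cfg.sf_single_occupancy:
        rel[(zg >= cfg.pore.sf_lower) & (zg <= cfg.pore.sf_upper)] = 0.0
    return zg, rel


def _sample_from_profile(zg, rel, n, rng):
    cdf = np.cumsum(np.maximum(rel, 0.0))
    if cdf[-1] <= 0:
        raise ValueError("water density profile is empty")
    cdf = cdf / cdf[-1]
    return np.interp(rng.random(n), cdf, zg)


def generate(config: SyntheticPoreConfig) -> tuple[LabeledTrajectory, GroundTruth]:
    """Generate a labeled trajectory plus its ground truth.

    Deterministic for a fixed seed.  With ``target_rate_events_per_us``
    set, permeation events are scheduled as a Poisson process and planted;
    otherwise ions diffuse freely on the configured potential.
    """
    if config.target_rate_events_per_us is not None:
        return _generate_scheduled(config)
    return _generate_diffusive(config)


def _potential_grids(cfg: SyntheticPoreConfig):
    z_lo, z_hi = cfg.resolved_z_limits()
    if cfg.potential is None:
        zg = np.linspace(z_lo, z_hi, 321)
        U = np.zeros_like(zg)
    else:
        zg = np.asarray(cfg.potential[0], dtype=float)
        U = np.asarray(cfg.potential[1], dtype=float)
        if zg[0] > z_lo + 1e-6 or zg[-1] < z_hi - 1e-6:
            raise ValueError("potential grid must span the pore z range")
    fine = np.linspace(z_lo, z_hi, 2001)
    U_fine = np.interp(fine, zg, U)
    F_fine = -np.gradient(U_fine, fine)
    return zg, U, fine, F_fine


def _max_radius(z, cfg: SyntheticPoreConfig, gate_radii: dict[str, float]) -> np.ndarray:
    """Confinement radius as a function of z given current gate states."""
    r = np.full_like(np.asarray(z, dtype=float), cfg.pore.pore_radius)
    for name, g in cfg.resolved_gates().items():
        near = np.abs(z - g.z) < 1.5
        r[near] = np.minimum(r[near], gate_radii[name])
    if cfg.sf_single_occupancy:
        in_sf = (z >= cfg.pore.sf_lower) & (z <= cfg.pore.sf_upper)
        r[in_sf] = np.minimum(r[in_sf], cfg.sf_radius)
    return r


def _generate_diffusive(cfg: SyntheticPoreConfig):
    rng = np.random.default_rng(cfg.seed)
    pore = cfg.pore
    z_lo, z_hi = cfg.resolved_z_limits()
    center_xy = np.array([cfg.box[0] / 2.0, cfg.box[1] / 2.0])
    zg, U, fine, F_fine = _potential_grids(cfg)
    gates = cfg.resolved_gates()
    kt = kT(cfg.temperature_K)
    f_field = voltage_force_kcal_per_mol_A(cfg.voltage_mV, cfg.box[2])

    # particles
    particles: list[Particle] = []
    scaffold_coords = np.empty((0, 3))
    gate_beads: dict[str, list] = {"gloop": [], "hbc": []}
    if cfg.scaffold:
        particles, scaffold_coords, gate_beads = _build_scaffold(pore, center_xy)
    n_scaffold = len(particles)
    particles += _ion_particles(cfg.n_ions, n_scaffold + 1)
    particles += _water_particles(cfg.n_waters, n_scaffold + cfg.n_ions + 1)

    # gate state series (frame resolution)
    dt_frame_ns = cfg.stride_ps / 1000.0
    gate_states = {name: _sample_gate_states(g, cfg.n_frames, dt_frame_ns, rng)
                   for name, g in gates.items()}

    # initial ion positions: spread over the z range, on-axis-ish
    ion_z = rng.uniform(z_lo + 2, z_hi - 2, cfg.n_ions)
    if cfg.sf_single_occupancy:  # keep the start legal
        in_sf = (ion_z >= pore.sf_lower) & (ion_z <= pore.sf_upper)
        ion_z[in_sf] = rng.uniform(z_lo + 2, pore.sf_lower - 2, int(in_sf.sum()))
    ion_xy = rng.normal(0.0, 1.5, (cfg.n_ions, 2))

    # waters: tracer diffusion on the effective potential -kT ln(rel density),
    # whose stationary distribution is the configured profile
    zw_grid, rel = _water_profile(cfg)
    Uw = -kt * np.log(np.maximum(rel, 1e-3))
    fine_w = np.linspace(z_lo, z_hi, 2001)
    # clip the profile force so the frame-resolution step stays stable at
    # sharp density edges (the hard filter exclusion is enforced separately)
    Fw_fine = np.clip(-np.gradient(np.interp(fine_w, zw_grid, Uw), fine_w), -0.2, 0.2)
    mob_w = cfg.water_diffusion / kt
    wat_z = _sample_from_profile(zw_grid, rel, cfg.n_waters, rng)
    r = cfg.pore.pore_radius * np.sqrt(rng.random(cfg.n_waters))
    th = rng.uniform(0, 2 * np.pi, cfg.n_waters)
    wat_xy = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

    dt = cfg.stride_ps / cfg.substeps
    sig_ion = np.sqrt(2 * cfg.ion_diffusion * dt)
    mob = cfg.ion_diffusion / kt
    lows = np.array([pore.site_windows()[s][0] for s in SITES])
    highs = np.array([pore.site_windows()[s][1] for s in SITES])
    centers = 0.5 * (lows + highs)

    n_particles = len(particles)
    coords = np.empty((cfg.n_frames, n_particles, 3))
    times = np.arange(cfg.n_frames) * cfg.stride_ps
    box_vec = np.asarray(cfg.box, dtype=float).copy()
    if cfg.boundary == "periodic":
        # the simulation cell along z is the dynamics range, so that
        # minimum-image unwrapping reconstructs continuous traces
        box_vec[2] = z_hi - z_lo
    box = np.broadcast_to(box_vec, (cfg.n_frames, 3)).copy()

    # ground-truth rate bookkeeping: signed boundary wraps in periodic runs
    # (an exact flux count), committed-plane logic in reflecting runs
    commit_state = np.zeros(cfg.n_ions, dtype=int)
    outward = 0
    net_wraps = 0
    margin = 2.0

    # precompute gate barrier force helpers
    gate_list = list(gates.items())

    for f in range(cfg.n_frames):
        gate_radii = {
            name: (g.open_radius if gate_states[name][f] else g.closed_radius)
            for name, g in gates.items()
        }
        for _ in range(cfg.substeps):
            Fz = np.interp(ion_z, fine, F_fine) + f_field
            for name, g in gate_list:
                if not gate_states[name][f] and g.closed_barrier_kcal > 0:
                    d = ion_z - g.z
                    Fz += (
                        g.closed_barrier_kcal
                        * d
                        / g.barrier_width**2
                        * np.exp(-0.5 * (d / g.barrier_width) ** 2)
                    )
            ion_z = ion_z + mob * Fz * dt + sig_ion * rng.standard_normal(cfg.n_ions)
            if cfg.boundary == "periodic":
                net_wraps += int(np.sum(ion_z > z_hi)) - int(np.sum(ion_z < z_lo))
                ion_z = z_lo + np.mod(ion_z - z_lo, z_hi - z_lo)
            else:
                ion_z = np.where(ion_z < z_lo, 2 * z_lo - ion_z, ion_z)
                ion_z = np.where(ion_z > z_hi, 2 * z_hi - ion_z, ion_z)
                ion_z = np.clip(ion_z, z_lo, z_hi)
            ion_xy = ion_xy + sig_ion * rng.standard_normal((cfg.n_ions, 2))
            rmax = _max_radius(ion_z, cfg, gate_radii)
            rr = np.linalg.norm(ion_xy, axis=1)
            over = rr > rmax
            if over.any():
                scale = (2 * rmax[over] - rr[over]).clip(min=0.0) / rr[over]
                ion_xy[over] *= scale[:, None]
            # water z-dynamics shares the fine step so the stationary
            # distribution tracks the configured profile accurately
            if cfg.n_waters:
                sig_w_sub = np.sqrt(2 * cfg.water_diffusion * dt)
                prev_wz = wat_z
                wat_z = (
                    wat_z
                    + mob_w * np.interp(wat_z, fine_w, Fw_fine) * dt
                    + sig_w_sub * rng.standard_normal(cfg.n_waters)
                )
                wat_z = np.where(wat_z < z_lo, 2 * z_lo - wat_z, wat_z)
                wat_z = np.where(wat_z > z_hi, 2 * z_hi - wat_z, wat_z)
                wat_z = np.clip(wat_z, z_lo, z_hi)
                if cfg.sf_single_occupancy:
                    entered = (wat_z >= pore.sf_lower - 1.0) & (wat_z <= pore.sf_upper + 1.0)
                    wat_z[entered] = prev_wz[entered]

        # single occupancy + knock-on at frame resolution
        if cfg.sf_single_occupancy and cfg.n_ions:
            order = np.argsort(ion_z)
            last = -1
            for i in order:
                z = ion_z[i]
                if z < lows[0] or z >= highs[-1]:
                    continue
                s = int(np.searchsorted(highs, z, side="right"))
                if s <= last:
                    s = last + 1
                if s > 4:
                    ion_z[i] = highs[-1] + margin + 1.0  # chain ejection
                    continue
                if not (lows[s] <= z < highs[s]):
                    ion_z[i] = centers[s]
                last = s

        # ground-truth outward crossings
        below = ion_z < pore.sf_lower - margin
        above = ion_z > pore.sf_upper + margin
        outward += int(np.sum(above & (commit_state == -1)))
        commit_state[below] = -1
        commit_state[above] = 1

        # water xy-diffusion, radial confinement and solvation re-seeding
        # run at frame resolution (they carry no fine-scale structure)
        if cfg.n_waters:
            sig_w = np.sqrt(2 * cfg.water_diffusion * cfg.stride_ps)
            wat_xy = wat_xy + sig_w * rng.standard_normal((cfg.n_waters, 2))
            rrw = np.linalg.norm(wat_xy, axis=1)
            rw_max = _max_radius(wat_z, cfg, gate_radii)
            overw = rrw > rw_max
            if overw.any():
                scale = (2 * rw_max[overw] - rrw[overw]).clip(min=0.0) / np.maximum(rrw[overw], 1e-9)
                wat_xy[overw] *= scale[:, None]
            # solvation re-seeding outside the filter
            if cfg.solvation_shell > 0 and cfg.n_ions:
                wat_pos = np.concatenate([wat_xy, wat_z[:, None]], axis=1)
                for i in range(cfg.n_ions):
                    if pore.sf_lower <= ion_z[i] <= pore.sf_upper:
                        continue
                    ion_pos = np.array([ion_xy[i, 0], ion_xy[i, 1], ion_z[i]])
                    d = np.linalg.norm(wat_pos - ion_pos, axis=1)
                    close = np.flatnonzero(d <= 3.5)
                    deficit = cfg.solvation_shell - close.size
                    if deficit > 0:
                        # pull the farthest waters onto the shell
                        moved = np.argsort(d)[::-1][:deficit]
                        for w in moved:
                            v = rng.standard_normal(3)
                            v /= np.linalg.norm(v)
                            wat_pos[w] = ion_pos + rng.uniform(2.6, 3.4) * v
                    elif deficit < 0:
                        # release the outermost excess back into the bulk
                        moved = close[np.argsort(d[close])[deficit:]]
                        for w in moved:
                            zb = _sample_from_profile(zw_grid, rel, 1, rng)[0]
                            rb = cfg.pore.pore_radius * np.sqrt(rng.random())
                            tb = rng.uniform(0, 2 * np.pi)
                            wat_pos[w] = np.array([rb * np.cos(tb), rb * np.sin(tb), zb])
                    else:
                        continue
                    wat_xy[moved] = wat_pos[moved, :2]
                    wat_z[moved] = wat_pos[moved, 2]

        # assemble frame
        if n_scaffold:
            frame_scaffold = scaffold_coords + rng.normal(0.0, 0.05, scaffold_coords.shape)
            for name, g in gates.items():
                radius = gate_radii[name]
                for idx, u in gate_beads[name]:
                    radial = scaffold_coords[idx] - np.array([center_xy[0], center_xy[1],
                                                              scaffold_coords[idx][2]])
                    shift = (radius - np.dot(radial[:2], u[:2])) * u
                    frame_scaffold[idx] = frame_scaffold[idx] + shift
            coords[f, :n_scaffold] = frame_scaffold
        coords[f, n_scaffold:n_scaffold + cfg.n_ions, 0] = center_xy[0] + ion_xy[:, 0]
        coords[f, n_scaffold:n_scaffold + cfg.n_ions, 1] = center_xy[1] + ion_xy[:, 1]
        coords[f, n_scaffold:n_scaffold + cfg.n_ions, 2] = ion_z
        if cfg.n_waters:
            w0 = n_scaffold + cfg.n_ions
            coords[f, w0:, 0] = center_xy[0] + wat_xy[:, 0]
            coords[f, w0:, 1] = center_xy[1] + wat_xy[:, 1]
            coords[f, w0:, 2] = wat_z

    traj = LabeledTrajectory(particles, coords, times, box)
    duration_us = cfg.n_frames * cfg.stride_ps / 1e6
    n_transfers = net_wraps if cfg.boundary == "periodic" else outward
    truth = GroundTruth(
        expected_permeation_rate=n_transfers / duration_us if duration_us > 0 else 0.0,
        true_pmf=(zg, U),
        gate_open_fraction={n: float(s.mean()) for n, s in gate_states.items()},
        planted_events=[],
    )
    return traj, truth


# ---------------------------------------------------------------------------
# scheduled-flux (Poisson) mode
# ---------------------------------------------------------------------------

def _generate_scheduled(cfg: SyntheticPoreConfig):
    rng = np.random.default_rng(cfg.seed)
    pore = cfg.pore
    z_lo, z_hi = cfg.resolved_z_limits()
    center_xy = np.array([cfg.box[0] / 2.0, cfg.box[1] / 2.0])
    gates = cfg.resolved_gates()
    duration_ps = cfg.n_frames * cfg.stride_ps
    rate_per_ps = cfg.target_rate_events_per_us / 1e6

    # Poisson arrivals over the run, each one a full pore transit
    arrivals = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_ps) if rate_per_ps > 0 else np.inf
        if t >= duration_ps:
            break
        arrivals.append(t)

    particles: list[Particle] = []
    scaffold_coords = np.empty((0, 3))
    gate_beads: dict[str, list] = {"gloop": [], "hbc": []}
    if cfg.scaffold:
        particles, scaffold_coords, gate_beads = _build_scaffold(pore, center_xy)
    n_scaffold = len(particles)
    n_ions = max(cfg.n_ions, 1)
    particles += _ion_particles(n_ions, n_scaffold + 1)
    particles += _water_particles(cfg.n_waters, n_scaffold + n_ions + 1)

    dt_frame_ns = cfg.stride_ps / 1000.0
    gate_states = {name: _sample_gate_states(g, cfg.n_frames, dt_frame_ns, rng)
                   for name, g in gates.items()}

    # each transit climbs exactly one box length so that recycling is a
    # clean periodic wrap rather than a teleport
    box_z = cfg.box[2]
    transit_ps = cfg.transit_time_ns * 1000.0
    rest_z = rng.uniform(z_lo + 1.0, pore.z_intracellular_entrance - 5.0, n_ions)
    speed = box_z / transit_ps

    # assign arrivals to ion slots; an arrival starts its climb so that the
    # filter is crossed near the arrival time
    busy_until = np.zeros(n_ions)
    transits: list[tuple[int, float]] = []  # (ion index, start time ps)
    for t in arrivals:
        start = t - (pore.sf_lower - rest_z.min()) / speed
        slot = int(np.argmin(busy_until))
        start = max(start, busy_until[slot])
        transits.append((slot, start))
        busy_until[slot] = start + transit_ps

    times = np.arange(cfg.n_frames) * cfg.stride_ps
    # continuous z per ion per frame
    ion_z_cont = np.tile(rest_z[:, None], (1, cfg.n_frames)).astype(float)
    planted: list[PermeationEvent] = []
    margin = 2.0
    for slot, start in transits:
        dtv = times - start
        climb = np.clip(dtv, 0.0, transit_ps) * speed
        ion_z_cont[slot] += climb  # a finished transit has climbed one box length
        t_entry = start + (pore.sf_lower - margin - rest_z[slot]) / speed
        t_exit = start + (pore.sf_upper + margin - rest_z[slot]) / speed
        if t_exit < duration_ps:
            planted.append(
                PermeationEvent(
                    ion_id=particles[n_scaffold + slot].id,
                    interval="SF_full",
                    entry_frame=int(np.searchsorted(times, t_entry)),
                    exit_frame=int(np.searchsorted(times, t_exit)),
                    entry_time=t_entry,
                    exit_time=t_exit,
                    direction="outward",
                )
            )

    # wrap into the box frame and add a little positional noise
    ion_z = z_lo + np.mod(ion_z_cont - z_lo, box_z)
    ion_z += rng.normal(0.0, 0.2, ion_z.shape)
    ion_xy = rng.normal(0.0, 0.8, (n_ions, cfg.n_frames, 2))

    # waters: equilibrium tracer field, no filter water
    zw_grid, rel = _water_profile(cfg)
    if cfg.n_waters:
        wat_z0 = _sample_from_profile(zw_grid, rel, cfg.n_waters, rng)
        r = pore.pore_radius * np.sqrt(rng.random(cfg.n_waters))
        th = rng.uniform(0, 2 * np.pi, cfg.n_waters)
        wat_xy0 = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

    coords = np.empty((cfg.n_frames, len(particles), 3))
    box = np.broadcast_to(np.asarray(cfg.box, dtype=float), (cfg.n_frames, 3)).copy()
    for f in range(cfg.n_frames):
        if n_scaffold:
            gate_radii = {
                name: (g.open_radius if gate_states[name][f] else g.closed_radius)
                for name, g in gates.items()
            }
            frame_scaffold = scaffold_coords + rng.normal(0.0, 0.05, scaffold_coords.shape)
            for name, g in gates.items():
                for idx, u in gate_beads[name]:
                    radial = scaffold_coords[idx] - np.array(
                        [center_xy[0], center_xy[1], scaffold_coords[idx][2]]
                    )
                    shift = (gate_radii[name] - np.dot(radial[:2], u[:2])) * u
                    frame_scaffold[idx] = frame_scaffold[idx] + shift
            coords[f, :n_scaffold] = frame_scaffold
        coords[f, n_scaffold:n_scaffold + n_ions, 0] = center_xy[0] + ion_xy[:, f, 0]
        coords[f, n_scaffold:n_scaffold + n_ions, 1] = center_xy[1] + ion_xy[:, f, 1]
        coords[f, n_scaffold:n_scaffold + n_ions, 2] = ion_z[:, f]
        if cfg.n_waters:
            w0 = n_scaffold + n_ions
            jitter = np.random.default_rng((cfg.seed, f)).normal(0.0, 0.3, (cfg.n_waters, 3))
            coords[f, w0:, 0] = center_xy[0] + wat_xy0[:, 0] + jitter[:, 0]
            coords[f, w0:, 1] = center_xy[1] + wat_xy0[:, 1] + jitter[:, 1]
            coords[f, w0:, 2] = wat_z0 + jitter[:, 2]

    traj = LabeledTrajectory(particles, coords, times, box)
    duration_us = duration_ps / 1e6
    truth = GroundTruth(
        expected_permeation_rate=len(planted) / duration_us,
        true_pmf=None,
        gate_open_fraction={n: float(s.mean()) for n, s in gate_states.items()},
        planted_events=planted,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# scripted scenarios (frame-exact, no noise)
# ---------------------------------------------------------------------------

def script_scenario(name: str, **params) -> tuple[LabeledTrajectory, GroundTruth]:
    """Hand-constructed trajectories with exactly known analysis outcomes."""
    builders = {
        "single_crossing": _scenario_single_crossing,
        "flicker_no_crossing": _scenario_flicker,
        "knockon_chain": _scenario_knockon_chain,
        "hbond_pair": _scenario_hbond_pair,
        "rotated_ctd": _scenario_rotated_ctd,
    }
    if name not in builders:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(builders)}")
    return builders[name](**params)


def _scenario_base(pore: PoreAxisModel | None, n_frames: int, extra: list[Particle],
                   stride_ps: float = 20.0):
    pore = pore or default_pore()
    box = np.array([80.0, 80.0, 145.0])
    center_xy = box[:2] / 2.0
    particles, scaffold, _ = _build_scaffold(pore, center_xy)
    particles = particles + [
        Particle(
            id=len(particles) + 1 + i, role=p.role, subunit=p.subunit,
            residue_number=p.residue_number, residue_name=p.residue_name,
            atom_name=p.atom_name, element=p.element,
        )
        for i, p in enumerate(extra)
    ]
    coords = np.empty((n_frames, len(particles), 3))
    coords[:, : scaffold.shape[0]] = scaffold[None, :, :]
    times = np.arange(n_frames) * stride_ps
    return pore, box, center_xy, particles, coords, times, scaffold.shape[0]


def _scenario_single_crossing(pore: PoreAxisModel | None = None, n_frames: int = 200):
    """One ion travels the whole pore; exactly one full-filter event."""
    ion = Particle(id=0, role=Role.ION, residue_name="K", atom_name="K", element="K")
    pore, box, cxy, particles, coords, times, n0 = _scenario_base(pore, n_frames, [ion])
    z = np.linspace(pore.z_intracellular_entrance - 10.0, pore.sf_upper + 10.0, n_frames)
    coords[:, n0, 0] = cxy[0]
    coords[:, n0, 1] = cxy[1]
    coords[:, n0, 2] = z
    traj = LabeledTrajectory(particles, coords, times, box)
    margin = 2.0
    entry = int(np.searchsorted(z, pore.sf_lower - margin))
    exit_ = int(np.searchsorted(z, pore.sf_upper + margin))
    ev = PermeationEvent(particles[n0].id, "SF_full", entry - 1, exit_,
                         times[entry - 1], times[exit_], "outward")
    return traj, GroundTruth(0.0, None, {}, [ev])


def _scenario_flicker(pore: PoreAxisModel | None = None, n_recrossings: int = 20):
    """An ion oscillates across the HBC plane; no committed crossing."""
    pore = pore or default_pore()
    n_frames = 2 * n_recrossings + 1
    ion = Particle(id=0, role=Role.ION, residue_name="K", atom_name="K", element="K")
    pore, box, cxy, particles, coords, times, n0 = _scenario_base(pore, n_frames, [ion])
    z = pore.z_hbc + np.where(np.arange(n_frames) % 2 == 0, -1.0, 1.0)
    coords[:, n0, 0] = cxy[0]
    coords[:, n0, 1] = cxy[1]
    coords[:, n0, 2] = z
    traj = LabeledTrajectory(particles, coords, times, box)
    return traj, GroundTruth(0.0, None, {}, [])


def _scenario_knockon_chain(pore: PoreAxisModel | None = None, water_mediated: bool = False,
                            hold: int = 4):
    """Single-file advance through the filter sites.

    Direct mode: two resident ions sit in S3/S2 with no waters anywhere in
    the filter; a walker ion climbs from the bulk, enters S4 and the whole
    file advances one site per phase until the walker leaves on the
    extracellular side.  Water-mediated mode moves a strictly alternating
    K-W-K-W-K single file (one-site spacing) through the filter, so every
    ion-ion gap always holds a water and one water fully co-permeates.
    """
    pore = pore or default_pore()
    windows = pore.site_windows()
    centers = {s: 0.5 * (windows[s][0] + windows[s][1]) for s in SITES}
    step = windows["S4"][1] - windows["S4"][0]
    b0 = windows["S4"][0]

    extra = [Particle(id=0, role=Role.ION, residue_name="K", atom_name="K", element="K")
             for _ in range(3)]
    n_waters = 2 if water_mediated else 0
    extra += [Particle(id=0, role=Role.WATER_OXYGEN, residue_name="HOH", atom_name="O",
                       element="O") for _ in range(n_waters)]

    phases = []
    if water_mediated:
        # contiguous alternating file, bottom to top: walker K, W, K, W, K;
        # the walker and the first water start below the committed plane so
        # that both score committed filter crossings
        chain = b0 + np.array([-6.5, -3.5, -0.5, 2.5, 5.5])
        n_phases = 12
        for _ in range(n_phases):
            phases.append(chain.copy())
            chain = chain + step
    else:
        # walker deep in the bulk; residents at S3 and S2
        chain = np.array([pore.z_intracellular_entrance - 8.0, centers["S3"], centers["S2"]])
        n_phases = 14
        for k in range(n_phases):
            phases.append(chain.copy())
            if k == 0:
                chain[0] = b0 - 3.0  # walker approaches the filter entrance
            else:
                chain = chain + step  # the file advances one site
                chain[0] = min(chain[0], centers["S4"] + (k - 1) * step)
    # expand phases into frames (hold each phase so stride halving is safe)
    frames = np.repeat(np.arange(n_phases), hold)
    n_frames = len(frames)
    pore, box, cxy, particles, coords, times, n0 = _scenario_base(pore, n_frames, extra)
    zs = np.stack([phases[p] for p in frames])  # (n_frames, chain length)
    # map chain order (bottom to top) onto particle columns (ions first)
    if water_mediated:
        col_order = [0, 3, 1, 4, 2]  # walker, W1, ion1, W2, ion2
    else:
        col_order = [0, 1, 2]
    for chain_pos, rel_col in enumerate(col_order):
        coords[:, n0 + rel_col, 0] = cxy[0]
        coords[:, n0 + rel_col, 1] = cxy[1]
        coords[:, n0 + rel_col, 2] = zs[:, chain_pos]
    traj = LabeledTrajectory(particles, coords, times, box)
    walker_id = particles[n0].id
    z_walker = zs[:, 0]
    margin = 2.0
    entry = int(np.argmax(z_walker >= pore.sf_lower - margin)) - 1
    exitf = int(np.argmax(z_walker > pore.sf_upper + margin))
    ev = PermeationEvent(walker_id, "SF_full", max(entry, 0), exitf,
                         times[max(entry, 0)], times[exitf], "outward")
    return traj, GroundTruth(0.0, None, {}, [ev])


def _scenario_hbond_pair(distance: float = 2.9, angle_deg: float = 0.0,
                         broken_fraction: float = 0.0, n_frames: int = 10):
    """A donor-H-acceptor triple at a set geometry (optionally broken part-time)."""
    donor = Particle(id=0, role=Role.PROTEIN, subunit="A", residue_number=150,
                     residue_name="GLU", atom_name="OE1", element="O")
    hydrogen = Particle(id=0, role=Role.PROTEIN, subunit="A", residue_number=150,
                        residue_name="GLU", atom_name="HE1", element="H")
    acceptor = Particle(id=0, role=Role.PROTEIN, subunit="B", residue_number=160,
                        residue_name="ARG", atom_name="NH1", element="N")
    pore, box, cxy, particles, coords, times, n0 = _scenario_base(None, n_frames,
                                                                  [donor, hydrogen, acceptor])
    base = np.array([cxy[0] + 20.0, cxy[1] + 20.0, 50.0])
    a = np.radians(angle_deg)
    d_pos = base
    h_pos = base + np.array([1.0, 0.0, 0.0])
    acc_pos = base + distance * np.array([np.cos(a), np.sin(a), 0.0])
    coords[:, n0] = d_pos
    coords[:, n0 + 1] = h_pos
    coords[:, n0 + 2] = acc_pos
    n_broken = int(round(broken_fraction * n_frames))
    if n_broken:
        coords[-n_broken:, n0 + 2] = base + np.array([0.0, 0.0, 8.0])
    traj = LabeledTrajectory(particles, coords, times, box)
    return traj, GroundTruth(0.0, None, {}, [])


def _scenario_rotated_ctd(angle: float = -4.0, n_frames: int = 5):
    """CTD bead cloud rotated about the pore axis by a set reported angle.

    ``angle`` is the value the rotation analysis should report: negative
    for a counterclockwise rotation viewed from the extracellular side.
    """
    pore, box, cxy, particles, coords, times, n0 = _scenario_base(None, n_frames, [])
    # counterclockwise (positive mathematical sense about +z) prints as
    # negative, so rotate by -angle mathematically
    theta = np.radians(-angle)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    ctd_rows = [i for i, p in enumerate(particles) if p.residue_number and 230 <= p.residue_number <= 234]
    for f in range(1, n_frames):
        xy = coords[f, ctd_rows, :2] - cxy
        coords[f, ctd_rows, :2] = xy @ R.T + cxy
    traj = LabeledTrajectory(particles, coords, times, box)
    return traj, GroundTruth(0.0, None, {}, [])
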
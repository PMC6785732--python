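"""Generator ground truth: determinism, equilibrium statistics, drift,
gate kinetics and the single-occupancy knock-on rule."""

import numpy as np
import pytest
from scipy import stats

from permeon import permeation
from permeon.model import Role, Selection, SITES
from permeon.synthetic import (
    GateKinetics,
    SyntheticPoreConfig,
    default_pore,
    generate,
    script_scenario,
)
from permeon.units import kT, voltage_force_kcal_per_mol_A

Z_LIMITS = (-40.0, 31.0)


def _equilibrium_cfg(**kw):
    base = dict(seed=7, n_frames=20000, stride_ps=20.0, voltage_mV=0.0, n_ions=4,
                ion_diffusion=0.5, n_waters=0, gate_flicker={},
                sf_single_occupancy=False, scaffold=False, boundary="reflecting",
                z_limits=Z_LIMITS)
    base.update(kw)
    return SyntheticPoreConfig(**base)


class TestBasics:
    def test_same_seed_identical_trajectories(self):
        cfg = SyntheticPoreConfig(seed=9, n_frames=50, n_ions=3, n_waters=40)
        t1, _ = generate(cfg)
        t2, _ = generate(cfg)
        assert np.array_equal(t1.coords, t2.coords)

    def test_zero_ions_zero_permeation(self, pore):
        cfg = SyntheticPoreConfig(seed=1, n_frames=100, n_ions=0, n_waters=10,
                                  scaffold=False, sf_single_occupancy=False)
        traj, truth = generate(cfg)
        assert truth.expected_permeation_rate == 0.0
        assert traj.select(Selection(role=Role.ION)).size == 0

    def test_gate_open_fraction_matches_kinetics(self, pore):
        gate = GateKinetics(pore.z_gloop, 1.1, 0.9, 3.5, 1.2)
        cfg = SyntheticPoreConfig(seed=2, n_frames=20000, n_ions=0, n_waters=0,
                                  scaffold=False, gate_flicker={"gloop": gate},
                                  sf_single_occupancy=False)
        _, truth = generate(cfg)
        expected = gate.equilibrium_open_fraction  # 0.55
        assert abs(truth.gate_open_fraction["gloop"] - expected) < 0.08

    def test_invalid_gate_radii_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            GateKinetics(0.0, 1.0, 1.0, open_radius=1.0, closed_radius=2.0)


class TestEquilibriumStatistics:
    def test_flat_potential_uniform_histogram(self):
        """Zero field, reflecting ends: z-histogram uniform within 3-sigma."""
        cfg = _equilibrium_cfg(seed=13, n_frames=10000)
        traj, _ = generate(cfg)
        cols = traj.select(Selection(role=Role.ION))
        z = traj.coords[2000:, cols, 2].ravel()  # discard equilibration
        counts, _ = np.histogram(z, bins=10, range=Z_LIMITS)
        # frames are correlated; scale Poisson bands by the mixing time in
        # frames (~ L_bin^2 / 2D / stride)
        n_eff = len(z) / 18.0
        expected = n_eff / 10
        scaled = counts * n_eff / len(z)
        assert np.all(np.abs(scaled - expected) < 3 * np.sqrt(expected))

    def test_boltzmann_sampling_of_planted_potential(self):
        """Occupancy of a planted double-well follows exp(-U/kT) (KS < 0.05)."""
        zg = np.linspace(*Z_LIMITS, 285)
        U = 2.0 * np.exp(-0.5 * ((zg + 12.0) / 3.0) ** 2) \
            + 1.5 * np.exp(-0.5 * ((zg - 13.0) / 2.5) ** 2)
        cfg = _equilibrium_cfg(seed=17, n_frames=50000, potential=(zg, U))
        traj, _ = generate(cfg)
        cols = traj.select(Selection(role=Role.ION))
        z = traj.coords[5000:, cols, 2].ravel()
        dens = np.exp(-U / kT())
        cdf_grid = np.cumsum(dens)
        cdf_grid /= cdf_grid[-1]
        ks = stats.kstest(z, lambda x: np.interp(x, zg, cdf_grid)).statistic
        assert ks < 0.05

    def test_field_drift_matches_mobility_times_force(self):
        """Flat potential with field on: net drift = (D/kT) F within 10%."""
        cfg = _equilibrium_cfg(seed=3, n_frames=4000, voltage_mV=580.0,
                               ion_diffusion=0.2, boundary="periodic", n_ions=6)
        traj, _ = generate(cfg)
        pore = default_pore()
        drifts = [
            (tr.z[-1] - tr.z[0]) / (traj.times[-1] - traj.times[0])
            for tr in permeation.ion_traces(traj, pore)
        ]
        v_theory = cfg.ion_diffusion / kT() * voltage_force_kcal_per_mol_A(
            cfg.voltage_mV, cfg.box[2]
        )
        assert np.mean(drifts) == pytest.approx(v_theory, rel=0.10)


class TestKnockOnRule:
    def test_ion_count_conserved_and_no_site_sharing(self, pore):
        cfg = SyntheticPoreConfig(seed=21, n_frames=3000, voltage_mV=580.0, n_ions=8,
                                  n_waters=0, gate_flicker={}, scaffold=False,
                                  boundary="periodic", z_limits=Z_LIMITS,
                                  sf_single_occupancy=True)
        traj, _ = generate(cfg)
        cols = traj.select(Selection(role=Role.ION))
        assert cols.size == 8  # conservation: nobody vanished
        windows = pore.site_windows()
        z = traj.coords[:, cols, 2]
        for lo, hi in windows.values():
            per_frame = np.sum((z >= lo) & (z < hi), axis=1)
            assert per_frame.max() <= 1

    def test_scripted_start_overfilled_filter_rejected(self, pore):
        # an alternating start is legal; the generator itself relocates any
        # illegally seeded ion rather than emitting a double occupancy
        cfg = SyntheticPoreConfig(seed=4, n_frames=200, n_ions=10, n_waters=0,
                                  gate_flicker={}, scaffold=False,
                                  boundary="reflecting", z_limits=Z_LIMITS)
        traj, _ = generate(cfg)
        cols = traj.select(Selection(role=Role.ION))
        z0 = traj.coords[0, cols, 2]
        for lo, hi in pore.site_windows().values():
            assert np.sum((z0 >= lo) & (z0 < hi)) <= 1


class TestScheduledFlux:
    def test_planted_events_match_detection(self, pore):
        cfg = SyntheticPoreConfig(seed=5, n_frames=8000, stride_ps=100.0, n_ions=5,
                                  n_waters=0, scaffold=False,
                                  target_rate_events_per_us=12.0)
        traj, truth = generate(cfg)
        detected = []
        for tr in permeation.ion_traces(traj, pore):
            detected += [e for e in permeation.detect_events(
                tr, "SF_full", pore, periodic_box_z=float(traj.box[0, 2]))
                if e.direction == "outward"]
        assert len(detected) == len(truth.planted_events)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            script_scenario("does_not_exist")


class TestWaterField:
    def test_configured_density_profile_reproduced(self, pore):
        """Chi-square of the stationary water histogram vs the profile."""
        z_lo, z_hi = Z_LIMITS
        zg = np.linspace(z_lo, z_hi, 161)
        rel = np.ones_like(zg)
        rel[(zg > -25) & (zg < -15)] = 0.45  # one smooth dry patch
        rel = np.convolve(rel, np.ones(9) / 9.0, mode="same")
        cfg = SyntheticPoreConfig(seed=6, n_frames=3000, n_ions=0, n_waters=300,
                                  gate_flicker={}, scaffold=False,
                                  sf_single_occupancy=False, boundary="reflecting",
                                  z_limits=Z_LIMITS, water_density_profile=(zg, rel))
        traj, _ = generate(cfg)
        cols = traj.select(Selection(role=Role.WATER_OXYGEN))
        z = traj.coords[500:, cols, 2].ravel()
        edges = np.linspace(z_lo + 2, z_hi - 2, 15)
        obs, _ = np.histogram(z, bins=edges)
        # expected counts are the bin integrals of the profile, not its
        # value at the bin center (the profile is steep at the patch edges)
        fine = np.linspace(edges[0], edges[-1], 4001)
        dens = np.interp(fine, zg, rel)
        exp = np.array([
            dens[(fine >= a) & (fine < b)].mean() for a, b in zip(edges[:-1], edges[1:])
        ])
        exp = exp / exp.sum() * obs.sum()
        # error model: Poisson counting noise plus a 2% systematic floor for
        # integrator discretization; reduced chi-square below 3
        var = exp + (0.02 * exp) ** 2
        chi2 = np.sum((obs - exp) ** 2 / var) / (len(obs) - 1)
        assert chi2 < 3.0
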
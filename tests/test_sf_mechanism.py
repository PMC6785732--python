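"""Filter site assignment, co-permeation, and knock-on classification."""

import numpy as np
import pytest

from permeon import permeation, sf_mechanism
from permeon.permeation import PermeationEvent
from permeon.sf_mechanism import SiteOccupancyStates, _gaps_with_water
from permeon.synthetic import SyntheticPoreConfig, generate, script_scenario

from conftest import ion, make_traj, water

CENTER = np.array([40.0, 40.0])


def _filter_traj(pore, site_content, n_frames=1):
    """Particles parked at site centers; site_content maps site -> 'K'|'W'."""
    windows = pore.site_windows()
    particles, zs, kinds = [], [], []
    pid = 1
    for site, kind in site_content.items():
        lo, hi = windows[site]
        particles.append(ion(pid) if kind == "K" else water(pid))
        zs.append(0.5 * (lo + hi))
        pid += 1
    coords = np.zeros((n_frames, len(particles), 3))
    coords[:, :, 0] = CENTER[0]
    coords[:, :, 1] = CENTER[1]
    coords[:, :, 2] = zs
    return make_traj(particles, coords)


class TestAssignSites:
    def test_classical_alternating_start_state(self, pore):
        """Ions in S0/S2/S4 and waters in S1/S3 read back as KWKWK."""
        traj = _filter_traj(pore, {"S4": "K", "S3": "W", "S2": "K", "S1": "W", "S0": "K"})
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        assert states.strings() == ["KWKWK"]

    def test_empty_filter(self, pore):
        traj = make_traj([ion(1)], np.zeros((2, 1, 3)) + 1.0)
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        assert states.strings() == ["00000", "00000"]

    def test_boundary_ion_goes_to_lower_site(self, pore):
        windows = pore.site_windows()
        traj = make_traj([ion(1)], np.zeros((1, 1, 3)))
        traj.coords[0, 0, :2] = CENTER
        traj.coords[0, 0, 2] = windows["S3"][0]  # exactly on the S4/S3 boundary
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        assert states.strings() == ["0K000"]  # left-closed: belongs to S3

    def test_ion_priority_over_water(self, pore):
        windows = pore.site_windows()
        zc = 0.5 * sum(windows["S2"])
        particles = [ion(1), water(2)]
        coords = np.zeros((1, 2, 3))
        coords[0, :, :2] = CENTER
        coords[0, :, 2] = zc
        traj = make_traj(particles, coords)
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        assert states.strings() == ["00K00"]
        assert states.multi_occupancy[0]

    def test_radial_cutoff_excludes_offaxis(self, pore):
        traj = _filter_traj(pore, {"S2": "K"})
        traj.coords[0, 0, 0] = CENTER[0] + 4.5  # beyond the 4-A filter radius
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        assert states.strings() == ["00000"]


class TestClassification:
    def _run(self, scenario_kwargs, pore):
        traj, truth = script_scenario("knockon_chain", **scenario_kwargs)
        events = []
        for tr in permeation.ion_traces(traj, pore):
            events += [e for e in permeation.detect_events(tr, "SF_full", pore)
                       if e.direction == "outward"]
        states = sf_mechanism.assign_sites(traj, pore)
        coperm, _ = sf_mechanism.water_copermeation(traj, pore, events)
        return sf_mechanism.classify_mechanism(states, events, coperm), coperm

    def test_direct_chain_is_direct_with_no_waters(self, pore):
        calls, coperm = self._run({}, pore)
        assert len(calls) == 1
        assert calls[0].mechanism == "direct_knock_on"
        assert coperm == [0]

    def test_alternating_file_is_water_mediated_with_copermeation(self, pore):
        calls, coperm = self._run({"water_mediated": True}, pore)
        assert len(calls) == 1
        assert calls[0].mechanism == "water_mediated"
        assert coperm[0] >= 1

    def test_classification_invariant_to_stride_halving(self, pore):
        for kwargs, expected in (({}, "direct_knock_on"),
                                 ({"water_mediated": True}, "water_mediated")):
            traj, _ = script_scenario("knockon_chain", **kwargs)
            half = make_traj(traj.particles, traj.coords[::2], stride_ps=40.0,
                             box=traj.box[0])
            events = []
            for tr in permeation.ion_traces(half, pore):
                events += [e for e in permeation.detect_events(tr, "SF_full", pore)
                           if e.direction == "outward"]
            states = sf_mechanism.assign_sites(half, pore)
            coperm, _ = sf_mechanism.water_copermeation(half, pore, events)
            calls = sf_mechanism.classify_mechanism(states, events, coperm)
            assert [c.mechanism for c in calls] == [expected]

    def test_generator_waterless_runs_all_direct(self, pore):
        """Scheduled-flux runs with a water-free filter classify 100% direct."""
        total = 0
        for seed in range(3):
            cfg = SyntheticPoreConfig(seed=seed, n_frames=4000, stride_ps=100.0,
                                      n_ions=4, n_waters=60, scaffold=True,
                                      target_rate_events_per_us=15.0)
            traj, _ = generate(cfg)
            events = []
            for tr in permeation.ion_traces(traj, pore):
                events += [e for e in permeation.detect_events(
                    tr, "SF_full", pore, periodic_box_z=float(traj.box[0, 2]))
                    if e.direction == "outward"]
            states = sf_mechanism.assign_sites(traj, pore)
            coperm, _ = sf_mechanism.water_copermeation(traj, pore, events)
            calls = sf_mechanism.classify_mechanism(states, events, coperm)
            assert len(calls) > 0
            assert all(c.mechanism == "direct_knock_on" for c in calls)
            total += len(calls)
        assert total >= 10

    def test_gap_scan_agrees_with_brute_force_oracle(self, rng):
        """Randomized occupancy strings: per-frame W-in-gap scan vs brute force."""
        for _ in range(200):
            row = rng.choice(list("KW0"), 5)
            gaps, wet = _gaps_with_water(row)
            ks = [i for i, s in enumerate(row) if s == "K"]
            expected_gaps = max(len(ks) - 1, 0)
            expected_wet = sum(
                1 for a, b in zip(ks[:-1], ks[1:]) if "W" in "".join(row[a + 1:b])
            )
            assert (gaps, wet) == (expected_gaps, expected_wet)

    def test_randomized_states_classification_oracle(self, rng):
        """Event calls agree with an exhaustive per-frame scan."""
        for _ in range(60):
            n = 12
            symbols = rng.choice(list("KW0"), (n, 5))
            states = SiteOccupancyStates(np.arange(n) * 20.0, symbols.astype("<U1"),
                                         np.zeros(n, bool))
            ev = PermeationEvent(1, "SF_full", 2, 9, 40.0, 180.0, "outward")
            call = sf_mechanism.classify_mechanism(states, [ev], [0])[0]
            g = w = 0
            for f in range(2, 10):
                gi, wi = _gaps_with_water(symbols[f])
                g += gi
                w += wi
            if w == 0:
                expected = "direct_knock_on"
            elif g > 0 and w == g:
                expected = "water_mediated"
            else:
                expected = "mixed"
            assert call.mechanism == expected


class TestOccupancyProfile:
    def test_parked_ion_fraction_one(self, pore):
        traj = _filter_traj(pore, {"S2": "K"}, n_frames=7)
        states = sf_mechanism.assign_sites(traj, pore, sf_sel=None)
        prof = sf_mechanism.site_ion_occupancy_profile(states)
        assert prof == {"S4": 0.0, "S3": 0.0, "S2": 1.0, "S1": 0.0, "S0": 0.0}

    def test_fractions_match_direct_recount(self, rng):
        n = 40
        symbols = rng.choice(list("KW0"), (n, 5)).astype("<U1")
        states = SiteOccupancyStates(np.arange(n) * 20.0, symbols, np.zeros(n, bool))
        prof = sf_mechanism.site_ion_occupancy_profile(states)
        for i, site in enumerate(("S4", "S3", "S2", "S1", "S0")):
            assert prof[site] == pytest.approx(np.mean(symbols[:, i] == "K"))

    def test_empty_series_rejected(self):
        states = SiteOccupancyStates(np.array([]), np.empty((0, 5), "<U1"),
                                     np.array([], bool))
        with pytest.raises(ValueError):
            sf_mechanism.site_ion_occupancy_profile(states)
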
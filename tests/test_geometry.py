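"""Distance, dihedral, RMSD, rotation and cation-pi operators vs oracles."""

import numpy as np
import pytest

from permeon import geometry
from permeon.model import Role, Selection
from permeon.synthetic import script_scenario

from conftest import ion, make_traj, protein_atom


def _cloud_traj(rng, n_a=20, n_b=20, n_frames=5):
    particles = [protein_atom(i + 1, "A", 100) for i in range(n_a)]
    particles += [protein_atom(n_a + i + 1, "B", 200) for i in range(n_b)]
    coords = rng.normal(50.0, 6.0, (n_frames, n_a + n_b, 3))
    return make_traj(particles, coords), n_a


class TestMinDistance:
    def test_two_atoms_known_distance(self):
        particles = [protein_atom(1, "A", 1), protein_atom(2, "B", 2)]
        coords = np.array([[[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]]) + 50.0
        traj = make_traj(particles, coords)
        d = geometry.min_distance(traj, Selection(subunit="A"), Selection(subunit="B"))
        assert d.values[0] == pytest.approx(4.0)

    def test_matches_brute_force_over_random_clouds(self, rng):
        traj, n_a = _cloud_traj(rng)
        series = geometry.min_distance(traj, Selection(subunit="A"), Selection(subunit="B"))
        for f in range(traj.n_frames):
            expected = min(
                np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                for i in range(n_a)
                for j in range(n_a, traj.n_particles)
            )
            assert series.values[f] == pytest.approx(expected, abs=1e-12)

    def test_identical_selections_rejected(self, rng):
        traj, _ = _cloud_traj(rng)
        with pytest.raises(ValueError, match="ambiguous"):
            geometry.min_distance(traj, Selection(subunit="A"), Selection(subunit="A"))

    def test_narrower_pair_is_elementwise_minimum(self, rng):
        particles = [protein_atom(i + 1, "ABCD"[i], 319) for i in range(4)]
        coords = rng.normal(50.0, 5.0, (6, 4, 3))
        traj = make_traj(particles, coords)
        pair1 = (Selection(subunit="A"), Selection(subunit="C"))
        pair2 = (Selection(subunit="B"), Selection(subunit="D"))
        narrow = geometry.narrower_pair_series(traj, pair1, pair2)
        d1 = geometry.min_distance(traj, *pair1)
        d2 = geometry.min_distance(traj, *pair2)
        assert np.allclose(narrow.values, np.minimum(d1.values, d2.values))


class TestCalphaDistance:
    def test_crystal_structure_hbc_marker(self):
        """Opposing F192 Calphas placed 15.3 A apart read back exactly."""
        particles = [
            protein_atom(1, "A", 192, "PHE"),
            protein_atom(2, "C", 192, "PHE"),
        ]
        coords = np.array([[[0.0, 0.0, 0.0], [15.3, 0.0, 0.0]]]) + 40.0
        traj = make_traj(particles, coords)
        d = geometry.calpha_distance(traj, 192, ("A", "C"))
        assert d.values[0] == pytest.approx(15.3)

    def test_invariant_under_global_rotation(self, rng):
        particles = [protein_atom(1, "A", 157, "TYR"), protein_atom(2, "C", 157, "TYR")]
        base = rng.normal(0.0, 5.0, (2, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        coords = np.stack([base, base @ R.T])
        traj = make_traj(particles, coords + 50.0)
        # rotation applied to frame 1 only shifts nothing if both atoms rotate
        d = geometry.calpha_distance(traj, 157, ("A", "C"))
        assert d.values[1] == pytest.approx(d.values[0], abs=1e-9)

    def test_min_distance_bounded_by_calpha_distance(self, rng):
        particles = [
            protein_atom(1, "A", 192, "PHE", "CA"),
            protein_atom(2, "A", 192, "PHE", "CB"),
            protein_atom(3, "C", 192, "PHE", "CA"),
            protein_atom(4, "C", 192, "PHE", "CB"),
        ]
        coords = rng.normal(50.0, 4.0, (8, 4, 3))
        traj = make_traj(particles, coords)
        dmin = geometry.min_distance(traj, Selection(subunit="A"), Selection(subunit="C"))
        dca = geometry.calpha_distance(traj, 192, ("A", "C"))
        assert np.all(dmin.values <= dca.values + 1e-12)


class TestHistogram:
    def test_counts_and_bins(self):
        h = geometry.histogram(np.array([1.0, 1.0, 2.0, 3.0]), 1.0)
        assert h.counts.sum() == 4
        assert dict(zip(h.bin_left_edges, h.counts)) == {1.0: 2, 2.0: 1, 3.0: 1}

    def test_threshold_fraction_exact(self):
        h = geometry.histogram(np.array([5.0, 6.0, 7.0, 8.0]), 1.0, threshold=6.4)
        assert h.fraction_above == pytest.approx(0.5)

    def test_fraction_matches_raw_count(self, rng):
        values = rng.normal(6.0, 2.0, 500)
        h = geometry.histogram(values, 0.5, threshold=6.4)
        assert h.fraction_above == pytest.approx(np.mean(values > 6.4))

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            geometry.histogram(np.array([1.0]), 0.0)


class TestRmsd:
    def test_identical_and_translated_frames_are_zero(self, rng):
        particles = [protein_atom(i + 1, "A", 100 + i) for i in range(5)]
        base = rng.normal(50.0, 3.0, (5, 3))
        coords = np.stack([base, base, base + np.array([1.0, 0.0, 0.0])])
        traj = make_traj(particles, coords)
        series = geometry.backbone_rmsd(traj, Selection(subunit="A"))
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_known_perturbation_closed_form(self, rng):
        """Perturbing k atoms by delta without fitting gives sqrt(k d^2 / N)."""
        n, k, delta = 10, 3, 0.7
        particles = [protein_atom(i + 1, "A", 100 + i) for i in range(n)]
        base = rng.normal(50.0, 3.0, (n, 3))
        moved = base.copy()
        moved[:k, 0] += delta
        traj = make_traj(particles, np.stack([base, moved]))
        series = geometry.backbone_rmsd(traj, Selection(subunit="A"), fit=False)
        assert series.values[1] == pytest.approx(np.sqrt(k * delta**2 / n))


class TestDihedral:
    def _quad_traj(self, pts):
        particles = [protein_atom(i + 1, "A", 157, "TYR", a)
                     for i, a in enumerate(("N", "CA", "C", "NX"))]
        return make_traj(particles, np.asarray(pts, dtype=float)[None] + 50.0)

    def test_planar_cis_is_zero(self):
        traj = self._quad_traj([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        s = geometry.dihedral_series(
            traj, *(Selection(atom_name=a) for a in ("N", "CA", "C", "NX"))
        )
        assert s.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        traj = self._quad_traj([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        s = geometry.dihedral_series(
            traj, *(Selection(atom_name=a) for a in ("N", "CA", "C", "NX"))
        )
        assert abs(s.values[0]) == pytest.approx(180.0, abs=1e-9)

    def test_random_quadruples_match_vector_algebra_oracle(self, rng):
        for _ in range(100):
            pts = rng.normal(0.0, 2.0, (4, 3))
            traj = self._quad_traj(pts)
            got = geometry.dihedral_series(
                traj, *(Selection(atom_name=a) for a in ("N", "CA", "C", "NX"))
            ).values[0]
            # independent oracle: angle between plane normals, signed by the
            # triple product with the central bond
            b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if np.dot(np.cross(n1, n2), b2) < 0:
                ang = -ang
            assert got == pytest.approx(ang, abs=1e-6)


class TestCtdRotation:
    TMD = Selection(role=Role.PROTEIN, residue_number=range(95, 100))
    CTD = Selection(role=Role.PROTEIN, residue_number=range(230, 235))
    TMD_A = Selection(role=Role.PROTEIN, subunit="A", residue_number=range(95, 100))
    CTD_A = Selection(role=Role.PROTEIN, subunit="A", residue_number=range(230, 235))

    def _series(self, traj):
        return geometry.ctd_rotation(traj, self.TMD, self.CTD, self.TMD_A, self.CTD_A)

    def test_reference_frame_reads_zero(self):
        traj, _ = script_scenario("rotated_ctd", angle=-3.0)
        assert self._series(traj).values[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [-4.0, -5.6, 2.5])
    def test_constructed_rotation_recovered(self, angle):
        traj, _ = script_scenario("rotated_ctd", angle=angle)
        assert self._series(traj).values[-1] == pytest.approx(angle, abs=0.01)

    def test_rotations_compose_additively(self):
        t1, _ = script_scenario("rotated_ctd", angle=-2.0)
        t2, _ = script_scenario("rotated_ctd", angle=-3.0)
        combined = self._series(t1).values[-1] + self._series(t2).values[-1]
        t3, _ = script_scenario("rotated_ctd", angle=-5.0)
        assert self._series(t3).values[-1] == pytest.approx(combined, abs=0.05)


class TestCationPi:
    def _ring_traj(self, ion_offset):
        ring = []
        for k, a in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            ang = np.radians(60.0 * k)
            ring.append(protein_atom(k + 1, "A", 192, "PHE", a))
        pts = [
            [1.39 * np.cos(np.radians(60 * k)), 1.39 * np.sin(np.radians(60 * k)), 0.0]
            for k in range(6)
        ]
        particles = ring + [ion(10)]
        coords = np.array(pts + [ion_offset])[None] + 50.0
        return make_traj(particles, coords)

    def test_ion_on_ring_axis(self):
        traj = self._ring_traj([0.0, 0.0, 3.0])
        dist, angle = geometry.cation_pi_geometry(traj, Selection(residue_name="PHE"), 10)
        assert dist.values[0] == pytest.approx(3.0, abs=1e-9)
        assert angle.values[0] == pytest.approx(0.0, abs=1e-6)

    def test_ion_in_ring_plane(self):
        traj = self._ring_traj([4.0, 0.0, 0.0])
        _, angle = geometry.cation_pi_geometry(traj, Selection(residue_name="PHE"), 10)
        assert angle.values[0] == pytest.approx(90.0, abs=1e-6)

    def test_tilted_planar_ring_matches_constructed_normal(self, rng):
        from scipy.spatial.transform import Rotation
        for _ in range(25):
            R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            pts = np.array(
                [[1.39 * np.cos(np.radians(60 * k)), 1.39 * np.sin(np.radians(60 * k)), 0.0]
                 for k in range(6)]
            ) @ R.as_matrix().T
            normal = R.as_matrix() @ np.array([0.0, 0.0, 1.0])
            off = rng.normal(0.0, 3.0, 3)
            particles = [protein_atom(k + 1, "A", 192, "PHE", "CG") for k in range(6)]
            particles += [ion(10)]
            coords = np.vstack([pts, off])[None] + 50.0
            traj = make_traj(particles, coords)
            dist, angle = geometry.cation_pi_geometry(traj, Selection(residue_name="PHE"), 10)
            v = off - pts.mean(axis=0)
            expected = np.degrees(
                np.arccos(abs(np.dot(normal, v)) / np.linalg.norm(v))
            )
            assert angle.values[0] == pytest.approx(expected, abs=1e-6)
            assert dist.values[0] == pytest.approx(np.linalg.norm(v), abs=1e-9)
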
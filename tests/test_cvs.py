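import numpy as np
import pytest

from conftest import random_rotation
from rnpmd import cvs
from rnpmd.cvs import ContactList
from rnpmd.io import AtomRecord, Frame, Selection


def anchors(n):
    return Selection(list(range(n)))


class TestDRIDFeatures:
    def test_equilateral_triangle_symmetry(self):
        side = 0.5
        pts = np.array(
            [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]]
        )
        feats = cvs.drid_features(Frame(pts), anchors(3)).matrix
        np.testing.assert_allclose(feats[0], 2.0, atol=1e-12)  # mu = 1/0.5
        np.testing.assert_allclose(feats[1], 0.0, atol=1e-12)  # nu
        np.testing.assert_allclose(feats[2], 0.0, atol=1e-12)  # xi

    def test_matches_brute_force_moments(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        feats = cvs.drid_features(Frame(pts), anchors(6)).matrix
        for i in range(6):
            inv = [
                1.0 / np.linalg.norm(pts[i] - pts[j]) for j in range(6) if j != i
            ]
            inv = np.array(inv)
            mu = inv.mean()
            m2 = np.mean((inv - mu) ** 2)
            m3 = np.mean((inv - mu) ** 3)
            assert feats[0, i] == pytest.approx(mu, abs=1e-12)
            assert feats[1, i] == pytest.approx(np.sqrt(m2), abs=1e-12)
            assert feats[2, i] == pytest.approx(np.cbrt(m3), abs=1e-12)

    def test_signed_cube_root_preserves_skew(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        feats = cvs.drid_features(Frame(pts), anchors(8)).matrix
        assert np.any(feats[2] < 0) or np.any(feats[2] > 0)

    def test_coincident_anchors_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            cvs.drid_features(Frame(pts), anchors(3))


class TestDRIDDistance:
    def test_identity_zero(self):
        rng = np.random.default_rng(2)
        f = Frame(rng.normal(size=(6, 3)))
        assert cvs.drid_distance(f, f, anchors(6)) == 0.0

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        R = random_rotation(rng)
        moved = Frame(pts @ R.T + rng.normal(size=3))
        assert cvs.drid_distance(moved, Frame(pts), anchors(6)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.1, size=(6, 3))
        va = cvs.drid_features(Frame(a), anchors(6)).matrix
        vb = cvs.drid_features(Frame(b), anchors(6)).matrix
        expected = np.sum(np.linalg.norm(vb - va, axis=0)) / (3 * 6)
        assert cvs.drid_distance(Frame(b), Frame(a), anchors(6)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            f = [Frame(rng.normal(size=(6, 3))) for _ in range(3)]
            dab = cvs.drid_distance(f[0], f[1], anchors(6))
            dbc = cvs.drid_distance(f[1], f[2], anchors(6))
            dac = cvs.drid_distance(f[0], f[2], anchors(6))
            assert dac <= dab + dbc + 1e-12


def lattice_system():
    """Two small chains on a lattice for contact-definition tests."""
    topology = []
    coords = []
    idx = 0
    for resi, x in enumerate([0.0, 0.3, 0.6], start=1):
        for name, el, off in [("CA", "C", 0.0), ("CB", "C", 0.1), ("HB", "H", 0.15)]:
            topology.append(AtomRecord(idx, name, el, resi, "ALA", "A"))
            coords.append([x + off, 0.0, 0.0])
            idx += 1
    for resi, x in enumerate([0.0, 0.3], start=28):
        for name, el, off in [("P", "P", 0.0), ("C1'", "C", 0.1)]:
            topology.append(AtomRecord(idx, name, el, resi, "U", "R"))
            coords.append([x + off, 0.35, 0.0])
            idx += 1
    return topology, Frame(np.array(coords))


class TestNativeContacts:
    def test_single_pair(self):
        topology = [
            AtomRecord(0, "CA", "C", 1, "ALA", "A"),
            AtomRecord(1, "P", "P", 28, "U", "R"),
        ]
        f = Frame(np.array([[0.0, 0, 0], [0.3, 0, 0]]))
        cl = cvs.native_contacts(
            topology, f, Selection([1]), Selection([0])
        )
        assert len(cl) == 1
        assert cl.r0[0] == pytest.approx(0.3)

    def test_all_far_gives_empty_flag(self):
        topology = [
            AtomRecord(0, "CA", "C", 1, "ALA", "A"),
            AtomRecord(1, "P", "P", 28, "U", "R"),
        ]
        f = Frame(np.array([[0.0, 0, 0], [0.5, 0, 0]]))
        cl = cvs.native_contacts(topology, f, Selection([1]), Selection([0]))
        assert len(cl) == 0 and cl.empty_flag

    def test_matches_exhaustive_scan_and_skips_hydrogens(self):
        topology, frame = lattice_system()
        rna = Selection([i for i, r in enumerate(topology) if r.chain_id == "R"])
        prot = Selection([i for i, r in enumerate(topology) if r.chain_id == "A"])
        cl = cvs.native_contacts(topology, frame, rna, prot, r_define=0.45)
        expected = set()
        for i in rna.atom_indices:
            for j in prot.atom_indices:
                if topology[i].element == "H" or topology[j].element == "H":
                    continue
                d = np.linalg.norm(frame.coordinates[i] - frame.coordinates[j])
                if d < 0.45:
                    expected.add((i, j))
        assert {tuple(p) for p in cl.pairs} == expected
        assert len(expected) > 0


class TestQFraction:
    def make_contacts(self, r0, beta=50.0, lam=1.8):
        pairs = [(i, i + len(r0)) for i in range(len(r0))]
        return ContactList(pairs=np.array(pairs), r0=np.array(r0), beta=beta, lam=lam)

    def frame_at(self, distances):
        n = len(distances)
        coords = np.zeros((2 * n, 3))
        for i, d in enumerate(distances):
            coords[i] = [0.0, i * 10.0, 0.0]
            coords[i + n] = [d, i * 10.0, 0.0]
        return Frame(coords)

    def test_reference_frame_near_one(self):
        r0 = [0.30, 0.35, 0.40]
        cl = self.make_contacts(r0)
        assert cvs.q_fraction(self.frame_at(r0), cl) >= 0.99

    def test_distant_frame_near_zero(self):
        cl = self.make_contacts([0.3, 0.4])
        assert cvs.q_fraction(self.frame_at([50.0, 50.0]), cl) < 1e-6

    def test_logistic_midpoint(self):
        r0 = [0.30]
        cl = self.make_contacts(r0)
        assert cvs.q_fraction(self.frame_at([1.8 * 0.30]), cl) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_matches_brute_force_eq(self):
        rng = np.random.default_rng(6)
        r0 = rng.uniform(0.25, 0.45, 20)
        cl = self.make_contacts(list(r0))
        d = r0 * rng.uniform(0.8, 2.5, 20)
        frame = self.frame_at(list(d))
        expected = np.mean(1.0 / (1.0 + np.exp(50.0 * (d - 1.8 * r0))))
        assert cvs.q_fraction(frame, cl) == pytest.approx(expected, abs=1e-12)

    def test_monotone_under_uniform_inflation(self):
        rng = np.random.default_rng(7)
        r0 = rng.uniform(0.25, 0.45, 10)
        cl = self.make_contacts(list(r0))
        q_vals = [
            cvs.q_fraction(self.frame_at(list(r0 * s)), cl)
            for s in (1.0, 1.3, 1.8, 2.5)
        ]
        assert all(a >= b for a, b in zip(q_vals, q_vals[1:]))

    def test_rigid_invariance(self):
        rng = np.random.default_rng(8)
        r0 = [0.3, 0.35]
        cl = self.make_contacts(r0)
        f = self.frame_at([0.45, 0.5])
        R = random_rotation(rng)
        moved = Frame(f.coordinates @ R.T + rng.normal(size=3))
        assert cvs.q_fraction(moved, cl) == pytest.approx(
            cvs.q_fraction(f, cl), abs=1e-12
        )


class TestKDE:
    def test_grid_integral_one(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(300, 2))
        out = cvs.kde_density(pts, grid_size=80)
        assert out["integral"] == pytest.approx(1.0, abs=1e-3)

    def test_unimodal_peak_at_cluster_mean(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(loc=[2.0, -1.0], scale=0.05, size=(500, 2))
        out = cvs.kde_density(pts, grid_size=100)
        i, j = np.unravel_index(np.argmax(out["density"]), out["density"].shape)
        assert out["x"][i] == pytest.approx(2.0, abs=0.05)
        assert out["y"][j] == pytest.approx(-1.0, abs=0.05)

    def test_two_planted_clusters_give_two_maxima(self):
        rng = np.random.default_rng(11)
        a = rng.normal(loc=[0.0, 0.0], scale=0.05, size=(400, 2))
        b = rng.normal(loc=[1.0, 1.0], scale=0.05, size=(400, 2))
        out = cvs.kde_density(np.vstack([a, b]), grid_size=120)
        dens = out["density"]
        cell_x = out["x"][1] - out["x"][0]
        # local maxima
        interior = dens[1:-1, 1:-1]
        maxima = (
            (interior > dens[:-2, 1:-1])
            & (interior > dens[2:, 1:-1])
            & (interior > dens[1:-1, :-2])
            & (interior > dens[1:-1, 2:])
        )
        peaks = np.argwhere(maxima) + 1
        peak_xy = [(out["x"][i], out["y"][j]) for i, j in peaks]
        assert any(abs(x) < 2 * cell_x and abs(y) < 2 * cell_x for x, y in peak_xy)
        assert any(
            abs(x - 1) < 2 * cell_x and abs(y - 1) < 2 * cell_x for x, y in peak_xy
        )

    def test_degenerate_dimension_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50)])
        with pytest.raises(ValueError, match="jitter"):
            cvs.kde_density(pts)
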
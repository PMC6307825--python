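import numpy as np
import pytest

from rnpmd import noe, synthetic as syn
from rnpmd.io import AtomRecord, Ensemble, Frame
from rnpmd.noe import NOERestraint


def pair_ensemble(distances):
    """One atom pair, one frame per requested distance."""
    topology = [
        AtomRecord(0, "H1", "H", 1, "ALA", "A"),
        AtomRecord(1, "H2", "H", 2, "U", "R"),
    ]
    frames = [
        Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), i)
        for i, d in enumerate(distances)
    ]
    return Ensemble(topology=topology, frames=frames)


def restraint(bound=1.0, category="intermolecular"):
    return NOERestraint(
        group1=(("A", 1, "H1"),), group2=(("R", 2, "H2"),), r_noe=bound,
        category=category,
    )


class TestBackcalc:
    def test_single_frame_identity(self):
        ens = pair_ensemble([0.30])
        assert noe.backcalc_noe(ens, restraint()) == pytest.approx(0.30, abs=1e-12)

    def test_two_frame_r6_average(self):
        ens = pair_ensemble([0.2, 0.4])
        expected = ((0.2**-6 + 0.4**-6) / 2) ** (-1 / 6)
        got = noe.backcalc_noe(ens, restraint())
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.224, abs=5e-4)

    def test_constant_distance_invariance(self):
        for n in (1, 3, 10):
            ens = pair_ensemble([0.27] * n)
            assert noe.backcalc_noe(ens, restraint()) == pytest.approx(0.27, abs=1e-12)

    def test_matches_brute_force_on_random_fixtures(self, planted_complex):
        ens, _ = planted_complex
        rng = np.random.default_rng(0)
        coords = ens.coordinate_array()
        for _ in range(100):
            i, j = rng.choice(ens.n_atoms, size=2, replace=False)
            a1, a2 = ens.topology[int(i)], ens.topology[int(j)]
            r = NOERestraint(
                group1=((a1.chain_id, a1.residue_index, a1.atom_name),),
                group2=((a2.chain_id, a2.residue_index, a2.atom_name),),
                r_noe=0.5,
            )
            d = np.linalg.norm(coords[:, int(i)] - coords[:, int(j)], axis=1)
            expected = np.mean(d**-6.0) ** (-1 / 6)
            assert noe.backcalc_noe(ens, r) == pytest.approx(expected, abs=1e-12)

    def test_group_effective_distance(self):
        # two protons in group1: per-frame r_eff = (r1^-6 + r2^-6)^(-1/6)
        topology = [
            AtomRecord(0, "HB1", "H", 1, "ALA", "A"),
            AtomRecord(1, "HB2", "H", 1, "ALA", "A"),
            AtomRecord(2, "H2", "H", 2, "U", "R"),
        ]
        coords = np.array([[0, 0, 0], [0, 0.1, 0], [0.3, 0, 0.0]], dtype=float)
        ens = Ensemble(topology=topology, frames=[Frame(coords)])
        r = NOERestraint(
            group1=(("A", 1, "HB1"), ("A", 1, "HB2")),
            group2=(("R", 2, "H2"),),
            r_noe=0.5,
        )
        r1 = np.linalg.norm(coords[0] - coords[2])
        r2 = np.linalg.norm(coords[1] - coords[2])
        expected = (r1**-6 + r2**-6) ** (-1 / 6)
        assert noe.backcalc_noe(ens, r) == pytest.approx(expected, abs=1e-12)
        # the "min" convention is available behind a flag
        assert noe.backcalc_noe(ens, r, group_mode="min") == pytest.approx(
            min(r1, r2), abs=1e-12
        )

    def test_generalized_mean_bounds(self):
        ens = pair_ensemble([0.2, 0.3, 0.5])
        r_avg = noe.backcalc_noe(ens, restraint())
        assert 0.2 <= r_avg <= 0.5

    def test_duplicated_frame_leaves_average_unchanged(self):
        base = pair_ensemble([0.2, 0.4])
        dup = pair_ensemble([0.2, 0.4, 0.2, 0.4])
        assert noe.backcalc_noe(dup, restraint()) == pytest.approx(
            noe.backcalc_noe(base, restraint()), abs=1e-12
        )

    def test_unresolvable_atom_raises(self):
        ens = pair_ensemble([0.3])
        bad = NOERestraint(group1=(("A", 1, "HX"),), group2=(("R", 2, "H2"),), r_noe=0.5)
        with pytest.raises(KeyError):
            noe.backcalc_noe(ens, bad)


class TestViolationReport:
    def test_planted_fixture_fractions(self, planted_complex):
        ens, _ = planted_complex
        restraints, truth = syn.make_noe_fixture(ens, 8, 2, margin=0.05, seed=0)
        rep = noe.violation_report(ens, restraints)
        assert rep.satisfied_fraction["all"] == pytest.approx(0.80)
        got = rep.table["violated"].tolist()
        assert got == truth.planted_noe_violations

    def test_no_violations_zero_average(self):
        ens = pair_ensemble([0.2, 0.4])
        r_avg = noe.backcalc_noe(ens, restraint())
        rep = noe.violation_report(ens, [restraint(bound=r_avg + 0.01)])
        assert rep.mean_violation_over_violated == 0.0
        assert rep.mean_violation_over_all == 0.0
        assert rep.n_violations_gt_005 == 0

    def test_threshold_counts(self):
        ens = pair_ensemble([0.3])
        # violations of exactly 0.06 and 0.02 nm
        rep = noe.violation_report(
            ens, [restraint(bound=0.24), restraint(bound=0.28)]
        )
        assert rep.n_violations_gt_005 == 1
        assert rep.n_violations_gt_03 == 0

    def test_pooled_frames_not_mean_of_reports(self):
        a = pair_ensemble([0.2, 0.2])
        b = pair_ensemble([0.5, 0.5])
        pooled = pair_ensemble([0.2, 0.2, 0.5, 0.5])
        r = restraint()
        rep = noe.violation_report(pooled, [r])
        expected = np.mean(np.array([0.2, 0.2, 0.5, 0.5]) ** -6.0) ** (-1 / 6)
        assert rep.table["r_avg_nm"].iloc[0] == pytest.approx(expected, abs=1e-12)
        mean_of_two = 0.5 * (noe.backcalc_noe(a, r) + noe.backcalc_noe(b, r))
        assert rep.table["r_avg_nm"].iloc[0] != pytest.approx(mean_of_two, abs=1e-6)

    def test_per_category_fractions(self, planted_complex):
        ens, _ = planted_complex
        restraints, _ = syn.make_noe_fixture(ens, 6, 4, margin=0.05, seed=2)
        rep = noe.violation_report(ens, restraints)
        for cat, frac in rep.satisfied_fraction.items():
            assert 0.0 <= frac <= 1.0


class TestPerFrameCount:
    def test_counts_match_construction(self, planted_complex):
        ens, _ = planted_complex
        restraints, truth = syn.make_noe_fixture(ens, 5, 0, margin=0.05, seed=3)
        # per-frame distances vary; count against single-frame bounds instead
        frame = ens.frames[0]
        count = noe.per_frame_violation_count(ens.topology, frame, restraints)
        assert 0 <= count <= len(restraints)

    def test_monotone_under_bound_shrinking(self, planted_complex):
        ens, _ = planted_complex
        rng = np.random.default_rng(1)
        restraints, _ = syn.make_noe_fixture(ens, 4, 4, margin=0.05, seed=4)
        for frame in ens.frames[:10]:
            base = noe.per_frame_violation_count(ens.topology, frame, restraints)
            shrunk = [
                NOERestraint(r.group1, r.group2, r.r_noe * 0.8, r.category)
                for r in restraints
            ]
            tighter = noe.per_frame_violation_count(ens.topology, frame, shrunk)
            assert tighter >= base


from conftest import two_conformer_noe_fixture


class TestMDAdaptedEnsemble:
    def test_retains_exactly_the_planted_best_frames(self):
        ens, restraints, _, _ = two_conformer_noe_fixture()
        res = noe.select_md_adapted_ensemble(ens, restraints, 0.10, k=2, seed=0)
        assert res.retained_frame_indices == list(range(10))

    def test_centroids_near_planted_conformers(self):
        from rnpmd.geometry import kabsch_superpose
        from rnpmd.io import Selection

        ens, restraints, truth, noise = two_conformer_noe_fixture()
        res = noe.select_md_adapted_ensemble(ens, restraints, 0.10, k=2, seed=0)
        sel = Selection(list(range(ens.n_atoms)))
        confs = truth.cluster_conformers
        for cf in res.ensemble.frames:
            best = min(
                kabsch_superpose(cf, Frame(confs[c]), sel).rmsd for c in range(2)
            )
            assert best <= 2 * noise * np.sqrt(3)

    def test_k_equals_retained_count(self):
        ens, restraints, _, _ = two_conformer_noe_fixture()
        res = noe.select_md_adapted_ensemble(ens, restraints, 0.10, k=10, seed=0)
        assert sorted(res.centroid_frame_indices) == list(range(10))

    def test_k_too_large_rejected(self):
        ens, restraints, _, _ = two_conformer_noe_fixture()
        with pytest.raises(ValueError):
            noe.select_md_adapted_ensemble(ens, restraints, 0.10, k=11)

    def test_populations_ordered_descending(self):
        ens, restraints, _, _ = two_conformer_noe_fixture()
        res = noe.select_md_adapted_ensemble(ens, restraints, 0.10, k=2, seed=0)
        assert res.cluster_populations == sorted(res.cluster_populations, reverse=True)
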
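"""Contact detection vs a brute-force oracle, profiles, segments, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_contacts, mini_model, random_contact_model
from ppiface.contacts import (
    ComplexScore,
    ContactPair,
    PPIfaceError,
    ResidueContactProfile,
    aggregate_profiles,
    compute_contacts,
    detect_segments,
    rank_complexes,
    residue_profile,
    score_complex,
)


class TestComputeContacts:
    def test_displaced_ligand_gives_no_contacts(self):
        model = mini_model([("A", 1, (0, 0, 0))], [(1, (100.0, 0, 0))])
        assert compute_contacts(model) == []

    def test_tiny_cutoff_gives_no_contacts(self):
        model = mini_model([("A", 1, (0, 0, 0))], [(1, (1.0, 0, 0))])
        assert compute_contacts(model, cutoff=0.1) == []

    def test_peptide_near_specific_residues(self):
        """A ligand 3.5 A from residues 10-14 of chain A reports exactly those."""
        receptor = [("A", r, (0.0, 4.0 * r, 0.0)) for r in range(5, 20)]
        ligand = [(i, (3.5, 4.0 * r, 0.0)) for i, r in enumerate(range(10, 15), start=1)]
        model = mini_model(receptor, ligand)
        pairs = compute_contacts(model, cutoff=5.0)
        assert sorted({p.receptor_residue for p in pairs}) == [10, 11, 12, 13, 14]
        assert all(p.min_distance == pytest.approx(3.5) for p in pairs if p.ligand_unit == p.receptor_residue - 9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            model = random_contact_model(rng)
            oracle = brute_force_contacts(model, cutoff=5.0)
            got = {
                (p.receptor_chain, p.receptor_residue, p.ligand_unit): p.min_distance
                for p in compute_contacts(model, cutoff=5.0)
            }
            assert set(got) == set(oracle)
            for key in oracle:
                assert got[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_atom_order_invariance(self, scaffold):
        from ppiface.synthetic_fixtures import plant_peptide_pose
        from ppiface.core_model import ComplexModel

        model = plant_peptide_pose(scaffold, "good", seed=2)
        shuffled = ComplexModel(
            model_id=model.model_id,
            receptor_chains=model.receptor_chains,
            receptor_atoms=list(reversed(model.receptor_atoms)),
            ligand_atoms=list(reversed(model.ligand_atoms)),
            ligand_chain=model.ligand_chain,
        )
        assert compute_contacts(model) == compute_contacts(shuffled)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(1.0, 8.0), st.floats(0.5, 4.0))
    def test_cutoff_monotonicity(self, seed, big, delta):
        """Enlarging the cutoff never removes a contact pair."""
        model = random_contact_model(np.random.default_rng(seed))
        small = max(big - delta, 0.1)
        keys_small = {(p.receptor_key, p.ligand_unit) for p in compute_contacts(model, small)}
        keys_big = {(p.receptor_key, p.ligand_unit) for p in compute_contacts(model, big)}
        assert keys_small <= keys_big

    def test_atom_grouping_reports_serials(self):
        model = mini_model([("A", 1, (0, 0, 0))], [(7, (2.0, 0, 0)), (7, (3.0, 0, 0))], ligand_chain=None)
        residue_level = compute_contacts(model, ligand_grouping="residue")
        atom_level = compute_contacts(model, ligand_grouping="atom")
        assert len(residue_level) == 1 and residue_level[0].min_distance == pytest.approx(2.0)
        assert len(atom_level) == 2


class TestResidueProfile:
    def test_pair_count_vs_binary(self):
        pairs = [ContactPair("A", 10, u, 3.0) for u in (5, 6, 7)]
        keys = [("A", 10), ("A", 11)]
        assert residue_profile(pairs, keys).counts[("A", 10)] == 3
        assert residue_profile(pairs, keys, mode="binary").counts[("A", 10)] == 1
        assert residue_profile(pairs, keys).counts[("A", 11)] == 0

    def test_empty_contacts_all_zero(self):
        prof = residue_profile([], [("A", 1), ("B", 2)])
        assert set(prof.counts.values()) == {0}

    def test_recount_matches_contact_list(self, ensemble):
        """Profile counts equal an independent recount of distinct ligand units."""
        _, models, _ = ensemble
        model = models[0]
        pairs = compute_contacts(model)
        prof = residue_profile(pairs, model.receptor_residues())
        recount: dict = {}
        for p in pairs:
            recount.setdefault(p.receptor_key, set()).add(p.ligand_unit)
        for key, units in recount.items():
            assert prof.counts[key] == len(units)
        assert sum(prof.counts.values()) == sum(len(u) for u in recount.values())


class TestAggregate:
    def test_sum_of_identical_one_hots(self):
        one = ResidueContactProfile({("A", 5): 1, ("A", 6): 0})
        agg = aggregate_profiles([one] * 15)
        assert agg.counts[("A", 5)] == 15 and agg.n_models == 15

    def test_order_invariance(self):
        a = ResidueContactProfile({("A", 1): 2, ("A", 2): 0})
        b = ResidueContactProfile({("A", 1): 1, ("A", 2): 5})
        assert aggregate_profiles([a, b]).counts == aggregate_profiles([b, a]).counts

    def test_mismatched_keys_error(self):
        a = ResidueContactProfile({("A", 1): 0})
        b = ResidueContactProfile({("A", 2): 0})
        with pytest.raises(PPIfaceError):
            aggregate_profiles([a, b])


class TestDetectSegments:
    def _profile(self, counts):
        return ResidueContactProfile({("A", i + 1): c for i, c in enumerate(counts)})

    def test_single_peak_called(self):
        segs = detect_segments(self._profile([0, 0, 5, 6, 7, 0, 0, 1, 0]))
        assert [(s.start, s.end, s.peak_count) for s in segs] == [(3, 5, 7)]

    def test_gap_wider_than_tolerance_splits(self):
        segs = detect_segments(self._profile([5, 5, 5, 0, 0, 0, 5, 5, 5]), gap_tolerance=2)
        assert [(s.start, s.end) for s in segs] == [(1, 3), (7, 9)]

    def test_gap_within_tolerance_merges(self):
        segs = detect_segments(self._profile([5, 5, 5, 0, 0, 5, 5, 5]), gap_tolerance=2)
        assert [(s.start, s.end) for s in segs] == [(1, 8)]

    def test_all_zero_profile_empty(self):
        assert detect_segments(self._profile([0] * 9)) == []

    def test_min_length_drops_short_runs(self):
        segs = detect_segments(self._profile([9, 9, 0, 0, 0, 9, 0, 0, 0]), min_length=2)
        assert [(s.start, s.end) for s in segs] == [(1, 2)]

    def test_absolute_floor_suppresses_single_contacts(self):
        # max=4 -> relative threshold 1, but the floor of 2 masks count-1 noise
        segs = detect_segments(self._profile([1, 1, 4, 4, 4, 1, 1, 0, 0]))
        assert [(s.start, s.end) for s in segs] == [(3, 5)]


class TestScoring:
    def test_score_formula(self):
        """10 distinct residues and 14 pairs score 10 + 0.1 x 14 = 11.4."""
        pairs = [ContactPair("A", r, 1, 3.0) for r in range(1, 11)]
        pairs += [ContactPair("A", r, 2, 3.5) for r in range(1, 5)]
        model = mini_model([("A", 1, (0, 0, 0))], [(1, (1, 0, 0))])
        score = score_complex(model, pairs)
        assert score.n_interface_residues == 10
        assert score.total_contacts == 14
        assert score.score == pytest.approx(11.4)

    def test_rank_truncates_and_breaks_ties_lexicographically(self):
        scores = [
            ComplexScore("m2", 5, 5, 5.5),
            ComplexScore("m1", 5, 5, 5.5),
            ComplexScore("m3", 9, 9, 9.9),
        ]
        top = rank_complexes(scores, k=10)
        assert [s.model_id for s in top] == ["m3", "m1", "m2"]
        assert [s.model_id for s in rank_complexes(scores, k=1)] == ["m3"]
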
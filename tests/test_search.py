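import numpy as np
import pytest

from conftest import all_lmers, random_seqs
from lddms import (
    DNA,
    LDDMSParams,
    SequenceSet,
    brute_force_search,
    delta,
    delta_child_update,
    generate_instance,
    lddms1,
    lddms2,
    lddms3,
    ldms_solve,
    min_distance,
    neighborhood,
    prune_decision,
    root_node,
    satisfies_d1_condition,
)
from lddms.search import PruneVerdict


class TestLdmsSolve:
    def test_matches_pattern_enumeration(self, toy_seqs):
        expected = [
            x for x in all_lmers(3) if satisfies_d1_condition(x, toy_seqs, 1)
        ]
        assert list(ldms_solve(toy_seqs, 3, 1)) == expected

    def test_radius_zero_is_common_exact_substrings(self):
        seqs = SequenceSet.from_strings(["ACGTT", "TACGT"])
        assert set(ldms_solve(seqs, 3, 0)) == {"ACG", "CGT"}

    def test_single_sequence_is_window_neighborhood_union(self):
        seqs = SequenceSet.from_strings(["ACGT"])
        expected = neighborhood("ACG", 1, DNA).as_set() | neighborhood(
            "CGT", 1, DNA
        ).as_set()
        assert ldms_solve(seqs, 3, 1).as_set() == expected


class TestLddms1:
    def test_toy_equals_brute_force(self, toy_seqs):
        assert list(lddms1(toy_seqs, LDDMSParams(3, 1, 0))) == ["AAA", "AAT", "ATT"]

    def test_relaxed_filter_is_vacuous(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 3, 20)
        p = LDDMSParams(4, 2, 2, relaxed=True)
        assert lddms1(seqs, p) == ldms_solve(seqs, 4, 2)

    def test_far_apart_sequences_give_empty_output(self):
        # no window pair across sequences within 2*d1: no common neighbor
        seqs = SequenceSet.from_strings(["AAAAAA", "TTTTTT"])
        assert len(lddms1(seqs, LDDMSParams(5, 1, 0))) == 0

    def test_counters_report_candidate_size(self, toy_seqs):
        counters = {}
        lddms1(toy_seqs, LDDMSParams(3, 1, 0), counters=counters)
        assert counters["c1"] == len(ldms_solve(toy_seqs, 3, 1))


class TestLddms2:
    def test_toy_equals_brute_force(self, toy_seqs):
        assert list(lddms2(toy_seqs, LDDMSParams(3, 1, 0))) == ["AAA", "AAT", "ATT"]

    def test_d2_zero_candidates_are_distinct_windows(self, toy_seqs):
        counters = {}
        lddms2(toy_seqs, LDDMSParams(3, 1, 0), counters=counters)
        assert counters["c2"] == 3  # AAA, AAT, ATT

    def test_candidate_guard(self, toy_seqs):
        with pytest.raises(ValueError, match="guard"):
            lddms2(toy_seqs, LDDMSParams(3, 2, 1), max_candidates=5)


class TestDelta:
    def test_exact_occurrence_everywhere_else_gives_zero(self):
        seqs = SequenceSet.from_strings(["GGGG", "TACG", "ACGT"])
        assert delta("ACG", 0, seqs) == 0

    def test_worst_sequence_dominates(self):
        seqs = SequenceSet.from_strings(["AAAA", "CCCC"])
        assert delta("AA", 0, seqs) == 2

    def test_single_sequence_is_undefined(self):
        with pytest.raises(ValueError):
            delta("AA", 0, SequenceSet.from_strings(["AAAA"]))

    def test_matches_min_distance_composition(self):
        rng = np.random.default_rng(23)
        seqs = random_seqs(rng, 4, 12)
        x = "ACGT"
        expected = max(
            min_distance(x, s) for q, s in enumerate(seqs.residues) if q != 1
        )
        assert delta(x, 1, seqs) == expected


class TestDeltaChildUpdate:
    def test_incremental_equals_from_scratch_on_random_cases(self):
        rng = np.random.default_rng(77)
        chars = "ACGT"
        for _ in range(250):
            n, m, l = int(rng.integers(2, 5)), int(rng.integers(8, 16)), int(rng.integers(3, 7))
            seqs = random_seqs(rng, n, m)
            i = int(rng.integers(n))
            start = int(rng.integers(m - l + 1))
            u = seqs[i][start : start + l]
            node = root_node(u, i, seqs)
            assert node.delta == delta(u, i, seqs)
            # walk a random root-to-leaf path, re-deriving state from scratch
            depth = int(rng.integers(1, min(3, l) + 1))
            positions = sorted(rng.choice(l, size=depth, replace=False))
            for p in positions:
                alternatives = [c for c in chars if c != u[p]]
                c = alternatives[int(rng.integers(len(alternatives)))]
                node = delta_child_update(node, int(p), c, seqs)
                assert node.delta == delta(node.x, i, seqs)
                for q in range(n):
                    expected = [
                        sum(a != b for a, b in zip(node.x, seqs[q][s : s + l]))
                        for s in range(m - l + 1)
                    ]
                    assert node.distances_to(q).tolist() == expected

    def test_child_level_equals_distance_to_root(self):
        seqs = SequenceSet.from_strings(["ACGTACG", "TTGCATG"])
        node = root_node("ACGT", 0, seqs)
        child = delta_child_update(node, 1, "G", seqs)
        grandchild = delta_child_update(child, 3, "A", seqs)
        assert (child.h, grandchild.h) == (1, 2)
        assert grandchild.x == "AGGA"
        assert grandchild.mutated == (1, 3)

    def test_remutation_and_identity_char_rejected(self):
        seqs = SequenceSet.from_strings(["ACGTACG", "TTGCATG"])
        node = root_node("ACGT", 0, seqs)
        child = delta_child_update(node, 1, "G", seqs)
        with pytest.raises(ValueError):
            delta_child_update(child, 1, "T", seqs)
        with pytest.raises(ValueError):
            delta_child_update(node, 2, "G", seqs)


class TestPruneDecision:
    @pytest.mark.parametrize(
        "delta_val,h,l,d1,d2,expected",
        [
            (4, 0, 10, 4, 2, PruneVerdict.OUTPUT_AND_DESCEND),
            (0, 2, 10, 4, 2, PruneVerdict.OUTPUT_AND_DESCEND),
            (7, 0, 10, 4, 2, PruneVerdict.PRUNE),  # 7-4 > 2-0
            (6, 0, 10, 4, 2, PruneVerdict.DESCEND_DECREASING_ONLY),  # 6-4 = 2-0
            (5, 0, 10, 4, 2, PruneVerdict.DESCEND_NONINCREASING_ONLY),  # 5-4 = 2-0-1
            (6, 0, 10, 4, 3, PruneVerdict.DESCEND_NONINCREASING_ONLY),
            (5, 0, 10, 4, 3, PruneVerdict.DESCEND_ALL),
        ],
    )
    def test_rule_table(self, delta_val, h, l, d1, d2, expected):
        assert prune_decision(delta_val, h, LDDMSParams(l, d1, d2)) is expected


class TestLddms3:
    def test_toy_equals_brute_force(self, toy_seqs):
        assert list(lddms3(toy_seqs, LDDMSParams(3, 1, 0))) == ["AAA", "AAT", "ATT"]

    def test_cross_algorithm_equivalence_random(self):
        rng = np.random.default_rng(100)
        for _ in range(10):
            n, m = int(rng.integers(2, 6)), int(rng.integers(12, 30))
            l = int(rng.integers(3, 7))
            d1 = int(rng.integers(1, min(3, l) + 1))
            d2 = int(rng.integers(0, d1))
            seqs = random_seqs(rng, n, m)
            p = LDDMSParams(l, d1, d2)
            ref = brute_force_search(seqs, p)
            assert lddms1(seqs, p) == ref
            assert lddms2(seqs, p) == ref
            assert lddms3(seqs, p) == ref

    def test_relaxed_mode_refused(self):
        seqs = SequenceSet.from_strings(["ACGTA", "TACGT"])
        with pytest.raises(ValueError, match="d2 < d1"):
            lddms3(seqs, LDDMSParams(3, 1, 1, relaxed=True))

    def test_single_sequence_falls_back_to_lddms2_semantics(self):
        seqs = SequenceSet.from_strings(["ACGTACG"])
        p = LDDMSParams(3, 2, 1)
        assert lddms3(seqs, p) == lddms2(seqs, p)

    def test_generous_d1_returns_full_candidate_set(self):
        rng = np.random.default_rng(8)
        seqs = random_seqs(rng, 3, 12)
        p = LDDMSParams(4, 4, 1, relaxed=False)
        counters = {}
        full = lddms2(seqs, p, counters=counters)
        assert len(full) == counters["c2"]  # every candidate passes d1 <= l
        assert lddms3(seqs, p) == full

    def test_planted_common_neighbors_recovered(self):
        inst = generate_instance(n=6, m=30, l=5, q=2, seed=42)
        p = LDDMSParams(5, 2, 1)
        out = lddms3(inst.seqs, p)
        common = neighborhood(inst.m1, 1, DNA).as_set() & neighborhood(
            inst.m2, 1, DNA
        ).as_set()
        assert len(common) == 2  # C(2*d2, d2) with d2 = 1
        assert out.issuperset(common)
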
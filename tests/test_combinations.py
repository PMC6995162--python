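"""Sequential-augmentation scoring of multi-gene normalization factors."""

from math import comb

import numpy as np
import pytest

from mirnorm import (
    ExpressionTable,
    compare_to_components,
    compute_stability_suite,
    enumerate_combinations,
    final_score,
    global_mean_factor,
    make_combination_profile,
    records_to_frame,
    score_augmented_entry,
)
from mirnorm.combinations import CombinationRecord
from .conftest import random_grouped_table, random_table


class TestCombinationProfile:
    def test_pairwise_mean(self, rng):
        t = ExpressionTable(["A", "B"], ["s1", "s2"], np.array([[20.0, 24.0], [22.0, 30.0]]))
        np.testing.assert_allclose(make_combination_profile(t, ("A", "B")), [21.0, 27.0])

    def test_triple_mean(self):
        t = ExpressionTable(
            ["A", "B", "C"], ["s1", "s2"], np.array([[20.0, 26.0], [20.0, 25.0], [23.0, 24.0]])
        )
        np.testing.assert_allclose(make_combination_profile(t, ("A", "B", "C")), [21.0, 25.0])

    def test_identical_members_give_shared_profile(self, rng):
        t = random_table(rng, n_genes=3, n_samples=5)
        t.cq[1] = t.cq[0]
        profile = make_combination_profile(t, (t.gene_ids[0], t.gene_ids[1]))
        np.testing.assert_allclose(profile, t.cq[0])

    def test_unknown_member_rejected(self, rng):
        t = random_table(rng, n_genes=3, n_samples=4)
        with pytest.raises(KeyError, match="nope"):
            make_combination_profile(t, ("g00", "nope"))


class TestScoreAugmentedEntry:
    def test_duplicate_profile_ties_its_twin_under_every_algorithm(self, rng):
        t = random_table(rng, n_genes=6, n_samples=6)
        twin = t.gene_ids[2]
        aug = t.with_entry("copy", t.cq[2])
        for scores in compute_stability_suite(aug):
            assert scores.score_by_gene["copy"] == pytest.approx(
                scores.score_by_gene[twin], abs=1e-10
            )
        record = score_augmented_entry(t, t.cq[2], "copy", members=("copy",))
        assert 1 <= record.place <= t.n_genes + 1

    def test_perfectly_stable_entry_tops_bestkeeper_and_genorm(self, rng):
        # the table contains a constant gene; a constant entry has zero SD and
        # zero pairwise variation against it, so both rank components are minimal
        cq = 24.0 + rng.normal(0, 1.0, size=(5, 6))
        cq[0] = 30.0
        t = ExpressionTable([f"g{i}" for i in range(5)], [f"s{j}" for j in range(6)], cq)
        record = score_augmented_entry(t, np.full(6, 21.0), "flat", members=("flat",))
        # tied with the constant co-gene at the minimum -> mean tie rank of
        # places 1 and 2 among 6 entries: ((0) + (1/6)) / 2
        assert record.rank_by_algorithm["bestkeeper"] == pytest.approx(1 / 12)
        assert record.rank_by_algorithm["genorm"] == pytest.approx(1 / 12)

    def test_augmented_ranking_covers_n_plus_one_entries(self, rng):
        t = random_table(rng, n_genes=7, n_samples=6)
        profile = t.cq[:2].mean(axis=0)
        record = score_augmented_entry(t, profile, "pair", members=("g00", "g01"))
        assert 1 <= record.place <= 8
        assert 0 <= record.final_score < 1

    def test_profile_length_mismatch_rejected(self, rng):
        t = random_table(rng, n_genes=4, n_samples=6)
        with pytest.raises(ValueError, match="does not match"):
            score_augmented_entry(t, np.zeros(5), "bad", members=("bad",))

    def test_existing_entry_id_rejected(self, rng):
        t = random_table(rng, n_genes=4, n_samples=6)
        with pytest.raises(ValueError, match="already present"):
            score_augmented_entry(t, t.cq[0], "g00", members=("g00",))


class TestEnumeration:
    def test_pair_count_is_binomial(self, rng):
        t = random_table(rng, n_genes=6, n_samples=6)
        records = enumerate_combinations(t, k=2, dataset_id="d")
        assert len(records) == comb(6, 2)
        assert len({r.members for r in records}) == comb(6, 2)

    def test_k1_reduces_exactly_to_single_gene_ranking(self, rng):
        t = random_table(rng, n_genes=8, n_samples=6)
        singles = {r.entry_id: r for r in final_score(t)}
        for record in enumerate_combinations(t, k=1):
            ref = singles[record.members[0]]
            assert record.final_score == ref.final_score
            assert record.place == ref.place
            assert record.rank_by_algorithm == ref.rank_by_algorithm

    def test_base_table_is_never_mutated(self, rng):
        t = random_table(rng, n_genes=6, n_samples=6)
        before = t.cq.tobytes()
        ids_before = list(t.gene_ids)
        enumerate_combinations(t, k=2)
        enumerate_combinations(t, k=3)
        assert t.cq.tobytes() == before
        assert t.gene_ids == ids_before

    def test_pool_restriction_and_errors(self, rng):
        t = random_table(rng, n_genes=8, n_samples=6)
        pool = t.gene_ids[:4]
        records = enumerate_combinations(t, k=3, candidate_pool=pool)
        assert len(records) == comb(4, 3)
        with pytest.raises(ValueError, match="smaller than k"):
            enumerate_combinations(t, k=3, candidate_pool=t.gene_ids[:2])
        with pytest.raises(KeyError):
            enumerate_combinations(t, k=2, candidate_pool=["g00", "absent"])
        with pytest.raises(ValueError, match="at most 3"):
            enumerate_combinations(t, k=4)

    @pytest.mark.parametrize("grouped", [False, True])
    def test_fast_path_equals_naive_recomputation(self, rng, grouped):
        for _ in range(5):
            if grouped:
                t = random_grouped_table(rng, n_genes=8, group_sizes=(4, 4))
            else:
                t = random_table(rng, n_genes=8, n_samples=8)
            fast = enumerate_combinations(t, k=2, dataset_id="d", naive=False)
            slow = enumerate_combinations(t, k=2, dataset_id="d", naive=True)
            assert [r.members for r in fast] == [r.members for r in slow]
            for a, b in zip(fast, slow):
                assert a.final_score == pytest.approx(b.final_score, abs=1e-12)
                assert a.place == b.place
                for alg in a.rank_by_algorithm:
                    assert a.rank_by_algorithm[alg] == pytest.approx(
                        b.rank_by_algorithm[alg], abs=1e-12
                    )

    def test_member_order_is_canonical(self, rng):
        t = random_table(rng, n_genes=5, n_samples=6)
        a = score_augmented_entry(t, t.cq[[0, 2]].mean(axis=0), "x", members=("g02", "g00"))
        b = score_augmented_entry(t, t.cq[[0, 2]].mean(axis=0), "x", members=("g00", "g02"))
        assert a.members == b.members == ("g00", "g02")
        assert a.final_score == b.final_score


class TestGlobalMean:
    def test_identical_genes_tie_the_global_mean(self, rng):
        # quarter-cycle values keep the 3-gene mean bit-exact, so the
        # augmented table holds four identical entries -> a full tie
        profile = 23.0 + 0.25 * rng.integers(-8, 8, size=6)
        t = ExpressionTable(
            ["A", "B", "C"], [f"s{j}" for j in range(6)], np.tile(profile, (3, 1))
        )
        record = global_mean_factor(t)
        assert record.place == 1

    def test_two_gene_table_global_mean_equals_the_pair(self, rng):
        t = random_table(rng, n_genes=2, n_samples=6)
        pair = enumerate_combinations(t, k=2)[0]
        record = global_mean_factor(t)
        assert record.final_score == pytest.approx(pair.final_score, abs=1e-12)
        assert record.place == pair.place

    def test_global_mean_not_guaranteed_first(self, rng):
        # when most genes share a co-regulated per-sample swing, the all-gene
        # mean inherits it while quiet genes do not, so the global mean loses
        n_samples = 8
        shared = rng.normal(0, 2.0, size=n_samples)
        cq = np.empty((12, n_samples))
        cq[0] = 22.0 + rng.normal(0, 0.05, n_samples)
        cq[1] = 26.0 + rng.normal(0, 0.05, n_samples)
        for i in range(2, 12):
            cq[i] = 20.0 + i + shared + rng.normal(0, 0.3, n_samples)
        t = ExpressionTable([f"g{i}" for i in range(12)], [f"s{j}" for j in range(n_samples)], cq)
        assert global_mean_factor(t).place > 1


class TestComponentComparison:
    def _record(self, members, score):
        return CombinationRecord(
            members=members, dataset_id="d", rank_by_algorithm={},
            final_score=score, place=1,
        )

    def test_pair_better_than_all_components(self):
        comp = compare_to_components(
            [self._record(("A", "B"), 0.1)], {"A": 0.2, "B": 0.3}
        )
        assert comp.category_counts()["better_than_all_components"] == 1

    def test_pair_better_than_some(self):
        comp = compare_to_components(
            [self._record(("A", "B"), 0.25)], {"A": 0.2, "B": 0.3}
        )
        assert comp.category_counts()["better_than_some"] == 1
        assert comp.counts_by_n_better == {0: 0, 1: 1, 2: 0}

    def test_triple_four_way_split(self):
        records = [
            self._record(("A", "B", "C"), 0.50),  # worse than all 3
            self._record(("A", "B", "D"), 0.25),  # 2 components better
            self._record(("A", "C", "D"), 0.15),  # 1 component better
            self._record(("B", "C", "D"), 0.05),  # better than all
        ]
        singles = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4}
        comp = compare_to_components(records, singles)
        assert comp.counts_by_n_better == {0: 1, 1: 1, 2: 1, 3: 1}
        fractions = comp.category_fractions()
        assert fractions["worse_than_all_components"] == pytest.approx(0.25)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_missing_single_score_rejected(self):
        with pytest.raises(KeyError):
            compare_to_components([self._record(("A", "B"), 0.2)], {"A": 0.1})


def test_records_export_roundtrip(rng):
    t = random_table(rng, n_genes=5, n_samples=6)
    records = enumerate_combinations(t, k=2, dataset_id="toy")
    frame = records_to_frame(records)
    assert len(frame) == comb(5, 2)
    assert frame["members"].str.contains(";").all()
    assert (frame["dataset_id"] == "toy").all()
    assert frame["final_score"].between(0, 1, inclusive="left").all()
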
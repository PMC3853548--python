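"""Tree data model: construction, validation, clade primitives."""

import itertools

import numpy as np
import pytest

from treesum.core import (
    TaxonSet,
    TreeError,
    branch_length,
    build_tree,
    divergence_time,
    mrca_age,
    pairs_splitting_at,
)

from conftest import random_tree


class TestBuildTree:
    def test_fixture_round_trip(self, tx, fixture_trees):
        TA, _, _ = fixture_trees
        A = tx.clade
        assert TA.ages[A("ab")] == 1.0
        assert TA.ages[A("abc")] == 2.0
        assert TA.ages[A("a")] == 0.0  # singleton implied at age 0

    def test_overlap_without_nesting_rejected(self, tx):
        A = tx.clade
        with pytest.raises(TreeError, match="overlap"):
            build_tree(tx, {A("ab"): 1.0, A("bc"): 1.0, A("abc"): 2.0})

    def test_child_older_than_parent_rejected(self, tx):
        A = tx.clade
        with pytest.raises(TreeError, match="older"):
            build_tree(tx, {A("ab"): 3.0, A("abc"): 2.0})

    def test_negative_age_rejected(self, tx):
        A = tx.clade
        with pytest.raises(TreeError, match="negative"):
            build_tree(tx, {A("ab"): -1.0, A("abc"): 2.0})

    def test_missing_root_rejected(self, tx):
        with pytest.raises(TreeError, match="root"):
            build_tree(tx, {tx.clade("ab"): 1.0})

    def test_dated_tips_rejected(self, tx):
        A = tx.clade
        with pytest.raises(TreeError, match="contemporaneous"):
            build_tree(tx, {A("a"): 0.5, A("ab"): 1.0, A("abc"): 2.0})

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            TaxonSet(["a", "a", "b"])

    def test_accessor_round_trip_random(self, rng):
        for _ in range(25):
            t = random_tree(rng, n=int(rng.integers(3, 9)))
            rebuilt = build_tree(t.taxa, dict(t.ages))
            assert rebuilt.equals(t, tol=0.0)


class TestMrcaAge:
    @pytest.mark.parametrize(
        "tree_i,subset,expected", [(0, "ab", 1.0), (2, "ab", 2.0), (0, "a", 0.0)]
    )
    def test_examples(self, tx, fixture_trees, tree_i, subset, expected):
        assert mrca_age(fixture_trees[tree_i], tx.clade(subset)) == expected

    def test_empty_subset_rejected(self, fixture_trees):
        with pytest.raises(TreeError):
            mrca_age(fixture_trees[0], 0)

    def test_monotone_in_subset(self, rng):
        for _ in range(20):
            t = random_tree(rng, n=7)
            full = t.taxa.full_mask
            x = int(rng.integers(1, full + 1))
            extra = int(rng.integers(0, full + 1))
            y = x | extra
            assert mrca_age(t, x) <= mrca_age(t, y)


class TestBranchLength:
    def test_examples(self, tx, fixture_trees):
        TA = fixture_trees[0]
        assert branch_length(TA, tx.clade("ab")) == 1.0
        assert branch_length(TA, tx.clade("abc")) == 0.0  # root
        assert branch_length(TA, tx.clade("bc")) == 0.0  # absent subset

    def test_total_length_matches_traversal_oracle(self, rng):
        # oracle: accumulate parent-minus-child age differences by an
        # explicit recursion over the children map
        for _ in range(20):
            t = random_tree(rng, n=int(rng.integers(3, 9)))

            def walk(clade):
                total = 0.0
                for ch in t.children[clade]:
                    total += t.ages[clade] - t.ages[ch] + walk(ch)
                return total

            assert np.isclose(t.total_length(), walk(t.root), atol=1e-12)


class TestPairsSplitting:
    def test_examples(self, tx, fixture_trees):
        TA = fixture_trees[0]
        a, b, c = (tx.clade(x) for x in "abc")
        root_pairs = {frozenset(p) for p in pairs_splitting_at(TA, tx.clade("abc"))}
        assert root_pairs == {frozenset({a, c}), frozenset({b, c})}
        assert pairs_splitting_at(TA, tx.clade("ab")) == [(a, b)]
        assert pairs_splitting_at(TA, a) == []

    def test_not_a_clade_rejected(self, tx, fixture_trees):
        with pytest.raises(TreeError):
            pairs_splitting_at(fixture_trees[0], tx.clade("bc"))

    def test_pairs_partition_all_taxon_pairs(self, rng):
        for _ in range(15):
            t = random_tree(rng, n=7)
            seen = []
            for c in t.internal_clades():
                seen.extend(
                    frozenset(p) for p in pairs_splitting_at(t, c)
                )
            n = len(t.taxa)
            assert len(seen) == n * (n - 1) // 2
            assert len(set(seen)) == len(seen)


class TestDivergenceTime:
    def test_examples(self, tx, fixture_trees):
        TA, _, TC = fixture_trees
        assert divergence_time(tx.clade("abc"), TA, TA) == 2.0
        assert divergence_time(tx.clade("abc"), TA, TC) == 1.5
        assert divergence_time(tx.clade("ab"), TA, TC) == 2.0

    def test_self_reference_returns_own_age(self, rng):
        for _ in range(15):
            t = random_tree(rng, n=6)
            for c in t.internal_clades():
                assert np.isclose(divergence_time(c, t, t), t.ages[c])
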
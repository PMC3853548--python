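"""Taxa-partition summary tree: ordering, split pooling, reconstruction."""

import numpy as np
import pytest

from treesum.core import TaxonSet, build_tree
from treesum.taxa_partition import (
    TaxaOrder,
    pair_distance_matrix,
    split_ages,
    taxa_order,
    taxa_partition_tree,
    tp_tree,
)

from conftest import make_sample, random_sample


@pytest.fixture(scope="module")
def abcd():
    return TaxonSet("abcd")


def _order(taxa, labels):
    return TaxaOrder(taxa, tuple(taxa.index[x] for x in labels))


def test_pair_distance_matrix_single_tree(tx, fixture_trees):
    m = pair_distance_matrix(make_sample(fixture_trees[0]))
    i = tx.index
    assert m[i["a"], i["b"]] == 2
    assert m[i["a"], i["c"]] == 3
    assert m[i["b"], i["c"]] == 3
    assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)


def test_pair_distance_matrix_mixture(tx, fixture_trees):
    TA, _, TC = fixture_trees
    m = pair_distance_matrix(make_sample(TA, TC))
    i = tx.index
    assert m[i["a"], i["b"]] == pytest.approx(2.5)


def test_pair_distance_star_tree(tx):
    star = build_tree(tx, {tx.clade("abc"): 1.0})
    m = pair_distance_matrix(make_sample(star))
    off = m[~np.eye(3, dtype=bool)]
    assert np.all(off == 3)


def test_taxa_order_puts_cherry_adjacent(tx, fixture_trees):
    order = taxa_order(
        pair_distance_matrix(make_sample(fixture_trees[0])), tx
    )
    labels = order.labels
    assert abs(labels.index("a") - labels.index("b")) == 1


def test_taxa_order_caterpillar(abcd):
    A = abcd.clade
    cat = build_tree(
        abcd, {A("ab"): 1.0, A("abc"): 2.0, A("abcd"): 3.0}
    )
    order = taxa_order(pair_distance_matrix(make_sample(cat)), abcd)
    labels = list(order.labels)
    # every clade of the caterpillar occupies a contiguous run
    for clade in ("ab", "abc", "abcd"):
        pos = sorted(labels.index(x) for x in clade)
        assert pos == list(range(pos[0], pos[0] + len(pos)))
    assert labels.index("d") in (0, 3)


def test_two_taxa_order():
    t2 = TaxonSet("ab")
    tree = build_tree(t2, {t2.clade("ab"): 1.0})
    order = taxa_order(pair_distance_matrix(make_sample(tree)), t2)
    assert sorted(order.labels) == ["a", "b"]


class TestSplitAges:
    """The three published contribution examples for the order [a b c d]."""

    def test_nested_caterpillar_contributes_everywhere(self, abcd):
        A = abcd.clade
        t = build_tree(
            abcd, {A("ab"): 1.0, A("abc"): 2.0, A("abcd"): 3.0}
        )
        sa = split_ages(_order(abcd, "abcd"), make_sample(t))
        assert sa.values[0] == [1.0]  # [a | bcd] gets age of (a,b)
        assert sa.values[1] == [2.0]  # [ab | cd] gets age of ((a,b),c)
        assert sa.values[2] == [3.0]  # [abc | d] gets the root height

    def test_discontiguous_clades_contribute_nothing(self, abcd):
        A = abcd.clade
        t = build_tree(
            abcd, {A("ad"): 1.0, A("bc"): 1.5, A("abcd"): 3.0}
        )
        sa = split_ages(_order(abcd, "abcd"), make_sample(t))
        assert sa.values[0] == []
        assert sa.values[1] == [1.5]  # only (b,c) spans an unbroken range
        assert sa.values[2] == []

    def test_root_only_contribution(self, abcd):
        A = abcd.clade
        t = build_tree(
            abcd, {A("bd"): 1.0, A("bcd"): 2.0, A("abcd"): 3.0}
        )
        sa = split_ages(_order(abcd, "abcd"), make_sample(t))
        assert sa.values[0] == [3.0]  # root height to [a | bcd]
        assert sa.values[1] == []
        assert sa.values[2] == []

    def test_each_age_lands_on_at_most_one_split(self, rng):
        for _ in range(10):
            sample = random_sample(rng, n=6, size=8, moves=1.5)
            order = taxa_order(pair_distance_matrix(sample), sample.taxa)
            sa = split_ages(order, sample)
            contributed = sum(len(v) for v in sa.values)
            available = sum(len(t.internal_clades()) for t in sample)
            assert contributed <= available


def test_tp_worked_mixture(tx):
    """Competing topologies: the higher split estimate wins the root."""
    A = tx.clade
    TA = build_tree(tx, {A("ab"): 1.0, A("abc"): 2.0})
    TCp = build_tree(tx, {A("bc"): 0.8, A("abc"): 2.0})
    sample = make_sample(TA, TA, TCp)
    order = _order(tx, "abc")
    sa = split_ages(order, sample)
    assert sorted(sa.values[0]) == [1.0, 1.0, 2.0]
    assert sorted(sa.values[1]) == [0.8, 2.0, 2.0]
    res = tp_tree(order, sa, "median")
    # [ab | c] estimate (2) is higher than [a | bc] (1): ((a,b),c) wins
    assert A("ab") in res.tree.ages
    assert res.tree.ages[A("ab")] == pytest.approx(1.0)
    assert res.tree.root_height == pytest.approx(2.0)


def test_identical_sample_recovers_tree(rng):
    for _ in range(10):
        t = random_sample(rng, n=6, size=1, moves=0.0, cv=0.0)[0]
        res = taxa_partition_tree(make_sample(*[t] * 5), "median")
        assert res.tree.equals(t, tol=1e-12)
        assert res.clamped == 0 and not res.fallback_used


def test_two_taxa_tp():
    t2 = TaxonSet("ab")
    trees = [build_tree(t2, {t2.clade("ab"): h}) for h in (1.0, 2.0, 6.0)]
    res = taxa_partition_tree(make_sample(*trees), "median")
    assert res.tree.root_height == pytest.approx(2.0)


def test_tp_output_always_valid(rng):
    for _ in range(20):
        sample = random_sample(rng, n=7, size=10, moves=2.0, cv=0.4)
        res = taxa_partition_tree(sample, "median")
        build_tree(sample.taxa, res.tree.ages)
        assert res.tree.root_height == pytest.approx(
            max(
                res.tree.ages[c] for c in res.tree.internal_clades()
            )
        )
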
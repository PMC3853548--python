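"""Likelihoods, error reports, and the ranking protocol."""

import itertools
import math

import numpy as np
import pytest

from treesum.core import TaxonSet, build_tree
from treesum.evaluate import (
    RankTable,
    bootstrap_scores,
    coalescent_log_likelihood,
    dense_rank,
    error_report,
    jc_log_likelihood,
    model_fit_percentile,
    normalize_errors,
)
from treesum.simulate import sample_coalescent, simulate_jc, pseudo_posterior

from conftest import make_sample


def _enumeration_loglik(tree, aln, mu):
    """Sum over all internal-state assignments (oracle for ≤4 taxa)."""
    labs = tree.taxa.labels
    nuc = {"A": 0, "C": 1, "G": 2, "T": 3}
    internals = sorted(tree.internal_clades())
    total = 0.0
    for site in range(aln.length):
        obs = {
            c: nuc[aln.sequences[labs[c.bit_length() - 1]][site]]
            for c in tree.ages
            if c.bit_count() == 1
        }
        lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, states))
            st.update(obs)
            pr = 0.25
            for c in tree.ages:
                p = tree.parent.get(c)
                if p is None:
                    continue
                d = (tree.ages[p] - tree.ages[c]) * mu
                e = math.exp(-4 * d / 3)
                pr *= 0.25 + 0.75 * e if st[c] == st[p] else 0.25 - 0.25 * e
            lik += pr
        total += math.log(lik)
    return total


class TestJcLikelihood:
    def test_identical_sequences_zero_branches(self, rng):
        tx = TaxonSet("ab")
        tree = build_tree(tx, {tx.clade("ab"): 0.0})
        aln = simulate_jc(tree, 50, 0.005, rng)
        assert jc_log_likelihood(tree, aln, 1.0) == pytest.approx(
            50 * math.log(0.25)
        )

    def test_cherry_closed_form(self):
        tx = TaxonSet("ab")
        height = 0.7
        tree = build_tree(tx, {tx.clade("ab"): height})
        from treesum.simulate import Alignment

        aln = Alignment(tx, {"a": "A", "b": "A"})
        expected = math.log(
            0.25 * (0.25 + 0.75 * math.exp(-8 * height / 3))
        )
        assert jc_log_likelihood(tree, aln, 1.0) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [3, 4])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(8):
            tree = sample_coalescent(n, 1.0, rng)
            aln = simulate_jc(tree, 12, 0.4, rng)
            assert jc_log_likelihood(tree, aln, 0.4) == pytest.approx(
                _enumeration_loglik(tree, aln, 0.4), abs=1e-10
            )


class TestCoalescentLikelihood:
    def test_two_tip_closed_form(self):
        tx = TaxonSet("ab")
        for h, ne in [(0.5, 1.0), (2.0, 3.0)]:
            tree = build_tree(tx, {tx.clade("ab"): h})
            assert coalescent_log_likelihood(tree, ne) == pytest.approx(
                -math.log(ne) - h / ne
            )

    def test_worked_three_taxon_value(self, fixture_trees):
        assert coalescent_log_likelihood(fixture_trees[0], 1.0) == \
            pytest.approx(-4.0)

    def test_scaling_identity(self, rng):
        """Scaling tree and Ne by s shifts the density by −(n−1)·log s."""
        for _ in range(10):
            n = int(rng.integers(3, 10))
            tree = sample_coalescent(n, 1.0, rng)
            s = float(rng.uniform(0.5, 4.0))
            scaled = build_tree(
                tree.taxa, {c: a * s for c, a in tree.ages.items()}
            )
            assert coalescent_log_likelihood(scaled, s) == pytest.approx(
                coalescent_log_likelihood(tree, 1.0) - (n - 1) * math.log(s)
            )

    def test_invalid_pop_size(self, fixture_trees):
        with pytest.raises(ValueError):
            coalescent_log_likelihood(fixture_trees[0], 0.0)


def test_model_fit_percentile_bounds(rng):
    truth = sample_coalescent(5, 1.0, rng)
    aln = simulate_jc(truth, 100, 0.01, rng)
    sample = pseudo_posterior(truth, 10, 1.0, 0.2, rng)
    fits = [
        jc_log_likelihood(t, aln, 0.01) + coalescent_log_likelihood(t, 1.0)
        for t in sample
    ]
    best = sample[int(np.argmax(fits))]
    assert model_fit_percentile(best, sample, aln, 0.01, 1.0) == 1.0
    conc = pseudo_posterior(truth, 5, 0.0, 0.0, rng)
    assert model_fit_percentile(truth, conc, aln, 0.01, 1.0) == 1.0


def test_error_report_composition(fixture_trees, rng):
    TA, _, TC = fixture_trees
    ev = error_report(TA, TC)
    assert ev.heights_error == pytest.approx(1.0)
    assert ev.divergence_error == pytest.approx(1.5)
    assert ev.clades_missed == 1
    assert ev.clades_called == 1
    same = error_report(TA, TA)
    assert same.root_height_error == same.heights_error == 0.0


class TestRanking:
    def test_dense_rank_1223_rule(self):
        assert list(dense_rank([0.1, 0.3, 0.3, 0.5])) == [1, 2, 2, 3]
        assert list(dense_rank([5, 5, 5])) == [1, 1, 1]
        assert list(dense_rank(range(4))) == [1, 2, 3, 4]

    def test_normalize_errors(self, rng):
        assert np.allclose(normalize_errors([[1.0, 3.0]]), [[-1, 1]])
        assert np.allclose(normalize_errors([[2.0, 2.0, 2.0]]), 0.0)
        m = rng.uniform(size=(5, 4))
        z = normalize_errors(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)

    def test_bootstrap_strict_ordering_scores_012(self):
        m = np.tile([1.0, 2.0, 3.0], (6, 1))
        scores = bootstrap_scores(m, 4000, 0.9, np.random.default_rng(0))
        assert list(scores) == [0, 1, 2]

    def test_bootstrap_duplicated_method_ties(self):
        m = np.tile([1.0, 1.0, 3.0], (6, 1))
        scores = bootstrap_scores(m, 1000, 0.9, np.random.default_rng(0))
        assert list(scores) == [0, 0, 1]

    def test_bootstrap_best_everywhere_scores_zero(self, rng):
        m = rng.uniform(1, 2, size=(8, 3))
        m[:, 1] = 0.0
        scores = bootstrap_scores(m, 500, 0.9, np.random.default_rng(1))
        assert scores[1] == 0

    def test_bootstrap_column_permutation_equivariant(self, rng):
        m = rng.uniform(size=(10, 4))
        perm = [2, 0, 3, 1]
        s1 = bootstrap_scores(m, 800, 0.9, np.random.default_rng(3))
        s2 = bootstrap_scores(m[:, perm], 800, 0.9, np.random.default_rng(3))
        assert list(s2) == [int(s1[j]) for j in perm]

    def test_rank_table_smoke(self, rng):
        errors = {
            "a": rng.uniform(size=(6, 3)),
            "b": rng.uniform(size=(6, 3)),
        }
        table = RankTable.from_errors(["m1", "m2", "m3"], errors, reps=300)
        for meas in ("a", "b"):
            assert np.all(np.isfinite(table.mean_ranks[meas]))
            assert table.comparison_scores[meas].shape == (3,)
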
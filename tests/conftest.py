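import numpy as np
import pytest

from treesum.core import TaxonSet, TreeSample, build_tree
from treesum.simulate import pseudo_posterior, sample_coalescent


@pytest.fixture(scope="session")
def tx():
    return TaxonSet("abc")


@pytest.fixture(scope="session")
def fixture_trees(tx):
    """The three worked-example trees on taxa {a, b, c}."""
    A = tx.clade
    TA = build_tree(tx, {A("ab"): 1.0, A("abc"): 2.0})
    TB = build_tree(tx, {A("ab"): 0.5, A("abc"): 3.0})
    TC = build_tree(tx, {A("bc"): 1.0, A("abc"): 2.0})
    return TA, TB, TC


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_tree(rng, n=6, ne=1.0):
    return sample_coalescent(n, ne, rng)


def random_sample(rng, n=6, size=10, moves=1.0, cv=0.3, ne=1.0):
    truth = sample_coalescent(n, ne, rng)
    return pseudo_posterior(truth, size, moves, cv, rng)


def make_sample(*trees):
    return TreeSample.from_trees(list(trees))
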
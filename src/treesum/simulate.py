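"""Synthetic test cases: coalescent trees, JC sequences, pseudo-posteriors.

The study conditions emulated here are a 5×4 grid of Kingman coalescent
trees (n ∈ {8, 16, 32, 64, 128} contemporaneous tips, constant population
size Ne ∈ {1, 2, 4, 8}) with 800 bp alignments simulated under the
Jukes-Cantor model at mutation rate 0.005 substitutions per site per
coalescent time unit, so mean tree heights range over roughly 0.01-0.08
substitutions.  Coalescent node ages are kept in population-size time
units; multiplying by the mutation rate converts to substitution units.

A real posterior from MCMC is replaced by a pseudo-posterior generator:
jittered copies of a reference tree, with topology noise applied as
random NNI moves and height noise applied in the ratio parametrization
(root height times a lognormal factor, each age/parent ratio perturbed
on the logit scale), which keeps every replicate a valid time tree.
This emulates unimodal posterior spread around the truth; it does not
emulate MCMC autocorrelation or multi-modal posteriors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core import TaxonSet, TimeTree, TreeSample
from .min_distance import encode, decode, ParamVector

__all__ = [
    "SimConfig",
    "Alignment",
    "sample_coalescent",
    "simulate_jc",
    "pseudo_posterior",
    "write_fasta",
]

#: the simulation grid of the study design
GRID_N = (8, 16, 32, 64, 128)
GRID_NE = (1, 2, 4, 8)


@dataclass
class SimConfig:
    """One simulation setting."""

    n_tips: int = 8
    pop_size: float = 1.0
    seq_length: int = 800
    mut_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2 or self.pop_size <= 0 or self.seq_length <= 0 \
                or self.mut_rate <= 0:
            raise ValueError("SimConfig fields must be positive (n_tips ≥ 2)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class Alignment:
    """Aligned nucleotide sequences, one per taxon."""

    taxa: TaxonSet
    sequences: dict[str, str]

    def __post_init__(self):
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError("sequences have unequal lengths")
        if set(self.sequences) != set(self.taxa.labels):
            raise ValueError("sequence labels do not match the taxon set")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


def sample_coalescent(
    n: int, pop_size: float, rng: np.random.Generator,
    labels: tuple[str, ...] | None = None,
) -> TimeTree:
    """Draw a tree from the Kingman coalescent with constant Ne.

    With k lineages the waiting time to the next merger is exponential
    with rate k(k−1)/(2 Ne); the merging pair is uniform.  Ages are in
    population-size time units.
    """
    if n < 2 or pop_size <= 0:
        raise ValueError("need n ≥ 2 and Ne > 0")
    taxa = TaxonSet(labels if labels is not None else
                    tuple(f"t{i + 1}" for i in range(n)))
    lineages = [1 << i for i in range(n)]
    ages = {m: 0.0 for m in lineages}
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 * pop_size / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [m for idx, m in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        ages[merged] = t
    return TimeTree(taxa, ages)


_NUC = "ACGT"


def simulate_jc(
    tree: TimeTree, length: int, mut_rate: float, rng: np.random.Generator
) -> Alignment:
    """Evolve sequences down the tree under Jukes-Cantor.

    The root sequence is uniform; along a branch of duration t each site
    changes with probability 3/4·(1 − e^(−4tμ/3)), to a uniformly chosen
    different state.
    """
    seqs: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=length)
    }
    stack = [tree.root]
    tip_seqs: dict[str, str] = {}
    while stack:
        c = stack.pop()
        s = seqs.pop(c)
        if c.bit_count() == 1:
            label = tree.taxa.labels[c.bit_length() - 1]
            tip_seqs[label] = "".join(_NUC[x] for x in s)
            continue
        for ch in tree.children[c]:
            t = tree.ages[c] - tree.ages[ch]
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t * mut_rate / 3.0))
            hit = rng.random(length) < p_change
            child = s.copy()
            child[hit] = (s[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            seqs[ch] = child
            stack.append(ch)
    return Alignment(tree.taxa, tip_seqs)


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label in alignment.taxa.labels:
            fh.write(f">{label}\n{alignment.sequences[label]}\n")


# ---------------------------------------------------------------------------
# Pseudo-posterior

def _nni(tree: TimeTree, rng: np.random.Generator) -> TimeTree:
    """One random nearest-neighbour interchange, preserving ages where
    the swap leaves them valid and redrawing the reattached node's age
    uniformly in its feasible interval otherwise."""
    cands = [c for c in tree.nontrivial_clades()
             if len(tree.children[c]) == 2]
    if not cands:
        return tree
    c = cands[rng.integers(len(cands))]
    p = tree.parent[c]
    sibs = [x for x in tree.children[p] if x != c]
    s = sibs[rng.integers(len(sibs))]
    kids = tree.children[c]
    keep = kids[rng.integers(2)]          # stays inside the new clade
    new_c = keep | s
    ages = dict(tree.ages)
    old = ages.pop(c)
    lo = max(ages[keep], ages[s])
    hi = ages[p]
    ages[new_c] = old if lo <= old <= hi else rng.uniform(lo, hi)
    return TimeTree(tree.taxa, ages)


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def pseudo_posterior(
    true_tree: TimeTree,
    size: int,
    topo_moves_mean: float = 1.0,
    height_cv: float = 0.1,
    rng: np.random.Generator | None = None,
) -> TreeSample:
    """Jittered copies of a reference tree standing in for an MCMC sample.

    Each replicate applies Poisson(topo_moves_mean) NNI moves, then (for
    height_cv > 0) multiplies the root height by exp(N(0, cv)) and adds
    N(0, cv) noise to each age ratio on the logit scale before decoding —
    so every replicate is a valid time tree.  Deterministic given the
    generator state; with both noise levels at 0 the replicates are exact
    copies.
    """
    if size < 1 or topo_moves_mean < 0 or height_cv < 0:
        raise ValueError("invalid pseudo-posterior parameters")
    rng = rng if rng is not None else np.random.default_rng(0)
    eps = 1e-9
    reps = []
    for _ in range(size):
        t = true_tree
        for _ in range(rng.poisson(topo_moves_mean)):
            t = _nni(t, rng)
        if height_cv > 0:
            pv = encode(t)
            z = pv.z.copy()
            z[0] *= np.exp(rng.normal(0.0, height_cv))
            a = np.clip(z[1:], eps, 1.0 - eps)
            z[1:] = 1.0 / (1.0 + np.exp(-(_logit(a)
                                          + rng.normal(0.0, height_cv,
                                                       a.shape))))
            t = decode(ParamVector(pv.topology, z))
        reps.append(t)
    return TreeSample(true_tree.taxa, reps)
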
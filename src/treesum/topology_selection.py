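"""Selecting a summary topology from the sampled trees.

All selectors return an index into the sample: the search is restricted
to topologies actually present in the posterior.  Ties are broken by the
lowest index, so every selector is deterministic.

* MCC — maximum clade credibility: highest product of clade posterior
  frequencies (computed in log space).
* CCD — conditional clade distribution: highest product of split
  probabilities conditional on clade occurrence.
* TCB — total clade branch: highest sum of per-clade scores, a clade's
  score being the total length of its matched branches in the sample
  (support weighted by branch length).  Whether the per-tree combination
  is a sum or a product is not published; the sum is the default here and
  the product is available via ``combine="product"``.
* HPF — highest posterior frequency topology; frequency ties go to the
  topology holding the sampled tree whose root height is closest to the
  posterior mean root height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import TimeTree, TreeSample

__all__ = [
    "CladeFrequencies",
    "SplitTally",
    "clade_frequencies",
    "clade_credibility",
    "select_mcc",
    "ccd_tally",
    "ccd_log_prob",
    "select_ccd",
    "tcb_scores",
    "select_tcb",
    "select_hpf",
]


@dataclass
class CladeFrequencies:
    """Posterior clade frequencies with exact sample-size denominator."""

    freq: dict[int, float]
    sample_size: int

    def __call__(self, clade: int) -> float:
        return self.freq.get(clade, 0.0)


def clade_frequencies(sample: TreeSample) -> CladeFrequencies:
    """Fraction of sampled trees containing each observed clade."""
    counts: dict[int, int] = {}
    for t in sample:
        for c in t.ages:
            counts[c] = counts.get(c, 0) + 1
    k = len(sample)
    return CladeFrequencies({c: n / k for c, n in counts.items()}, k)


def clade_credibility(tree: TimeTree, freqs: CladeFrequencies) -> float:
    """Log clade credibility: Σ log F(c) over the tree's clades.

    A clade never observed in the sample yields −inf (sentinel), which
    cannot happen for trees taken from the sample itself.
    """
    total = 0.0
    for c in tree.ages:
        f = freqs(c)
        if f == 0.0:
            return -math.inf
        total += math.log(f)
    return total


def _argmax_first(scores: list[float]) -> int:
    best = max(scores)
    return scores.index(best)


def select_mcc(sample: TreeSample) -> int:
    """Index of the sampled tree with maximal clade credibility."""
    freqs = clade_frequencies(sample)
    return _argmax_first([clade_credibility(t, freqs) for t in sample])


# ---------------------------------------------------------------------------
# Conditional clade distribution

@dataclass
class SplitTally:
    """Observed child splits per internal clade, with clade counts."""

    splits: dict[int, dict[tuple[int, ...], int]]
    clade_counts: dict[int, int]
    sample_size: int


def _split_key(tree: TimeTree, clade: int) -> tuple[int, ...]:
    return tuple(sorted(tree.children[clade]))


def ccd_tally(sample: TreeSample) -> SplitTally:
    """Count, per internal clade, how often each child split occurs."""
    splits: dict[int, dict[tuple[int, ...], int]] = {}
    counts: dict[int, int] = {}
    for t in sample:
        for c in t.internal_clades():
            counts[c] = counts.get(c, 0) + 1
            d = splits.setdefault(c, {})
            key = _split_key(t, c)
            d[key] = d.get(key, 0) + 1
    return SplitTally(splits, counts, len(sample))


def ccd_log_prob(tree: TimeTree, tally: SplitTally) -> float:
    """Log CCD probability: Σ over internal clades of
    log(split count / clade count); −inf for an unobserved split."""
    total = 0.0
    for c in tree.internal_clades():
        d = tally.splits.get(c)
        if not d:
            return -math.inf
        n = d.get(_split_key(tree, c), 0)
        if n == 0:
            return -math.inf
        total += math.log(n / tally.clade_counts[c])
    return total


def select_ccd(sample: TreeSample) -> int:
    """Index of the sampled tree with maximal CCD probability."""
    tally = ccd_tally(sample)
    return _argmax_first([ccd_log_prob(t, tally) for t in sample])


# ---------------------------------------------------------------------------
# Total clade branch

def tcb_scores(sample: TreeSample) -> dict[int, float]:
    """Per-clade total matched branch length across the sample."""
    scores: dict[int, float] = {}
    for t in sample:
        for c in t.ages:
            scores[c] = scores.get(c, 0.0) + t.branch_length(c)
    return scores


def select_tcb(sample: TreeSample, combine: str = "sum") -> int:
    """Index of the sampled tree with the highest total clade-branch score."""
    scores = tcb_scores(sample)
    if combine == "sum":
        tree_scores = [sum(scores[c] for c in t.ages) for t in sample]
    elif combine == "product":
        tree_scores = [
            sum(math.log(scores[c]) if scores[c] > 0 else -math.inf
                for c in t.ages if c != t.root)
            for t in sample
        ]
    else:
        raise ValueError("combine must be 'sum' or 'product'")
    return _argmax_first(tree_scores)


def select_hpf(sample: TreeSample) -> int:
    """Index of (the first tree of) the most frequent sampled topology.

    Among topologies tied on frequency, the winner is the one containing
    the sampled tree whose root height is closest to the posterior mean
    root height; remaining ties go to the lowest index.
    """
    topo_of = [t.topology_key() for t in sample]
    counts: dict[frozenset[int], int] = {}
    for key in topo_of:
        counts[key] = counts.get(key, 0) + 1
    top = max(counts.values())
    tied = {key for key, n in counts.items() if n == top}
    if len(tied) > 1:
        mean_root = sum(t.root_height for t in sample) / len(sample)
        best_key = None
        best_dev = math.inf
        for i, t in enumerate(sample):
            if topo_of[i] in tied:
                dev = abs(t.root_height - mean_root)
                if dev < best_dev:
                    best_dev = dev
                    best_key = topo_of[i]
        tied = {best_key}
    (winner,) = tied
    return topo_of.index(winner)
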
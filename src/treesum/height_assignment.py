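"""Assigning node ages to a fixed summary topology.

Two families:

* pointwise (TreeAnnotator-style AVG/MED) — each clade's age is the mean
  or median of its ages in the posterior trees that contain it.  Because
  each age uses a different subset of trees, the result may violate the
  age ordering ("negative branches"); such assignments are returned
  flagged, never silently repaired.
* common-ancestor (CAT) — each clade's age is the mean over *all*
  posterior trees of the age of its MRCA there.  Since nesting of clades
  implies ordering of MRCA ages within every tree, the mean preserves it
  and the result is always a valid tree.

Majority-rule consensus (CONS) takes the clades above a frequency
threshold (default strict majority) and ages them CAT-style (MRCA ages
over all trees, mean or median), which again guarantees validity; a
matched-ages-only variant is available via ``matched_only=True``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable

from .core import TaxonSet, TimeTree, TreeSample, TreeError, build_tree
from .topology_selection import clade_frequencies

__all__ = [
    "HeightAssignment",
    "pointwise_heights",
    "cat_heights",
    "consensus_tree",
]

_STATS = {"mean": statistics.fmean, "median": statistics.median}


@dataclass
class HeightAssignment:
    """A topology with per-clade ages; possibly not a valid tree."""

    taxa: TaxonSet
    heights: dict[int, float]
    negative_branches: list[tuple[int, float]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.negative_branches

    def tree(self) -> TimeTree:
        """Materialize as a validated TimeTree (fails if invalid)."""
        if not self.valid:
            raise TreeError(
                f"assignment has {len(self.negative_branches)} negative branches"
            )
        return build_tree(self.taxa, self.heights)


def _topology_clades(topology: Iterable[int] | TimeTree) -> list[int]:
    if isinstance(topology, TimeTree):
        return [c for c in topology.ages if c.bit_count() > 1]
    return [c for c in topology if c.bit_count() > 1]


def _flag_negatives(taxa: TaxonSet, heights: dict[int, float]):
    """List (clade, magnitude) for child-older-than-parent violations."""
    by_size = sorted(heights, key=lambda c: c.bit_count())
    neg = []
    for i, c in enumerate(by_size[:-1]):
        for p in by_size[i + 1:]:
            if c & p == c and p != c:  # p is c's parent (minimal superset)
                if heights[c] > heights[p] + 1e-12:
                    neg.append((c, heights[c] - heights[p]))
                break
    return neg


def pointwise_heights(
    topology: Iterable[int] | TimeTree, sample: TreeSample, stat: str = "mean"
) -> HeightAssignment:
    """TreeAnnotator-style ages: per-clade mean/median of matched ages.

    Every internal clade of the topology must occur in at least one
    sampled tree.  Validity is flagged, not repaired.
    """
    agg = _STATS[stat]
    heights: dict[int, float] = {}
    for c in _topology_clades(topology):
        matched = [t.ages[c] for t in sample if c in t.ages]
        if not matched:
            raise TreeError("topology clade never observed in the sample")
        heights[c] = agg(matched)
    for i in range(len(sample.taxa)):
        heights[1 << i] = 0.0
    return HeightAssignment(
        sample.taxa, heights, _flag_negatives(sample.taxa, heights)
    )


def cat_heights(
    topology: Iterable[int] | TimeTree, sample: TreeSample, stat: str = "mean"
) -> HeightAssignment:
    """Common-ancestor ages: per-clade mean (over *all* sampled trees) of
    the clade's MRCA age.  Always yields a valid tree."""
    agg = _STATS[stat]
    heights: dict[int, float] = {}
    for c in _topology_clades(topology):
        heights[c] = agg(t.mrca_age(c) for t in sample)
    for i in range(len(sample.taxa)):
        heights[1 << i] = 0.0
    return HeightAssignment(
        sample.taxa, heights, _flag_negatives(sample.taxa, heights)
    )


def consensus_tree(
    sample: TreeSample,
    threshold: float = 0.5,
    stat: str = "median",
    matched_only: bool = False,
) -> TimeTree:
    """Majority-rule consensus with ages.

    Topology: clades with posterior frequency strictly above ``threshold``
    (≥ 0.5, which guarantees mutual compatibility).  Ages: ``stat`` of the
    clade's MRCA age over all trees (default), or of matched ages only
    when ``matched_only`` (which may need clamping and is repaired
    child-to-parent here since consensus must return a tree).
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    freqs = clade_frequencies(sample)
    agg = _STATS[stat]
    keep = [
        c
        for c, f in freqs.freq.items()
        if c.bit_count() > 1 and (f > threshold or c == sample.taxa.full_mask)
    ]
    heights: dict[int, float] = {}
    for c in keep:
        if matched_only:
            heights[c] = agg(t.ages[c] for t in sample if c in t.ages)
        else:
            heights[c] = agg(t.mrca_age(c) for t in sample)
    if matched_only:  # repair any inversions: consensus must be a tree
        for c in sorted(heights, key=lambda x: -x.bit_count()):
            for d in heights:
                if d & c == d and d != c and heights[d] > heights[c]:
                    heights[d] = heights[c]
    return build_tree(sample.taxa, heights)
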
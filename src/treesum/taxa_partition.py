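"""The taxa-partition (TP) summary tree.

A single-stage method: order the taxa, pool node ages from the whole
sample onto the n−1 boundaries ("splits") between adjacent taxa, and
only then reconstruct a topology from the per-split point estimates —
so ages from competing topologies all inform the result.

Ordering: agglomerative clustering on the mean MRCA-clade-size matrix,
always joining the two closest ordered groups end-to-end in the
orientation that puts the two closest boundary taxa next to each other.

Age pooling: a clade of a sampled tree contributes its age to the split
k exactly when its taxa occupy a contiguous run of order positions, its
children occupy contiguous sub-blocks, and k is the boundary between
those blocks.  (A formal rule allowing every k inside the clade's span
over-counts: each clade age must land on at most one split, the one its
own subdivision marks.)

Reconstruction: the split with the maximal point age becomes the root
(leftmost on ties), recursing left and right.  Because the per-split
estimates are made independently a child's estimate can exceed its
parent's; such children are clamped down to the parent age and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean, median

import numpy as np

from .core import TaxonSet, TimeTree, TreeSample

__all__ = [
    "TaxaOrder",
    "SplitAges",
    "TPResult",
    "pair_distance_matrix",
    "taxa_order",
    "split_ages",
    "tp_tree",
    "taxa_partition_tree",
]

_STATS = {"mean": fmean, "median": median}


@dataclass
class TaxaOrder:
    """A permutation of the taxon set (positions index the splits)."""

    taxa: TaxonSet
    order: tuple[int, ...]  # taxon indices, left to right

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.taxa.labels[i] for i in self.order)


@dataclass
class SplitAges:
    """Per-boundary pooled ages.

    ``values[k-1]`` holds the ages contributed to the boundary between
    order positions k and k+1 (1-based k in 1..n−1); ``fallback[k-1]``
    holds the MRCA ages of the adjacent taxon pair over all trees, used
    when no clade ever contributes to the split.
    """

    values: list[list[float]]
    fallback: list[list[float]]


@dataclass
class TPResult:
    tree: TimeTree
    order: TaxaOrder
    fallback_used: list[int] = field(default_factory=list)
    clamped: int = 0


def pair_distance_matrix(sample: TreeSample) -> np.ndarray:
    """Mean (over trees) size of the MRCA clade of each taxon pair."""
    n = len(sample.taxa)
    acc = np.zeros((n, n))
    for t in sample:
        for c in t.internal_clades():
            size = c.bit_count()
            kids = t.children[c]
            for i in range(len(kids)):
                ai = _positions(kids[i])
                for j in range(i + 1, len(kids)):
                    bj = _positions(kids[j])
                    acc[np.ix_(ai, bj)] += size
                    acc[np.ix_(bj, ai)] += size
    return acc / len(sample)


def _positions(mask: int) -> list[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return out


def taxa_order(matrix: np.ndarray, taxa: TaxonSet) -> TaxaOrder:
    """Order taxa by agglomerative clustering on the pair distances.

    Group distance is the mean of cross-pair distances; joining
    concatenates the two ordered groups in whichever of the four
    end-to-end orientations minimizes the distance between the adjacent
    boundary taxa.  All ties resolve to the lexicographically smallest
    label sequence.
    """
    labels = taxa.labels
    groups: list[tuple[int, ...]] = [(i,) for i in range(len(labels))]
    while len(groups) > 1:
        best = None  # (dist, joined-label-seq, gi, gj, joined)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                d = float(np.mean(matrix[np.ix_(gi, gj)]))
                joined = _orient(gi, gj, matrix, labels)
                key = (d, tuple(labels[x] for x in joined))
                if best is None or key < best[0]:
                    best = (key, i, j, joined)
        _, i, j, joined = best
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(joined)
    return TaxaOrder(taxa, groups[0])


def _orient(g1, g2, matrix, labels):
    cands = []
    for left in (g1, g1[::-1]):
        for right in (g2, g2[::-1]):
            seq = left + right
            boundary = matrix[left[-1], right[0]]
            cands.append((boundary, tuple(labels[x] for x in seq), seq))
    return min(cands)[2]


def split_ages(order: TaxaOrder, sample: TreeSample) -> SplitAges:
    """Pool clade ages from the sample onto the boundaries of ``order``."""
    n = len(order.taxa)
    pos = {t: p for p, t in enumerate(order.order)}  # taxon index -> position
    values: list[list[float]] = [[] for _ in range(n - 1)]
    for t in sample:
        for c in t.internal_clades():
            ps = sorted(pos[i] for i in _positions(c))
            if ps[-1] - ps[0] + 1 != len(ps):
                continue  # clade not contiguous in this ordering
            blocks = []
            ok = True
            for ch in t.children[c]:
                cps = sorted(pos[i] for i in _positions(ch))
                if cps[-1] - cps[0] + 1 != len(cps):
                    ok = False
                    break
                blocks.append((cps[0], cps[-1]))
            if not ok:
                continue
            blocks.sort()
            for _, end in blocks[:-1]:  # boundary after each non-last block
                values[end].append(t.ages[c])
    fallback = [
        [t.mrca_age((1 << order.order[k]) | (1 << order.order[k + 1]))
         for t in sample]
        for k in range(n - 1)
    ]
    return SplitAges(values, fallback)


def tp_tree(order: TaxaOrder, splits: SplitAges, stat: str = "median") -> TPResult:
    """Reconstruct the summary tree from per-split point estimates."""
    agg = _STATS[stat]
    n = len(order.taxa)
    points = []
    fallback_used = []
    for k in range(n - 1):
        if splits.values[k]:
            points.append(agg(splits.values[k]))
        else:
            points.append(agg(splits.fallback[k]))
            fallback_used.append(k + 1)
    ages: dict[int, float] = {}
    clamped = 0

    def build(lo: int, hi: int, cap: float) -> int:
        """Clade for order positions [lo, hi); returns its bitmask."""
        nonlocal clamped
        mask = 0
        for p in range(lo, hi):
            mask |= 1 << order.order[p]
        if hi - lo == 1:
            ages[mask] = 0.0
            return mask
        k = lo + int(np.argmax(points[lo:hi - 1]))  # leftmost maximal split
        age = points[k]
        if age > cap:
            age = cap
            clamped += 1
        ages[mask] = age
        build(lo, k + 1, age)
        build(k + 1, hi, age)
        return mask

    build(0, n, float("inf"))
    return TPResult(TimeTree(order.taxa, ages), order, fallback_used, clamped)


def taxa_partition_tree(sample: TreeSample, stat: str = "median") -> TPResult:
    """Full TP pipeline: distance matrix → ordering → split ages → tree."""
    order = taxa_order(pair_distance_matrix(sample), sample.taxa)
    return tp_tree(order, split_ages(order, sample), stat)
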
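"""Distances between rooted time trees, and fast mean distance to a tree set.

Four pairwise scores are provided.  All treat a clade present in only one
of the two trees as having a zero-length branch in the other, so private
clades contribute their whole branch:

* ``rbs``  — rooted branch score: sum over the clade union of absolute
  branch-length differences.  A metric.
* ``srbs`` — squared rooted branch score: squared differences instead of
  absolute ones.  Not a metric.
* ``hs``   — heights score: absolute clade-age differences over shared
  clades, plus the private-branch penalty.  Not a metric.
* ``ras``  — rooted agreement score: branches compared as age intervals
  [h, h+b] via the measure of their symmetric difference, plus the
  private-branch penalty.  A metric.
* ``hs_matched`` — the shared-clade heights term of ``hs`` alone (no
  private penalty); the "heights only" objective used by the HSO summary
  method.  The exact objective of that method is not published; this is
  the reading documented in the methods note.

The mean distance of a tree ``T`` to a whole sample is evaluated in
O(|clades| log |sample|) through a :class:`CladeIndex`: the pairwise sums
are regrouped into per-clade sums over the sample, whose data-dependent
parts (sorted matched branch lengths / ages / interval endpoints with
prefix sums) are precomputed once, leaving a binary search per clade per
evaluation.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .core import TimeTree, TreeSample, TreeError

__all__ = [
    "METRICS",
    "rbs",
    "srbs",
    "hs",
    "ras",
    "hs_matched",
    "tree_distance",
    "interval_symdiff",
    "CladeIndex",
    "build_clade_index",
    "set_distance",
]

METRICS = ("rbs", "srbs", "hs", "ras", "hs_matched")


def _check_taxa(t1: TimeTree, t2: TimeTree) -> None:
    if t1.taxa != t2.taxa:
        raise TreeError("trees are on different taxon sets")


def rbs(t1: TimeTree, t2: TimeTree) -> float:
    """Rooted branch score: Σ over the clade union of |b1(c) − b2(c)|."""
    _check_taxa(t1, t2)
    return sum(
        abs(t1.branch_length(c) - t2.branch_length(c))
        for c in t1.ages.keys() | t2.ages.keys()
    )


def srbs(t1: TimeTree, t2: TimeTree) -> float:
    """Squared rooted branch score: Σ over the union of (b1 − b2)²."""
    _check_taxa(t1, t2)
    return sum(
        (t1.branch_length(c) - t2.branch_length(c)) ** 2
        for c in t1.ages.keys() | t2.ages.keys()
    )


def hs(t1: TimeTree, t2: TimeTree) -> float:
    """Heights score: shared-clade |Δ age| plus private branch lengths."""
    _check_taxa(t1, t2)
    total = 0.0
    for c in t1.ages:
        if c in t2.ages:
            total += abs(t1.ages[c] - t2.ages[c])
        else:
            total += t1.branch_length(c)
    for c in t2.ages:
        if c not in t1.ages:
            total += t2.branch_length(c)
    return total


def hs_matched(t1: TimeTree, t2: TimeTree) -> float:
    """Shared-clade heights term only (the HSO objective)."""
    _check_taxa(t1, t2)
    return sum(
        abs(t1.ages[c] - t2.ages[c]) for c in t1.ages.keys() & t2.ages.keys()
    )


def interval_symdiff(i1: tuple[float, float], i2: tuple[float, float]) -> float:
    """Measure of the symmetric difference of two closed intervals."""
    l1, h1 = i1
    l2, h2 = i2
    if h1 < l1 or h2 < l2:
        raise ValueError("malformed interval (low > high)")
    return (h1 - l1) + (h2 - l2) - 2.0 * max(min(h1, h2) - max(l1, l2), 0.0)


def ras(t1: TimeTree, t2: TimeTree) -> float:
    """Rooted agreement score: branch intervals compared by symmetric
    difference over shared clades, plus private branch lengths."""
    _check_taxa(t1, t2)
    total = 0.0
    for c in t1.ages:
        b1 = t1.branch_length(c)
        if c in t2.ages:
            b2 = t2.branch_length(c)
            total += interval_symdiff(
                (t1.ages[c], t1.ages[c] + b1), (t2.ages[c], t2.ages[c] + b2)
            )
        else:
            total += b1
    for c in t2.ages:
        if c not in t1.ages:
            total += t2.branch_length(c)
    return total


_PAIRWISE = {"rbs": rbs, "srbs": srbs, "hs": hs, "ras": ras,
             "hs_matched": hs_matched}


def tree_distance(t1: TimeTree, t2: TimeTree, metric: str) -> float:
    return _PAIRWISE[metric](t1, t2)


# ---------------------------------------------------------------------------
# Clade index: per-clade sorted matched values with prefix sums.

def _prefix(a: np.ndarray) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(a)))


@dataclass
class _CladeStats:
    """Matched values for one observed clade, pre-sorted for binary search."""

    n: int = 0
    b_sorted: np.ndarray = field(default_factory=lambda: np.empty(0))
    b_pref: np.ndarray = field(default_factory=lambda: np.zeros(1))
    h_sorted: np.ndarray = field(default_factory=lambda: np.empty(0))
    h_pref: np.ndarray = field(default_factory=lambda: np.zeros(1))
    lo_sorted: np.ndarray = field(default_factory=lambda: np.empty(0))
    lo_pref: np.ndarray = field(default_factory=lambda: np.zeros(1))
    hi_sorted: np.ndarray = field(default_factory=lambda: np.empty(0))
    hi_pref: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sum_b: float = 0.0
    sum_b2: float = 0.0
    sum_h: float = 0.0
    # plain-list mirrors for the scalar (bisect) fast path
    b_l: list = field(default_factory=list)
    bp_l: list = field(default_factory=lambda: [0.0])
    h_l: list = field(default_factory=list)
    hp_l: list = field(default_factory=lambda: [0.0])
    lo_l: list = field(default_factory=list)
    lop_l: list = field(default_factory=lambda: [0.0])
    hi_l: list = field(default_factory=list)
    hip_l: list = field(default_factory=lambda: [0.0])


def _abs_dev(sorted_v, pref, sum_v, n, x):
    """Σ_i |x − v_i|, vectorized over x."""
    m = np.searchsorted(sorted_v, x, side="right")
    return x * (2.0 * m - n) - 2.0 * pref[m] + sum_v


def _abs_dev_grad(sorted_v, n, x):
    """One-sided (from below) derivative of Σ|x − v_i|."""
    return 2.0 * np.searchsorted(sorted_v, x, side="left") - n


def _cum_min_sum(sorted_v, pref, n, t):
    """Σ_i min(t, v_i), vectorized over t."""
    m = np.searchsorted(sorted_v, t, side="right")
    return pref[m] + t * (n - m)


def _cum_count_below(sorted_v, n, t):
    """One-sided derivative of Σ min(t, v_i): #{v_i ≥ t}."""
    return n - np.searchsorted(sorted_v, t, side="left")


class CladeIndex:
    """Preprocessed tree sample enabling O(|ℂ| log k) mean-distance queries.

    Built by :func:`build_clade_index`.  Holds, per clade ever observed in
    the sample, the sorted matched branch lengths, clade ages and branch
    interval endpoints with prefix sums, plus the sample-wide constants
    (total branch length / squared length) of the per-clade expansion of
    the pairwise sums.
    """

    def __init__(self, sample: TreeSample, metric: str):
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        self.metric = metric
        self.taxa = sample.taxa
        self.size = len(sample)
        self.root = sample.taxa.full_mask

        raw_b: dict[int, list[float]] = {}
        raw_h: dict[int, list[float]] = {}
        raw_hi: dict[int, list[float]] = {}
        total_b = 0.0
        total_b2 = 0.0
        for t in sample:
            for c, h in t.ages.items():
                b = t.branch_length(c)
                raw_b.setdefault(c, []).append(b)
                raw_h.setdefault(c, []).append(h)
                raw_hi.setdefault(c, []).append(h + b)
                total_b += b
                total_b2 += b * b
        self.total_branch = total_b
        self.total_branch_sq = total_b2

        self.stats: dict[int, _CladeStats] = {}
        for c, bs in raw_b.items():
            st = _CladeStats()
            st.n = len(bs)
            st.b_sorted = np.sort(np.asarray(bs))
            st.b_pref = _prefix(st.b_sorted)
            st.sum_b = float(st.b_pref[-1])
            st.sum_b2 = float(np.sum(st.b_sorted**2))
            st.h_sorted = np.sort(np.asarray(raw_h[c]))
            st.h_pref = _prefix(st.h_sorted)
            st.lo_sorted = st.h_sorted  # interval low = clade age
            st.lo_pref = st.h_pref
            st.hi_sorted = np.sort(np.asarray(raw_hi[c]))
            st.hi_pref = _prefix(st.hi_sorted)
            st.sum_h = float(st.h_pref[-1])
            st.b_l, st.bp_l = st.b_sorted.tolist(), st.b_pref.tolist()
            st.h_l, st.hp_l = st.h_sorted.tolist(), st.h_pref.tolist()
            st.lo_l, st.lop_l = st.h_l, st.hp_l
            st.hi_l, st.hip_l = st.hi_sorted.tolist(), st.hi_pref.tolist()
            self.stats[c] = st
        self._empty = _CladeStats()

    # -- per-clade terms, vectorized over the age arguments --------------
    def clade_term(self, clade: int, low, high, grad: bool = False):
        """Sample-summed contribution of one non-root clade of the scored
        tree with age ``low`` and parent age ``high``.

        Returns the summed term, or ``(term, d/dlow, d/dhigh)`` with
        one-sided (from below) derivatives at the L1 kinks when ``grad``.
        Accepts scalars or broadcastable numpy arrays.
        """
        st = self.stats.get(clade, self._empty)
        k, n = self.size, st.n
        x = np.asarray(high) - np.asarray(low)
        m = self.metric
        if m == "rbs":
            term = _abs_dev(st.b_sorted, st.b_pref, st.sum_b, n, x) + x * (k - n)
            if not grad:
                return term
            dx = _abs_dev_grad(st.b_sorted, n, x) + (k - n)
            return term, -dx, dx
        if m == "srbs":
            term = k * x**2 - 2.0 * x * st.sum_b + st.sum_b2
            if not grad:
                return term
            dx = 2.0 * k * x - 2.0 * st.sum_b
            return term, -dx, dx
        if m == "hs":
            term = (
                _abs_dev(st.h_sorted, st.h_pref, float(st.h_pref[-1]), n, low)
                + x * (k - n)
            )
            if not grad:
                return term
            dlow = _abs_dev_grad(st.h_sorted, n, low) - (k - n)
            return term, dlow, np.broadcast_to(float(k - n), np.shape(term))
        if m == "hs_matched":
            term = _abs_dev(st.h_sorted, st.h_pref, float(st.h_pref[-1]), n, low)
            if not grad:
                return term
            return term, _abs_dev_grad(st.h_sorted, n, low), np.zeros(np.shape(term))
        # ras
        f_hi = _cum_min_sum(st.hi_sorted, st.hi_pref, n, high) - _cum_min_sum(
            st.lo_sorted, st.lo_pref, n, high
        )
        f_lo = _cum_min_sum(st.hi_sorted, st.hi_pref, n, low) - _cum_min_sum(
            st.lo_sorted, st.lo_pref, n, low
        )
        term = st.sum_b + n * x - 2.0 * (f_hi - f_lo) + x * (k - n)
        if not grad:
            return term
        dhi = k - 2.0 * (
            _cum_count_below(st.hi_sorted, n, high)
            - _cum_count_below(st.lo_sorted, n, high)
        )
        dlo = (
            2.0
            * (
                _cum_count_below(st.hi_sorted, n, low)
                - _cum_count_below(st.lo_sorted, n, low)
            )
            - k
        )
        return term, dlo, dhi

    def clade_term_scalar(self, clade: int, low: float, high: float,
                          grad: bool = False):
        """Scalar twin of :meth:`clade_term` (bisect instead of numpy —
        the optimizer's inner loop)."""
        st = self.stats.get(clade, self._empty)
        k, n = self.size, st.n
        x = high - low
        m = self.metric
        if m == "rbs":
            j = bisect_right(st.b_l, x)
            term = x * (2 * j - n) - 2 * st.bp_l[j] + st.sum_b + x * (k - n)
            if not grad:
                return term
            dx = 2 * bisect_left(st.b_l, x) - n + (k - n)
            return term, -dx, dx
        if m == "srbs":
            term = k * x * x - 2 * x * st.sum_b + st.sum_b2
            if not grad:
                return term
            dx = 2 * k * x - 2 * st.sum_b
            return term, -dx, dx
        if m in ("hs", "hs_matched"):
            j = bisect_right(st.h_l, low)
            term = low * (2 * j - n) - 2 * st.hp_l[j] + st.sum_h
            if m == "hs":
                term += x * (k - n)
            if not grad:
                return term
            dlow = 2 * bisect_left(st.h_l, low) - n
            if m == "hs_matched":
                return term, dlow, 0.0
            return term, dlow - (k - n), float(k - n)
        # ras
        def F(t):
            j = bisect_right(st.hi_l, t)
            s = st.hip_l[j] + t * (n - j)
            j = bisect_right(st.lo_l, t)
            return s - (st.lop_l[j] + t * (n - j))
        term = st.sum_b + n * x - 2.0 * (F(high) - F(low)) + x * (k - n)
        if not grad:
            return term

        def dF(t):
            return (n - bisect_left(st.hi_l, t)) - (n - bisect_left(st.lo_l, t))
        return term, 2.0 * dF(low) - k, k - 2.0 * dF(high)

    def root_term(self, root_age, grad: bool = False):
        """Root contribution (hs/hs_matched age term; zero otherwise)."""
        if self.metric in ("hs", "hs_matched"):
            st = self.stats[self.root]
            if isinstance(root_age, float):
                j = bisect_right(st.h_l, root_age)
                term = root_age * (2 * j - st.n) - 2 * st.hp_l[j] + st.sum_h
                if not grad:
                    return term
                return term, float(2 * bisect_left(st.h_l, root_age) - st.n)
            term = _abs_dev(
                st.h_sorted, st.h_pref, float(st.h_pref[-1]), st.n, root_age
            )
            if not grad:
                return term
            return term, _abs_dev_grad(st.h_sorted, st.n, root_age)
        z = np.zeros(np.shape(np.asarray(root_age)))
        return (z, z.copy()) if grad else z

    def residual(self, clades) -> float:
        """Sample branches never matched by the scored tree's clades."""
        if self.metric == "hs_matched":
            return 0.0
        r = self.root
        if self.metric == "srbs":
            return self.total_branch_sq - sum(
                self.stats[c].sum_b2 for c in clades if c in self.stats and c != r
            )
        return self.total_branch - sum(
            self.stats[c].sum_b for c in clades if c in self.stats and c != r
        )

    def frequency(self, clade: int) -> float:
        st = self.stats.get(clade)
        return st.n / self.size if st else 0.0


def build_clade_index(sample: TreeSample, metric: str) -> CladeIndex:
    """Preprocess a tree sample for fast mean-distance evaluation."""
    return CladeIndex(sample, metric)


def set_distance(tree: TimeTree, index: CladeIndex) -> float:
    """Mean distance of ``tree`` to every tree of the indexed sample.

    Equals ``mean(tree_distance(tree, t_i, metric))`` exactly (up to
    floating-point round-off) but costs O(|ℂ| log k).
    """
    if tree.taxa != index.taxa:
        raise TreeError("tree taxa do not match the index")
    total = index.residual(tree.ages.keys())
    total += float(index.root_term(tree.root_height))
    for c in tree.ages:
        if c == tree.root:
            continue
        p = tree.parent[c]
        total += float(index.clade_term(c, tree.ages[c], tree.ages[p]))
    return total / index.size
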
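"""Minimum mean-distance summary trees.

For a fixed topology the tree is encoded as a point z = (h_r, α_2 … α_m):
the root height plus, for every other internal clade (in a fixed
pre-order), the ratio of its age to its parent's age.  Every coordinate
has a simple bound (h_r ≥ 0, α ∈ [0, 1]), every decoded point is a valid
tree by construction, and the mean distance to the sample — evaluated
through the :class:`~treesum.distances.CladeIndex` — is minimized with
bounded L-BFGS-B using exact analytic gradients (one-sided from below at
the L1 kinks of rbs/hs/ras).

The search over topologies is restricted to those present in the sample.
Sampled trees themselves are always evaluated as candidates, so the
returned tree is never worse (in mean distance) than any sampled tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import TaxonSet, TimeTree, TreeSample, TreeError
from .distances import CladeIndex, build_clade_index, set_distance
from .topology_selection import select_mcc, select_tcb

__all__ = [
    "ParamVector",
    "OptimizerOptions",
    "Topology",
    "encode",
    "decode",
    "objective",
    "init_tree",
    "optimize_fixed_topology",
    "min_distance_tree",
]


@dataclass
class OptimizerOptions:
    gradient_tolerance: float = 1e-9
    max_iterations: int = 500
    restarts: int = 16
    seed: int = 0
    max_topologies: int = 1024

    def __post_init__(self):
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")


class Topology:
    """A clade hierarchy with a fixed pre-order over internal clades."""

    def __init__(self, taxa: TaxonSet, clades: Iterable[int]):
        self.taxa = taxa
        full = taxa.full_mask
        cs = {c for c in clades if c.bit_count() > 1}
        cs.add(full)
        allc = sorted(cs) + [1 << i for i in range(len(taxa))]
        # parent = minimal proper superset
        by_size = sorted(allc, key=lambda c: c.bit_count())
        parent: dict[int, int] = {}
        for i, c in enumerate(by_size[:-1]):
            for p in by_size[i + 1:]:
                if c & p == c and p != c:
                    parent[c] = p
                    break
        children: dict[int, list[int]] = {c: [] for c in allc}
        for c, p in parent.items():
            children[p].append(c)
        for p in children:
            children[p].sort()
        # pre-order over internal clades (root first, deterministic)
        self.internal: list[int] = []
        stack = [full]
        while stack:
            c = stack.pop()
            self.internal.append(c)
            for ch in reversed(children[c]):
                if ch.bit_count() > 1:
                    stack.append(ch)
        self.pos = {c: i for i, c in enumerate(self.internal)}
        self.parent = parent
        self.children = children
        #: parent position (into ``internal``) of each non-root internal clade
        self.parent_pos = np.array(
            [self.pos[parent[c]] for c in self.internal[1:]], dtype=int
        )
        self.tips = [1 << i for i in range(len(taxa))]
        self.tip_parent_pos = np.array(
            [self.pos[parent[t]] for t in self.tips], dtype=int
        )

    @classmethod
    def of(cls, taxa: TaxonSet, source) -> "Topology":
        if isinstance(source, Topology):
            return source
        if isinstance(source, TimeTree):
            return cls(source.taxa, source.ages.keys())
        return cls(taxa, source)

    @property
    def m(self) -> int:
        """Number of internal clades (the dimension of the encoding)."""
        return len(self.internal)

    def ages_from(self, z: np.ndarray) -> np.ndarray:
        """Internal ages (pre-order) from (root height, ratios)."""
        h = np.empty(self.m)
        h[0] = z[0]
        for i in range(1, self.m):
            h[i] = z[i] * h[self.parent_pos[i - 1]]
        return h

    def tree_from_ages(self, h: Sequence[float]) -> TimeTree:
        ages = {c: float(h[i]) for i, c in enumerate(self.internal)}
        for t in self.tips:
            ages[t] = 0.0
        return TimeTree(self.taxa, ages)


@dataclass
class ParamVector:
    """(root height, per-clade age/parent-age ratios) for one topology."""

    topology: Topology
    z: np.ndarray  # length m: [h_r, α_2, …, α_m]

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.topology.m,):
            raise ValueError("parameter dimension does not match topology")
        if self.z[0] < 0:
            raise ValueError("negative root height")
        if np.any(self.z[1:] < -1e-12) or np.any(self.z[1:] > 1 + 1e-12):
            raise ValueError("ratio outside [0, 1]")


def encode(tree: TimeTree) -> ParamVector:
    """Represent a tree as root height plus age ratios (exact inverse of
    :func:`decode` for positive ancestor ages)."""
    topo = Topology.of(tree.taxa, tree)
    z = np.empty(topo.m)
    z[0] = tree.root_height
    for i, c in enumerate(topo.internal[1:], start=1):
        hp = tree.ages[topo.internal[topo.parent_pos[i - 1]]]
        z[i] = tree.ages[c] / hp if hp > 0 else 0.0
    return ParamVector(topo, z)


def decode(pv: ParamVector) -> TimeTree:
    """Rebuild the tree: each clade's age is the root height times the
    product of the ratios along its ancestor path."""
    h = pv.topology.ages_from(np.clip(pv.z, 0.0, None))
    return pv.topology.tree_from_ages(h)


# ---------------------------------------------------------------------------
# Objective with analytic gradient

def _value_grad(topo: Topology, z: np.ndarray, index: CladeIndex,
                residual: float | None = None):
    k = index.size
    h = topo.ages_from(z)
    g = np.zeros(topo.m)  # ∂(total)/∂h_i
    total = (
        residual
        if residual is not None
        else index.residual(set(topo.internal) | set(topo.tips))
    )
    rt, drt = index.root_term(float(h[0]), grad=True)
    total += float(rt)
    g[0] += float(drt)
    for i, c in enumerate(topo.internal[1:], start=1):
        p = topo.parent_pos[i - 1]
        term, dlo, dhi = index.clade_term_scalar(
            c, float(h[i]), float(h[p]), grad=True
        )
        total += term
        g[i] += dlo
        g[p] += dhi
    for t, p in zip(topo.tips, topo.tip_parent_pos):
        term, _dlo, dhi = index.clade_term_scalar(
            t, 0.0, float(h[p]), grad=True
        )
        total += term
        g[p] += dhi
    # adjoint pass: fold per-age gradients back onto (h_r, ratios)
    dz = np.zeros(topo.m)
    a = g.copy()
    for i in range(topo.m - 1, 0, -1):
        p = topo.parent_pos[i - 1]
        dz[i] = h[p] * a[i]
        a[p] += z[i] * a[i]
    dz[0] = a[0]
    return total / k, dz / k


def objective(pv: ParamVector, index: CladeIndex):
    """Mean distance of the decoded tree to the indexed sample, with its
    exact gradient w.r.t. (root height, ratios).

    The value equals ``set_distance(decode(pv), index)``; at the kinks of
    the L1-type metrics the gradient is the one-sided derivative from
    below.
    """
    return _value_grad(pv.topology, pv.z, index)


# ---------------------------------------------------------------------------
# Initialization

def _padded_branch_stat(index: CladeIndex, clade: int, metric: str) -> float:
    """Optimal isolated branch length: the minimizer of the clade's own
    term with the (k − n) absent trees contributing zero-length branches —
    the median of the zero-padded matched branches for the L1-type
    metrics, their mean for srbs."""
    st = index.stats.get(clade)
    k = index.size
    if st is None:
        return 0.0
    if metric == "srbs":
        return st.sum_b / k
    zeros = k - st.n
    vals = st.b_sorted
    # median of [0]*zeros + sorted matched values, even count -> midpoint
    def at(i: int) -> float:
        return 0.0 if i < zeros else float(vals[i - zeros])
    if k % 2:
        return at(k // 2)
    return 0.5 * (at(k // 2 - 1) + at(k // 2))


def init_tree(topology, index: CladeIndex) -> TimeTree:
    """Starting tree: per-branch optima combined post-order.

    Each branch first gets its isolated optimum; then ages are assigned
    children-first, a clade's age being the mean over its children of
    (child age + child's optimal branch), floored at the maximum child
    age so the result is always a valid tree.
    """
    topo = Topology.of(index.taxa, topology)
    metric = index.metric
    bstar = {
        c: _padded_branch_stat(index, c, metric)
        for c in topo.internal[1:] + topo.tips
    }
    ages: dict[int, float] = {t: 0.0 for t in topo.tips}
    for c in reversed(topo.internal):  # post-order
        kids = topo.children[c]
        est = sum(ages[ch] + bstar[ch] for ch in kids) / len(kids)
        ages[c] = max(est, max(ages[ch] for ch in kids))
    return topo.tree_from_ages([ages[c] for c in topo.internal])


# ---------------------------------------------------------------------------
# Optimization

def optimize_fixed_topology(
    topology,
    sample: TreeSample | CladeIndex,
    metric: str | None = None,
    opts: OptimizerOptions | None = None,
) -> TimeTree:
    """Best height assignment for one topology under one metric.

    Bounded quasi-Newton (L-BFGS-B) descent from the per-branch
    initialization, plus seeded random restarts; the returned tree's mean
    distance never exceeds the initial tree's.  Deterministic given
    ``opts.seed``.
    """
    opts = opts or OptimizerOptions()
    index = (
        sample
        if isinstance(sample, CladeIndex)
        else build_clade_index(sample, metric or "rbs")
    )
    topo = Topology.of(index.taxa, topology)
    start = init_tree(topo, index)
    if start.root_height == 0.0:  # degenerate flat sample
        return start
    residual = index.residual(set(topo.internal) | set(topo.tips))
    fun = lambda z: _value_grad(topo, z, index, residual)  # noqa: E731
    best_tree = start
    best_val, _ = fun(encode(start).z)

    max_root = max(
        float(index.stats[index.root].h_sorted[-1]), start.root_height
    )
    bounds = [(0.0, None)] + [(0.0, 1.0)] * (topo.m - 1)
    rng = np.random.default_rng(opts.seed)
    starts = [encode(start).z]
    if opts.restarts > 0:
        # local minima can be plentiful and far apart; screen a cheap
        # randomized pool (squared-uniform root to reach tiny heights)
        # and descend from the most promising points
        pool = max(48 * opts.restarts, 8 * topo.m)
        cand = np.empty((pool, topo.m))
        cand[:, 0] = 1.5 * max_root * rng.uniform(0.0, 1.0, pool) ** 2
        # U-shaped ratio proposals: minima often sit near collapsed
        # (α≈1) or root-hugging (α≈0) configurations
        cand[:, 1:] = rng.beta(0.3, 0.3, (pool, topo.m - 1))
        vals = np.array([fun(z)[0] for z in cand])
        starts.extend(cand[np.argsort(vals)[: opts.restarts]])
    cand_best = None
    cand_val = np.inf
    for z0 in starts:
        res = minimize(
            fun,
            z0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.max_iterations,
                "gtol": opts.gradient_tolerance,
                "ftol": 1e-14,
            },
        )
        if res.fun < cand_val:
            cand_val = res.fun
            cand_best = res.x
    if cand_best is not None and index.metric != "srbs":
        # the L1-type objectives are piecewise linear; a quasi-Newton step
        # can stall on a kink, so polish the best endpoint with a bounded
        # derivative-free direction-set search
        res2 = minimize(
            lambda z: fun(z)[0],
            cand_best,
            method="Powell",
            bounds=bounds,
            options={"maxiter": 20, "xtol": 1e-10, "ftol": 1e-12},
        )
        if res2.fun < cand_val:
            cand_val = res2.fun
            cand_best = res2.x
    if cand_best is not None:
        z = np.clip(cand_best, 0.0, None)
        z[1:] = np.clip(z[1:], 0.0, 1.0)
        val, _ = fun(z)
        if val < best_val - 1e-15:
            best_tree = topo.tree_from_ages(topo.ages_from(z))
    return best_tree


def min_distance_tree(
    sample: TreeSample,
    metric: str,
    topology_source="all_sampled",
    opts: OptimizerOptions | None = None,
) -> TimeTree:
    """Summary tree minimizing the mean distance to the sample.

    ``topology_source`` is ``"all_sampled"`` (optimize every distinct
    sampled topology — the mRBS/mSRBS/mRAS/mHS family), ``"mcc"`` or
    ``"tcb"`` (single selected topology), or an explicit list of
    topologies.  Sampled trees are always candidates too, so the result
    is at least as close to the sample as the best sampled tree; ties go
    to the first candidate found (sampled trees first).
    """
    opts = opts or OptimizerOptions()
    index = build_clade_index(sample, metric)

    best_tree: TimeTree | None = None
    best_val = np.inf
    for t in sample:  # sampled trees as-is are candidates
        val = set_distance(t, index)
        if val < best_val - 1e-15:
            best_val = val
            best_tree = t

    if topology_source == "all_sampled":
        order: dict[frozenset, int] = {}
        for t in sample:
            key = t.topology_key()
            order[key] = order.get(key, 0) + 1
        keys = sorted(order, key=lambda k: -order[k])
        if len(keys) > opts.max_topologies:
            import warnings

            warnings.warn(
                f"topology search truncated to the {opts.max_topologies} "
                f"most frequent of {len(keys)} distinct sampled topologies"
            )
            keys = keys[: opts.max_topologies]
        topologies = [Topology.of(sample.taxa, set(k)) for k in keys]
    elif topology_source == "mcc":
        topologies = [Topology.of(sample.taxa, sample[select_mcc(sample)])]
    elif topology_source == "tcb":
        topologies = [Topology.of(sample.taxa, sample[select_tcb(sample)])]
    else:
        topologies = [Topology.of(sample.taxa, t) for t in topology_source]

    for topo in topologies:
        cand = optimize_fixed_topology(topo, index, opts=opts)
        val = set_distance(cand, index)
        if val < best_val - 1e-15:
            best_val = val
            best_tree = cand
    assert best_tree is not None
    return best_tree
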
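"""Rooted time trees as hierarchies of aged clades.

A tree on taxa ``L`` is represented as the pair (set of clades, age per
clade).  A clade is a subset of taxa stored as an integer bitmask over a
fixed taxon ordering (:class:`TaxonSet`), so clade identity, nesting and
disjointness are plain bit operations and clades match across trees in
O(1).  A valid tree contains every singleton, the full set (the root),
forms a strict hierarchy (any two clades are nested or disjoint) and has
non-decreasing ages root-ward.  Tips are contemporaneous at age 0.
"""

from __future__ import annotations

import itertools
from functools import cached_property
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxonSet",
    "TimeTree",
    "TreeSample",
    "TreeError",
    "build_tree",
    "mrca_age",
    "branch_length",
    "pairs_splitting_at",
    "divergence_time",
]

#: absolute tolerance for age-order validation; smaller violations are clamped
AGE_TOL = 1e-9


class TreeError(ValueError):
    """Raised when input does not form a valid rooted time tree."""


class TaxonSet:
    """An ordered set of unique taxon labels defining the bitmask layout."""

    __slots__ = ("labels", "index")

    def __init__(self, labels: Iterable[str]):
        self.labels: tuple[str, ...] = tuple(labels)
        if not self.labels:
            raise TreeError("taxon set must not be empty")
        self.index: dict[str, int] = {x: i for i, x in enumerate(self.labels)}
        if len(self.index) != len(self.labels):
            raise TreeError("duplicate taxon labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def clade(self, members: Iterable[str]) -> int:
        """Bitmask of the clade containing the given labels."""
        m = 0
        for x in members:
            m |= 1 << self.index[x]
        return m

    def members(self, clade: int) -> tuple[str, ...]:
        """Labels contained in a clade bitmask, in taxon order."""
        return tuple(x for i, x in enumerate(self.labels) if clade >> i & 1)


def _nested_or_disjoint(a: int, b: int) -> bool:
    i = a & b
    return i == 0 or i == a or i == b


class TimeTree:
    """A rooted ultrametric tree: aged clades over a :class:`TaxonSet`.

    Construct through :func:`build_tree` (which validates); the raw
    constructor trusts its input.  ``ages`` maps every clade bitmask —
    singletons, internal clades and the root — to its age.
    """

    def __init__(self, taxa: TaxonSet, ages: Mapping[int, float]):
        self.taxa = taxa
        self.ages: dict[int, float] = dict(ages)

    # -- basic accessors -------------------------------------------------
    @property
    def root(self) -> int:
        return self.taxa.full_mask

    @property
    def root_height(self) -> float:
        return self.ages[self.root]

    def __contains__(self, clade: int) -> bool:
        return clade in self.ages

    def clades(self) -> Iterable[int]:
        return self.ages.keys()

    def internal_clades(self) -> list[int]:
        """All non-singleton clades (the root included)."""
        return [c for c in self.ages if c.bit_count() > 1]

    def nontrivial_clades(self) -> list[int]:
        """Internal clades excluding the root."""
        r = self.root
        return [c for c in self.ages if c.bit_count() > 1 and c != r]

    @cached_property
    def parent(self) -> dict[int, int]:
        """Minimal proper superset for every non-root clade."""
        by_size = sorted(self.ages, key=lambda c: c.bit_count())
        par: dict[int, int] = {}
        for i, c in enumerate(by_size[:-1]):
            for p in by_size[i + 1:]:
                if c & p == c and p != c:
                    par[c] = p
                    break
        return par

    @cached_property
    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {c: [] for c in self.ages}
        for c, p in self.parent.items():
            ch[p].append(c)
        return ch

    def branch_length(self, subset: int) -> float:
        """Parent age minus clade age; 0 for the root and for non-clades."""
        if subset not in self.ages:
            if subset == 0:
                raise TreeError("empty subset")
            return 0.0
        p = self.parent.get(subset)
        if p is None:
            return 0.0
        return self.ages[p] - self.ages[subset]

    def total_length(self) -> float:
        return sum(self.branch_length(c) for c in self.ages)

    def mrca(self, subset: int) -> int:
        """Minimal clade containing ``subset`` (descends from the root)."""
        if subset == 0:
            raise TreeError("empty subset")
        if subset & ~self.root:
            raise TreeError("subset contains unknown taxa")
        cur = self.root
        while True:
            for ch in self.children[cur]:
                if subset & ch == subset:
                    cur = ch
                    break
            else:
                return cur

    def mrca_age(self, subset: int) -> float:
        return self.ages[self.mrca(subset)]

    def topology_key(self) -> frozenset[int]:
        """Hashable topology identity: the set of non-trivial clades."""
        return frozenset(self.nontrivial_clades())

    # -- misc ------------------------------------------------------------
    def copy(self) -> "TimeTree":
        return TimeTree(self.taxa, self.ages)

    def equals(self, other: "TimeTree", tol: float = 1e-9) -> bool:
        """Same taxa, same clades, ages within ``tol``."""
        if self.taxa != other.taxa or self.ages.keys() != other.ages.keys():
            return False
        return all(abs(a - other.ages[c]) <= tol for c, a in self.ages.items())

    def __repr__(self) -> str:
        n = len(self.taxa)
        return f"<TimeTree n={n} root_height={self.root_height:.6g}>"


def build_tree(
    taxa: TaxonSet,
    aged_clades: Iterable[tuple[int, float]] | Mapping[int, float],
) -> TimeTree:
    """Validate and build a :class:`TimeTree`.

    ``aged_clades`` must list the root and every internal clade; singletons
    may be omitted and are implied at age 0.

    Raises :class:`TreeError` on: clades that overlap without nesting,
    a child older than its parent (beyond tolerance), negative ages, a
    missing root, or a singleton at a non-zero age.
    """
    items = aged_clades.items() if isinstance(aged_clades, Mapping) else aged_clades
    ages: dict[int, float] = {}
    full = taxa.full_mask
    for clade, age in items:
        if clade == 0:
            raise TreeError("empty clade")
        if clade & ~full:
            raise TreeError("clade contains taxa outside the taxon set")
        if age < 0:
            raise TreeError(f"negative age {age}")
        if clade.bit_count() == 1 and abs(age) > AGE_TOL:
            raise TreeError("tips must be contemporaneous at age 0")
        ages[clade] = float(age)
    for i in range(len(taxa)):
        ages.setdefault(1 << i, 0.0)
    if full not in ages:
        raise TreeError("missing root clade")

    clades = sorted(ages, key=lambda c: c.bit_count())
    for a, b in itertools.combinations(clades, 2):
        if not _nested_or_disjoint(a, b):
            raise TreeError(
                f"clades {taxa.members(a)} and {taxa.members(b)} overlap "
                "without nesting"
            )
    tree = TimeTree(taxa, ages)
    for c, p in tree.parent.items():
        if tree.ages[c] > tree.ages[p] + AGE_TOL:
            raise TreeError(
                f"clade {taxa.members(c)} (age {tree.ages[c]}) is older than "
                f"its parent {taxa.members(p)} (age {tree.ages[p]})"
            )
        if tree.ages[c] > tree.ages[p]:  # within tolerance: clamp to order
            tree.ages[c] = tree.ages[p]
    return tree


class TreeSample:
    """An ordered collection of trees on one shared taxon set."""

    def __init__(self, taxa: TaxonSet, trees: Sequence[TimeTree]):
        if not trees:
            raise TreeError("tree sample must not be empty")
        for t in trees:
            if t.taxa != taxa:
                raise TreeError("all trees in a sample must share one taxon set")
        self.taxa = taxa
        self.trees: list[TimeTree] = list(trees)

    @classmethod
    def from_trees(cls, trees: Sequence[TimeTree]) -> "TreeSample":
        return cls(trees[0].taxa, trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> TimeTree:
        return self.trees[i]


# ---------------------------------------------------------------------------
# Clade-level primitives shared by the distance and error modules.

def mrca_age(tree: TimeTree, subset: int) -> float:
    """Age of the most recent common ancestor of a taxon subset."""
    return tree.mrca_age(subset)


def branch_length(tree: TimeTree, subset: int) -> float:
    """Branch above ``subset``; 0 for the root and for absent subsets."""
    return tree.branch_length(subset)


def pairs_splitting_at(tree: TimeTree, clade: int) -> list[tuple[int, int]]:
    """Unordered taxon pairs whose MRCA in ``tree`` is exactly ``clade``.

    Pairs are returned as singleton bitmask pairs.  For an internal clade
    these are the cross-pairs between distinct children; singletons yield
    no pairs.
    """
    if clade not in tree.ages:
        raise TreeError("clade is not a clade of the tree")
    kids = tree.children[clade]
    out: list[tuple[int, int]] = []
    for i in range(len(kids)):
        ai = [1 << k for k in _bit_positions(kids[i])]
        for j in range(i + 1, len(kids)):
            bj = [1 << k for k in _bit_positions(kids[j])]
            out.extend((a, b) for a in ai for b in bj)
    return out


def _bit_positions(mask: int) -> list[int]:
    pos = []
    i = 0
    while mask:
        if mask & 1:
            pos.append(i)
        mask >>= 1
        i += 1
    return pos


def divergence_time(clade: int, source: TimeTree, reference: TimeTree) -> float:
    """Mean split time of the pairs of ``clade``, with split ages read off
    ``reference``.

    The pairs are those splitting exactly at ``clade`` in ``source``; each
    pair contributes the age of its MRCA in ``reference``.  Singletons have
    divergence time 0.  For ``reference is source`` this is the clade's own
    age, which makes the divergence-times error coincide with the heights
    error whenever two trees share a topology.
    """
    if clade not in source.ages:
        raise TreeError("clade is not a clade of the source tree")
    pairs = pairs_splitting_at(source, clade)
    if not pairs:
        return 0.0
    return sum(reference.mrca_age(a | b) for a, b in pairs) / len(pairs)
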
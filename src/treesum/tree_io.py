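"""Reading and writing tree sets and annotated summary trees.

Input: NEXUS trees blocks (BEAST dialect — translate tables, bracketed
`[&…]` metadata comments, case-insensitive keywords) and plain Newick,
one tree per line, parsed through dendropy.  Branch lengths are turned
into clade ages by placing every tip at age 0 and giving each internal
node the maximum root-ward path length from any descendant tip; trees
whose tip depths drift apart by more than a relative tolerance of the
root height are rejected as non-ultrametric.  Metadata comments are
tolerated on read but do not affect ages.

Output: Newick (or a minimal NEXUS wrapper) with branch lengths written
to 12 significant digits and optional BEAST-style node annotations
`[&posterior=…,height=…,height_95%_HPD={low,high}]`.  Zero-length
branches are legal in both directions; they encode polytomies.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import dendropy

from .core import TaxonSet, TimeTree, TreeSample, TreeError

__all__ = [
    "TreeFileDialect",
    "NodeAnnotation",
    "read_trees",
    "write_tree",
    "write_trees",
    "height_hpd",
]


@dataclass
class TreeFileDialect:
    """How to interpret a tree file."""

    format: str = "auto"  # nexus | newick | auto (sniffed)
    burnin: float | int = 0  # fraction in [0,1) or absolute tree count
    ultrametric_tolerance: float = 1e-6

    def __post_init__(self):
        if isinstance(self.burnin, float) and not 0 <= self.burnin < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        if isinstance(self.burnin, int) and self.burnin < 0:
            raise ValueError("burn-in count must be non-negative")
        if self.ultrametric_tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class NodeAnnotation:
    """Posterior support and height summary attached to one clade."""

    posterior: float | None = None
    height_point: float | None = None
    height_interval: tuple[float, float] | None = None

    def __post_init__(self):
        if self.posterior is not None and not 0 <= self.posterior <= 1:
            raise ValueError("posterior must be in [0, 1]")
        if self.height_interval is not None and self.height_point is not None:
            lo, hi = self.height_interval
            if not lo <= self.height_point <= hi:
                raise ValueError("height point outside its interval")

    def format(self) -> str:
        parts = []
        if self.posterior is not None:
            parts.append(f"posterior={self.posterior:.12g}")
        if self.height_point is not None:
            parts.append(f"height={self.height_point:.12g}")
        if self.height_interval is not None:
            lo, hi = self.height_interval
            parts.append(f"height_95%_HPD={{{lo:.12g},{hi:.12g}}}")
        return f"[&{','.join(parts)}]" if parts else ""


def _sniff_schema(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "nexus" if line.strip().upper().startswith("#NEXUS") \
                    else "newick"
    raise TreeError(f"{path}: empty tree file")


def _convert(dtree: dendropy.Tree, taxa: TaxonSet, tol: float,
             source: str) -> TimeTree:
    # clade bitmasks and node ages in one post-order sweep
    ages: dict[int, float] = {}
    mask: dict[object, int] = {}
    depth_min = math.inf
    depth_max = -math.inf
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise TreeError(f"{source}: unlabeled leaf")
            m = 1 << taxa.index[node.taxon.label]
            mask[node] = m
            ages[m] = 0.0
        else:
            m = 0
            age = 0.0
            for ch in node.child_nodes():
                if ch.edge.length is None:
                    raise TreeError(f"{source}: missing branch length")
                m |= mask[ch]
                age = max(age, ages[mask[ch]] + ch.edge.length)
            mask[node] = m
            if m in ages and m != taxa.full_mask:
                raise TreeError(f"{source}: duplicated clade (unifurcation?)")
            ages[m] = age
    root_mask = mask[dtree.seed_node]
    if root_mask != taxa.full_mask:
        raise TreeError(f"{source}: tree does not cover all taxa")
    # ultrametricity: tip depths measured from the root
    root_age = ages[root_mask]
    for leaf in dtree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node is not dtree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth_min = min(depth_min, d)
        depth_max = max(depth_max, d)
    if depth_max - depth_min > tol * max(root_age, 1e-300):
        raise TreeError(
            f"{source}: non-ultrametric tree (tip depth spread "
            f"{depth_max - depth_min:g} exceeds tolerance)"
        )
    return TimeTree(taxa, ages)


def read_trees(path, dialect: TreeFileDialect | None = None) -> TreeSample:
    """Read a tree set, convert branch lengths to ages, drop burn-in."""
    dialect = dialect or TreeFileDialect()
    schema = dialect.format if dialect.format != "auto" else _sniff_schema(path)
    try:
        tlist = dendropy.TreeList.get(
            path=str(path), schema=schema,
            rooting="force-rooted", preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"{path}: cannot parse as {schema}: {exc}") from exc
    if not tlist:
        raise TreeError(f"{path}: no trees found")
    labels = sorted(t.label for t in tlist.taxon_namespace)
    taxa = TaxonSet(labels)
    trees = []
    for i, dt in enumerate(tlist):
        leaves = {lf.taxon.label for lf in dt.leaf_node_iter() if lf.taxon}
        if leaves != set(labels):
            raise TreeError(f"{path}: tree {i} uses a different taxon set")
        trees.append(
            _convert(dt, taxa, dialect.ultrametric_tolerance, f"{path}:{i}")
        )
    skip = (
        int(round(dialect.burnin * len(trees)))
        if isinstance(dialect.burnin, float)
        else dialect.burnin
    )
    if skip >= len(trees):
        raise TreeError(f"{path}: burn-in removes all {len(trees)} trees")
    return TreeSample(taxa, trees[skip:])


def _newick(tree: TimeTree, annotations) -> str:
    def fmt(clade: int) -> str:
        ann = annotations.get(clade)
        a = ann.format() if ann else ""
        p = tree.parent.get(clade)
        blen = "" if p is None else f":{tree.ages[p] - tree.ages[clade]:.12g}"
        if clade.bit_count() == 1:
            label = tree.taxa.labels[clade.bit_length() - 1]
            return f"{label}{a}{blen}"
        kids = sorted(tree.children[clade],
                      key=lambda c: (c & -c).bit_length())
        inner = ",".join(fmt(k) for k in kids)
        return f"({inner}){a}{blen}"

    return fmt(tree.root) + ";"


def write_tree(
    tree: TimeTree,
    path=None,
    annotations: dict[int, NodeAnnotation] | None = None,
    format: str = "newick",
) -> str:
    """Write one (optionally annotated) tree; returns the serialization.

    ``annotations`` maps clade bitmasks (all of which must be clades of
    the tree) to :class:`NodeAnnotation`.
    """
    annotations = annotations or {}
    for c in annotations:
        if c not in tree.ages:
            raise TreeError("annotation attached to a non-clade")
    text = _newick(tree, annotations)
    if format == "nexus":
        text = _nexus_wrap([text], tree.taxa)
    elif format != "newick":
        raise ValueError("format must be 'newick' or 'nexus'")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def write_trees(sample: TreeSample, path, format: str = "newick") -> None:
    """Write a tree set, one Newick per line or a NEXUS trees block."""
    texts = [_newick(t, {}) for t in sample]
    out = _nexus_wrap(texts, sample.taxa) if format == "nexus" \
        else "\n".join(texts)
    with open(path, "w") as fh:
        fh.write(out + "\n")


def _nexus_wrap(newicks: list[str], taxa: TaxonSet) -> str:
    buf = io.StringIO()
    buf.write("#NEXUS\nbegin trees;\n\ttranslate\n")
    buf.write(",\n".join(f"\t\t{i + 1} {lab}"
                         for i, lab in enumerate(taxa.labels)))
    buf.write(";\n")
    for i, nwk in enumerate(newicks):
        for j, lab in sorted(enumerate(taxa.labels),
                             key=lambda p: -len(p[1])):
            nwk = _replace_label(nwk, lab, str(j + 1))
        buf.write(f"tree TREE{i + 1} = {nwk}\n")
    buf.write("end;")
    return buf.getvalue()


def _replace_label(newick: str, label: str, repl: str) -> str:
    out = []
    i = 0
    n = len(label)
    while i < len(newick):
        if (newick.startswith(label, i)
                and (i == 0 or newick[i - 1] in "(,")
                and (i + n < len(newick) and newick[i + n] in ":,)[")):
            out.append(repl)
            i += n
        else:
            out.append(newick[i])
            i += 1
    return "".join(out)


def height_hpd(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted samples containing
    ⌈level·k⌉ of them; ties resolve to the lowest start."""
    xs = sorted(samples)
    k = len(xs)
    if k == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    need = math.ceil(level * k)
    best = (math.inf, 0)
    for i in range(k - need + 1):
        span = xs[i + need - 1] - xs[i]
        if span < best[0]:
            best = (span, i)
    i = best[1]
    return xs[i], xs[i + need - 1]
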
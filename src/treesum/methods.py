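"""Named summary-tree methods: topology selector × height rule.

Method ids follow the field's naming, lowercased and hyphenated:

* ``cat-X`` / ``med-X`` / ``avg-X`` — common-ancestor mean ages, matched
  medians, matched means on the topology picked by selector
  X ∈ {mcc, tcb, ccd, hpf};
* ``hso-X`` — heights optimized against matched posterior ages only;
* ``rbs-X``, ``srbs-X``, ``ras-X``, ``hs-X`` — minimum mean distance
  under the named metric, on the selected topology;
* ``mrbs``, ``msrbs``, ``mras``, ``mhs`` — minimum distance with the
  topology searched over all sampled topologies;
* ``tp-median`` / ``tp-mean`` — taxa-partition tree;
* ``cons-median`` / ``cons-mean`` — majority-rule consensus;
* ``ccd`` / ``hpf`` — bare selectors, aged with common-ancestor means.

MED/AVG assignments may order a child above its parent ("negative
branches"); the result records them and the returned tree clamps each
offending child down to its parent age so that downstream evaluation
always receives a valid tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import TimeTree, TreeSample, build_tree
from .height_assignment import (
    HeightAssignment,
    cat_heights,
    consensus_tree,
    pointwise_heights,
)
from .min_distance import OptimizerOptions, min_distance_tree, \
    optimize_fixed_topology
from .taxa_partition import taxa_partition_tree
from .topology_selection import select_ccd, select_hpf, select_mcc, select_tcb

__all__ = ["SummaryResult", "summarize", "METHOD_IDS", "DEFAULT_METHODS"]

_SELECTORS = {"mcc": select_mcc, "tcb": select_tcb, "ccd": select_ccd,
              "hpf": select_hpf}
_POINTWISE = {"med": "median", "avg": "mean"}
_METRIC_RULES = {"rbs": "rbs", "srbs": "srbs", "ras": "ras", "hs": "hs",
                 "hso": "hs_matched"}

METHOD_IDS: tuple[str, ...] = tuple(
    [f"{rule}-{sel}"
     for rule in ("cat", "med", "avg", "hso", "rbs", "srbs", "ras", "hs")
     for sel in ("mcc", "tcb", "ccd", "hpf")]
    + ["mrbs", "msrbs", "mras", "mhs",
       "tp-median", "tp-mean", "cons-median", "cons-mean", "ccd", "hpf"]
)

#: the default battery for the experiment driver
DEFAULT_METHODS: tuple[str, ...] = (
    "cat-mcc", "cat-tcb", "med-mcc", "avg-mcc", "hso-mcc",
    "rbs-mcc", "rbs-tcb", "mrbs", "msrbs", "mras", "mhs",
    "hs-mcc", "tp-median", "tp-mean", "cons-median", "ccd", "hpf",
)


@dataclass
class SummaryResult:
    """A summary tree plus diagnostics of its construction."""

    tree: TimeTree
    method: str
    negative_branches: list[tuple[int, float]] = field(default_factory=list)
    clamped: int = 0
    fallback_splits: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _repair(assignment: HeightAssignment) -> TimeTree:
    """Clamp children above their parents down to the parent age."""
    heights = dict(assignment.heights)
    for c in sorted(heights, key=lambda x: -x.bit_count()):
        for d in heights:
            if d & c == d and d != c and heights[d] > heights[c]:
                heights[d] = heights[c]
    return build_tree(assignment.taxa, heights)


def summarize(
    sample: TreeSample,
    method: str,
    opts: OptimizerOptions | None = None,
) -> SummaryResult:
    """Build the summary tree named by ``method`` from a posterior sample."""
    opts = opts or OptimizerOptions()
    if method in ("tp-median", "tp-mean"):
        res = taxa_partition_tree(sample, method.split("-")[1])
        out = SummaryResult(res.tree, method, clamped=res.clamped,
                            fallback_splits=res.fallback_used)
        if res.clamped:
            out.warnings.append(
                f"{res.clamped} split age(s) clamped to their parent")
        return out
    if method in ("cons-median", "cons-mean"):
        tree = consensus_tree(sample, stat=method.split("-")[1])
        return SummaryResult(tree, method)
    if method in ("mrbs", "msrbs", "mras", "mhs"):
        tree = min_distance_tree(sample, method[1:], "all_sampled", opts)
        return SummaryResult(tree, method)
    if method in ("ccd", "hpf"):
        topo = sample[_SELECTORS[method](sample)]
        return SummaryResult(cat_heights(topo, sample).tree(), method)

    try:
        rule, sel = method.split("-")
        selector = _SELECTORS[sel]
    except (ValueError, KeyError):
        raise ValueError(f"unknown method {method!r}; known ids: "
                         f"{', '.join(METHOD_IDS)}") from None
    topo = sample[selector(sample)]
    if rule == "cat":
        return SummaryResult(cat_heights(topo, sample).tree(), method)
    if rule in _POINTWISE:
        assignment = pointwise_heights(topo, sample, _POINTWISE[rule])
        out = SummaryResult(_repair(assignment), method,
                            negative_branches=assignment.negative_branches)
        if not assignment.valid:
            out.warnings.append(
                f"{len(assignment.negative_branches)} negative branch(es) "
                "flagged and clamped")
        return out
    if rule in _METRIC_RULES:
        tree = optimize_fixed_topology(topo, sample, _METRIC_RULES[rule], opts)
        return SummaryResult(tree, method)
    raise ValueError(f"unknown method {method!r}")
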
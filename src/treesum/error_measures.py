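"""Discrepancy measures between a summary tree and a reference (true) tree.

These are directed scores — the first argument is the tree being judged,
the second the reference.  "Non-trivial" clades are internal clades other
than the root; singletons and the root are present in every tree on the
same taxa, so only this convention makes the missed-clade count agree
with half the Robinson-Foulds distance for fully resolved trees.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

from .core import TimeTree, TreeError, divergence_time

__all__ = [
    "ErrorVector",
    "heights_error",
    "divergence_error",
    "clades_missed",
    "clades_called",
    "root_height_error",
    "write_error_table",
]


def _check(t: TimeTree, ref: TimeTree) -> None:
    if t.taxa != ref.taxa:
        raise TreeError("trees are on different taxon sets")


def heights_error(t: TimeTree, ref: TimeTree) -> float:
    """Total clade-age error: Σ over clades c of t of |h(c) − h̄_ref(c)|.

    A clade absent from the reference is scored against the age of its
    MRCA there (a larger clade).  Not symmetric.  Tips contribute zero;
    the root term (root-height difference) is included.
    """
    _check(t, ref)
    return sum(abs(h - ref.mrca_age(c)) for c, h in t.ages.items())


def divergence_error(t: TimeTree, ref: TimeTree) -> float:
    """Total divergence-time error: Σ over clades c of t of
    |h(c) − h̃(c, ref)| where h̃ is the mean over the pairs splitting at c
    of their MRCA age in the reference.

    Coincides with :func:`heights_error` when the two trees share a
    topology; diverges from it as the topologies do.
    """
    _check(t, ref)
    return sum(
        abs(h - divergence_time(c, t, ref)) for c, h in t.ages.items()
    )


def _positive_nontrivial(t: TimeTree) -> set[int]:
    return {c for c in t.nontrivial_clades() if t.branch_length(c) > 0.0}


def clades_missed(t: TimeTree, ref: TimeTree) -> int:
    """Number of non-trivial reference clades absent from ``t``.

    A clade of ``t`` sitting on a zero-length branch does not count as a
    match (it is indistinguishable from its parent).  Equals half the
    Robinson-Foulds distance when ``t`` is fully resolved with positive
    branches.
    """
    _check(t, ref)
    matched = _positive_nontrivial(t)
    return sum(1 for c in ref.nontrivial_clades() if c not in matched)


def clades_called(t: TimeTree, ref: TimeTree) -> int:
    """Wrongly-called minus correctly-called clades of ``t`` (lower is
    better): every positive-branch non-trivial clade of ``t`` scores +1 if
    absent from the reference and −1 if present."""
    _check(t, ref)
    ref_clades = set(ref.nontrivial_clades())
    score = 0
    for c in _positive_nontrivial(t):
        score += -1 if c in ref_clades else 1
    return score


def root_height_error(t: TimeTree, ref: TimeTree) -> float:
    """Absolute difference of the two root heights."""
    return abs(t.root_height - ref.root_height)


@dataclass
class ErrorVector:
    """All error measures of one summary tree against one truth.

    The likelihood fields are filled by the evaluation layer;
    ``model_fit`` is the sum of the tree and coalescent log-likelihoods.
    """

    method: str = ""
    case: str = ""
    root_height_error: float = float("nan")
    heights_error: float = float("nan")
    divergence_error: float = float("nan")
    clades_missed: int = 0
    clades_called: int = 0
    tree_loglik: float = float("nan")
    coalescent_loglik: float = float("nan")
    model_fit: float = float("nan")

    # Normalized variants for condensed reporting: age error per internal
    # clade as a percentage of the true root height, and missed clades as
    # a percentage of the reference's non-trivial clades.
    heights_error_pct: float = float("nan")
    clades_missed_pct: float = float("nan")


def write_error_table(rows: Iterable[ErrorVector], path) -> None:
    """Write error vectors as a TSV, one row per (case, method)."""
    cols = [f.name for f in fields(ErrorVector)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write(
                "\t".join(str(getattr(r, c)) for c in cols) + "\n"
            )
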
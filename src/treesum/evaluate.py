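"""Model-fit likelihoods, per-case error reports, and method ranking.

Model fit of a summary tree is the sum of two log densities evaluated at
the generating model: the Jukes-Cantor likelihood of the alignment given
the tree (Felsenstein pruning) and the constant-size Kingman coalescent
density of the tree at the true population size.

Ranking follows a two-track protocol.  Per test case each method gets an
error value; methods are dense-ranked (ties share a rank, 1-2-2-3) and,
separately, the per-case errors are standardized to mean 0 / variance 1.
Either statistic is then bootstrapped over cases: method A dominates B
if A's mean beats B's in at least a threshold fraction (default 90%) of
4000 case-resamples, and each method's final score is 0 if undominated,
else one more than the best score among its dominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TimeTree, TreeSample, TreeError
from .error_measures import (
    ErrorVector,
    clades_called,
    clades_missed,
    divergence_error,
    heights_error,
    root_height_error,
)
from .simulate import Alignment

__all__ = [
    "jc_log_likelihood",
    "coalescent_log_likelihood",
    "model_fit_percentile",
    "error_report",
    "dense_rank",
    "normalize_errors",
    "bootstrap_scores",
    "RankTable",
]

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def jc_log_likelihood(
    tree: TimeTree, alignment: Alignment, mut_rate: float
) -> float:
    """Log-likelihood of the alignment given the tree under Jukes-Cantor.

    Felsenstein pruning with transition probability
    p_same(d) = 1/4 + 3/4·e^(−4d/3) at distance d = branch duration × μ,
    uniform root frequencies, independent sites.  Per-node rescaling
    guards against underflow.
    """
    if tree.taxa != alignment.taxa:
        raise TreeError("tree and alignment taxa differ")
    L = alignment.length
    if L == 0:
        raise ValueError("empty alignment")
    log_scale = 0.0

    def partial(clade: int) -> np.ndarray:
        nonlocal log_scale
        if clade.bit_count() == 1:
            label = tree.taxa.labels[clade.bit_length() - 1]
            s = np.fromiter(
                (_NUC_INDEX[ch] for ch in alignment.sequences[label]),
                dtype=int, count=L,
            )
            out = np.zeros((4, L))
            out[s, np.arange(L)] = 1.0
            return out
        out = np.ones((4, L))
        for ch in tree.children[clade]:
            d = (tree.ages[clade] - tree.ages[ch]) * mut_rate
            e = np.exp(-4.0 * d / 3.0)
            p_same, p_diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
            v = partial(ch)
            out *= p_diff * v.sum(axis=0) + (p_same - p_diff) * v
        mx = out.max(axis=0)
        log_scale += float(np.sum(np.log(mx)))
        return out / mx

    site_lik = 0.25 * partial(tree.root).sum(axis=0)
    return float(np.sum(np.log(site_lik))) + log_scale


def coalescent_log_likelihood(tree: TimeTree, pop_size: float) -> float:
    """Log density of a contemporaneous-tip tree under the constant-size
    Kingman coalescent: −Σ k(k−1)/2 · Δt/Ne over inter-event intervals,
    minus log Ne per coalescent event."""
    if pop_size <= 0:
        raise ValueError("population size must be positive")
    events = sorted(
        (tree.ages[c], len(tree.children[c]) - 1)
        for c in tree.internal_clades()
    )
    k = len(tree.taxa)
    t_prev = 0.0
    ll = 0.0
    for age, merges in events:
        for _ in range(merges):
            ll -= k * (k - 1) / 2.0 * (age - t_prev) / pop_size
            ll -= np.log(pop_size)
            t_prev = age
            k -= 1
    return ll


def model_fit_percentile(
    summary: TimeTree,
    sample: TreeSample,
    alignment: Alignment,
    mut_rate: float,
    pop_size: float,
) -> float:
    """Fraction of sampled trees whose total model fit (tree + coalescent
    log-likelihood) does not exceed the summary tree's."""
    def fit(t: TimeTree) -> float:
        return jc_log_likelihood(t, alignment, mut_rate) + \
            coalescent_log_likelihood(t, pop_size)
    s = fit(summary)
    return sum(1 for t in sample if fit(t) <= s) / len(sample)


def error_report(
    summary: TimeTree,
    truth: TimeTree,
    alignment: Alignment | None = None,
    mut_rate: float = 0.005,
    pop_size: float = 1.0,
    method: str = "",
    case: str = "",
) -> ErrorVector:
    """All error measures of one summary tree, likelihoods included."""
    ev = ErrorVector(method=method, case=case)
    ev.root_height_error = root_height_error(summary, truth)
    ev.heights_error = heights_error(summary, truth)
    ev.divergence_error = divergence_error(summary, truth)
    ev.clades_missed = clades_missed(summary, truth)
    ev.clades_called = clades_called(summary, truth)
    n_internal = len(summary.internal_clades())
    ev.heights_error_pct = (
        100.0 * ev.heights_error / n_internal / truth.root_height
        if truth.root_height > 0 else float("nan")
    )
    n_ref = len(truth.nontrivial_clades())
    ev.clades_missed_pct = 100.0 * ev.clades_missed / n_ref if n_ref else 0.0
    if alignment is not None:
        ev.tree_loglik = jc_log_likelihood(summary, alignment, mut_rate)
        ev.coalescent_loglik = coalescent_log_likelihood(summary, pop_size)
        ev.model_fit = ev.tree_loglik + ev.coalescent_loglik
    return ev


# ---------------------------------------------------------------------------
# Ranking

def dense_rank(values) -> np.ndarray:
    """Dense ranks (1-2-2-3): smallest value gets 1, ties share a rank,
    the next distinct value increments by one."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty values")
    _, inv = np.unique(v, return_inverse=True)
    return inv + 1


def normalize_errors(matrix) -> np.ndarray:
    """Standardize each row (case) to mean 0, variance 1 (population
    convention); constant rows become all zeros."""
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    out = np.zeros_like(m)
    np.divide(m - mu, sd, out=out, where=sd > 0)
    return out


def bootstrap_scores(
    matrix,
    reps: int = 4000,
    dominance_threshold: float = 0.9,
    rng: np.random.Generator | None = None,
    statistic: str = "rank",
) -> np.ndarray:
    """Final dominance scores from a case × method error matrix
    (lower error = better).

    Per bootstrap resample of the cases, each method's mean per-case
    dense rank (``statistic="rank"``) or mean normalized error
    (``statistic="value"``) is computed; A dominates B when A's mean is
    smaller in at least ``dominance_threshold`` of the resamples.  A
    method scores 0 if undominated, else 1 + the maximum score among its
    dominators.
    """
    if reps < 1 or not 0.5 < dominance_threshold <= 1.0:
        raise ValueError("need reps ≥ 1 and threshold in (0.5, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    m = np.asarray(matrix, dtype=float)
    ncases, nmeth = m.shape
    if statistic == "rank":
        stat = np.vstack([dense_rank(row) for row in m]).astype(float)
    elif statistic == "value":
        stat = normalize_errors(m)
    else:
        raise ValueError("statistic must be 'rank' or 'value'")
    idx = rng.integers(0, ncases, size=(reps, ncases))
    means = stat[idx].mean(axis=1)  # reps × methods
    dominates = np.zeros((nmeth, nmeth), dtype=bool)
    for a in range(nmeth):
        for b in range(nmeth):
            if a != b:
                frac = np.mean(means[:, a] < means[:, b])
                dominates[a, b] = frac >= dominance_threshold
    scores = np.full(nmeth, -1, dtype=int)
    for _ in range(nmeth):
        progressed = False
        for b in range(nmeth):
            if scores[b] >= 0:
                continue
            doms = np.nonzero(dominates[:, b])[0]
            if len(doms) == 0:
                scores[b] = 0
                progressed = True
            elif all(scores[a] >= 0 for a in doms):
                scores[b] = 1 + int(scores[doms].max())
                progressed = True
        if scores.min() >= 0:
            break
        if not progressed:
            raise AssertionError("cyclic dominance relation (should be "
                                 "impossible at threshold > 0.5)")
    return scores


@dataclass
class RankTable:
    """Aggregated ranking results: one row per method, per error measure
    the mean dense rank plus the comparison- and magnitude-based final
    scores."""

    methods: list[str]
    measures: list[str]
    #: measure -> case × method error matrix
    errors: dict[str, np.ndarray] = field(default_factory=dict)
    mean_ranks: dict[str, np.ndarray] = field(default_factory=dict)
    comparison_scores: dict[str, np.ndarray] = field(default_factory=dict)
    magnitude_scores: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_errors(
        cls,
        methods: list[str],
        errors: dict[str, np.ndarray],
        reps: int = 4000,
        dominance_threshold: float = 0.9,
        rng: np.random.Generator | None = None,
    ) -> "RankTable":
        rng = rng if rng is not None else np.random.default_rng(0)
        table = cls(methods, list(errors), errors)
        for meas, m in errors.items():
            ranks = np.vstack([dense_rank(row) for row in m])
            table.mean_ranks[meas] = ranks.mean(axis=0)
            seed = int(rng.integers(2**31))
            table.comparison_scores[meas] = bootstrap_scores(
                m, reps, dominance_threshold,
                np.random.default_rng(seed), "rank",
            )
            table.magnitude_scores[meas] = bootstrap_scores(
                m, reps, dominance_threshold,
                np.random.default_rng(seed), "value",
            )
        return table

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("measure\tmethod\tmean_rank\tcomparison_score\t"
                     "magnitude_score\n")
            for meas in self.measures:
                for i, meth in enumerate(self.methods):
                    fh.write(
                        f"{meas}\t{meth}\t{self.mean_ranks[meas][i]:.4f}\t"
                        f"{self.comparison_scores[meas][i]}\t"
                        f"{self.magnitude_scores[meas][i]}\n"
                    )
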
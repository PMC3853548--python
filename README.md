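# treesum

Summary trees from posterior samples of rooted time trees.

Bayesian phylogenetic inference (BEAST-style) yields thousands of
correlated draws of rooted, ultrametric *time trees*.  For presentation
and downstream use this forest is usually condensed into a single
summary tree — but with real posteriors the trees disagree, and the
common practice (pick the maximum-clade-credibility topology, then age
each clade from the subset of trees containing it) throws away most of
the sample and can even produce negative branch lengths.  `treesum`
implements a family of summary constructions that use the whole
posterior, together with the error measures and the
simulation/ranking machinery needed to compare them.

## The model and the methods

A tree on taxa L is a triple (L, ℂ, h): a strict hierarchy of clades
ℂ ⊆ 2^L (every singleton, the root L, any two clades nested or
disjoint) with ages h: ℂ → ℝ≥0 that never decrease root-ward; tips sit
at age 0.  Clades are stored as bitsets over a fixed taxon order, so
matching clades across trees is a hash lookup.  The branch above clade
c has length b(c) = h(P(c)) − h(c), and b(x) = 0 for any taxon subset x
that is not a clade of the tree.

Four scores compare two trees T₁, T₂ on the same taxa:

* **RBS** (rooted branch score) = Σ_{c ∈ ℂ₁∪ℂ₂} |b⁽¹⁾(c) − b⁽²⁾(c)| — a
  metric;
* **SRBS** — the same sum with squared differences;
* **HS** (heights score) = Σ_{shared} |h⁽¹⁾(c) − h⁽²⁾(c)| + (total branch
  length of private clades);
* **RAS** (rooted agreement score) — branches compared as age intervals
  [h(c), h(P(c))] via the measure of their symmetric difference, plus
  the private-branch penalty — also a metric.

The distance from a tree T to a sample 𝕋 is the mean pairwise score
d(T, 𝕋) = |𝕋|⁻¹ Σᵢ d(T, tᵢ).  Rewriting the pairwise sums per clade and
pre-sorting each clade's matched branch lengths / ages / interval
endpoints (with prefix sums) makes one evaluation cost
O(|ℂ| log |𝕋|) — a binary search per clade — instead of O(|ℂ|·|𝕋|).

Summary constructions:

* **Topology selectors** — MCC (max product of clade posterior
  frequencies), CCD (max product of conditional split probabilities),
  TCB (max total matched branch length), HPF (most frequent sampled
  topology); all restricted to sampled topologies.
* **Height rules on a fixed topology** — AVG/MED (mean/median of matched
  clade ages; may produce negative branches, which are flagged),
  CAT (mean over *all* trees of the clade's MRCA age — always a valid
  tree), and minimum-distance heights: the tree is encoded as
  z = (h_root, α₂…α_m) with α the age/parent-age ratios, every
  coordinate simply bounded (h ≥ 0, α ∈ [0,1]), and d(T, 𝕋) is
  minimized by bounded L-BFGS-B with exact analytic (sub)gradients,
  multi-start screening and a derivative-free polish.
* **mRBS / mSRBS / mHS / mRAS** — the same optimization repeated over
  every distinct sampled topology, with the sampled trees themselves
  kept as candidates, so the result is never farther from the sample
  than the best sampled tree.
* **TP** (taxa partition) — orders the taxa by clustering on mean
  MRCA-clade sizes, pools every compatible clade age from the whole
  sample onto the n−1 between-taxon splits, and only then builds the
  topology recursively from the split point estimates.
* **CONS** — majority-rule consensus aged like CAT.

Evaluation against a known truth: root-height error, total clade-age
error, divergence-times error, missed clades (= RF/2 for resolved
trees), wrongly-called clades, and model fit (Jukes-Cantor tree
likelihood via Felsenstein pruning + constant-size Kingman coalescent
density).  Methods are compared over simulated cases by dense ranks and
standardized errors, with bootstrap dominance scoring.

## Worked example

Three trees on taxa {a, b, c} — two with topology ((a,b),c) at cherry
heights 1 and 0.5 (roots 2 and 3), one with (a,(b,c)) (root 2):

```python
import numpy as np
from treesum import (TaxonSet, TreeSample, build_tree, summarize,
                     build_clade_index, set_distance)

taxa = TaxonSet("abc")
c = taxa.clade
sample = TreeSample.from_trees([
    build_tree(taxa, {c("ab"): 1.0, c("abc"): 2.0}),
    build_tree(taxa, {c("ab"): 0.5, c("abc"): 3.0}),
    build_tree(taxa, {c("bc"): 1.0, c("abc"): 2.0}),
])
idx = build_clade_index(sample, "rbs")
for method in ("cat-mcc", "med-mcc", "mrbs", "tp-median", "cons-median"):
    res = summarize(sample, method)
    ages = {"".join(taxa.members(cl)): round(a, 4)
            for cl, a in sorted(res.tree.ages.items()) if cl.bit_count() > 1}
    print(f"{method:12s} heights={ages}  mean-RBS={set_distance(res.tree, idx):.4f}")
```

prints

```
cat-mcc      heights={'ab': 1.1667, 'abc': 2.3333}  mean-RBS=2.8889
med-mcc      heights={'ab': 0.75, 'abc': 2.0}  mean-RBS=2.7500
mrbs         heights={'ab': 1.0, 'abc': 2.0}  mean-RBS=2.5000
tp-median    heights={'ab': 1.0, 'abc': 2.0}  mean-RBS=2.5000
cons-median  heights={'ab': 1.0, 'abc': 2.0}  mean-RBS=2.5000
```

All five summaries pick the majority topology ((a,b),c).  CAT ages the
cherry at the mean MRCA age of {a,b} over all three trees
((1 + 0.5 + 2)/3 = 1.1667); MED uses only the two trees containing the
cherry (median of {1, 0.5}); the minimum-RBS tree, the taxa-partition
tree and the consensus all land on the first sampled tree, whose mean
RBS distance to the sample (2.5) is the smallest achievable here.

The same is available from a shell:

```sh
treesum simulate --n-tips 8 --seed 3 -o case/          # synthetic test case
treesum summarize -i case/posterior.trees -o summary.nex \
    --method tp-median --burnin 0.1 --seed 42
treesum experiment --n 8 --ne 1 --cases 5 --posterior-size 100 \
    --methods cat-mcc,med-mcc,mrbs,tp-median --seed 5 -o exp/
```

`summarize` writes a NEXUS tree annotated with clade posterior support
and 95% HPD age intervals; `experiment` writes per-case error tables
(`errors.tsv`) and the bootstrap rank tables (`ranks.tsv`).

## Layout

| module | contents |
| --- | --- |
| `treesum.core` | taxon sets, bitset clades, `TimeTree` validation, MRCA/branch primitives |
| `treesum.tree_io` | NEXUS/Newick reading (dendropy), annotated writer, HPD intervals |
| `treesum.distances` | RBS/SRBS/HS/RAS, clade index, fast mean distance |
| `treesum.topology_selection` | clade frequencies, MCC, CCD, TCB, HPF |
| `treesum.height_assignment` | AVG/MED, CAT, consensus |
| `treesum.min_distance` | ratio encoding, objective + gradients, bounded optimization |
| `treesum.taxa_partition` | taxa ordering, split-age pooling, TP reconstruction |
| `treesum.error_measures` | summary-vs-truth error measures |
| `treesum.simulate` | Kingman coalescent, Jukes-Cantor sequences, pseudo-posteriors |
| `treesum.evaluate` | likelihoods, dense ranks, bootstrap dominance scores |
| `treesum.methods`, `treesum.cli`, `treesum.experiment` | method registry, CLI, simulation driver |

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
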
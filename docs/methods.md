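# Methods notes

## Data model and assumptions

A time tree is a strict hierarchy of clades with non-decreasing ages
root-ward; all tips are contemporaneous at age 0.  Serially-sampled
(dated) tips are rejected at load: every definition here that treats a
branch as the age interval [h(c), h(P(c))] measures from the common tip
time, and the agreement score and the taxa-partition pooling both rely
on that.  Unrooted trees are out of scope.  Multifurcations are legal
and arise two ways: genuinely (a clade with three or more children, as
in majority-rule consensus output) or encoded as zero-length internal
branches.  A clade sitting on a zero-length branch never counts as a
"called" or "matched" clade in the topological error measures, since it
cannot be distinguished from its parent.

Clades are bitsets over a taxon order fixed when a sample is loaded;
equality and hashing are on the bit patterns, so clade matching across
thousands of trees is O(1) and the whole toolkit shares one identity
notion.  Age-order validation uses an absolute tolerance of 1e-9 (ages
read back from 12-significant-digit text must revalidate); violations
inside the tolerance are clamped to preserve ordering, larger ones are
errors.

## Interpretive choices in the scores

Two definitional gaps had to be closed, and both choices are load-bearing:

* **Divergence-times error.**  The pairs whose split time is averaged
  are taken from the tree being scored, while the split ages are read
  off the reference tree.  This is the only reading under which the
  divergence-times error equals the clade-age error whenever the two
  trees share a topology (a property the tests assert), while the two
  errors diverge as topologies disagree.
* **"Heights only" (HSO).**  Implemented as minimization of the matched
  -clades heights term alone — Σ over shared clades of |Δh| with no
  private-branch penalty.  This is the only objective that differs from
  both the full heights score and the matched-median rule; it is a
  documented guess, flagged here because the name alone underdetermines
  it.

Likewise underdetermined and resolved as follows: the TCB tree score
combines per-clade scores by **sum** (a product variant is available via
`select_tcb(..., combine="product")`); HPF frequency ties are broken by
the tree whose root height is closest to the posterior mean root height,
with candidates drawn from the tied topologies only; consensus heights
use the CAT rule (mean/median of the clade's MRCA age over *all* trees),
which guarantees a valid tree — a matched-ages-only variant exists
behind `matched_only=True` and is repaired child-to-parent when it
inverts.

## Taxa-partition pooling rule

A clade of a sampled tree contributes its age to the boundary k of a
taxa ordering exactly when (i) its taxa occupy a contiguous run of
order positions, (ii) each child's taxa do too, and (iii) k is the
boundary between the children's blocks.  A laxer rule — any k inside
the clade's span — would let one clade age land on several splits and
double-count; the strict rule reproduces all the worked contribution
examples in the test suite and gives each age at most one destination.
Splits that never receive a contribution fall back to the mean/median
MRCA age of the two adjacent taxa over all trees (always defined); the
reconstruction clamps a child estimate exceeding its parent's
(child := min(child, parent)) and reports the count.  Ties at the
maximal split age resolve to the leftmost split.  The ordering
heuristic is average-linkage agglomeration over ordered groups on the
mean MRCA-clade-size matrix, concatenating end-to-end in whichever of
the four orientations brings the closest boundary taxa together, with
all ties resolved to the lexicographically smallest label sequence —
clustering linkage and orientation are themselves design choices; any
ordering compatible with the sample's dominant clades works.

## Optimization

Fixed-topology minimum-distance trees use the (root height, age-ratio)
parametrization: every coordinate has a simple bound (h ≥ 0,
α ∈ [0, 1]) and every point decodes to a valid tree, so condition
checking never enters the search.  Gradients are exact and analytic;
at the kinks of the L1-type objectives (RBS/HS/RAS and the HSO term)
the one-sided derivative from below is used.  The mean distance is
evaluated through the clade index in O(|ℂ| log |𝕋|): per clade, a
binary search against its pre-sorted matched branch lengths (RBS/SRBS),
ages (HS), or interval endpoints with prefix sums (RAS), plus
topology-only constants.

The objective surfaces are multimodal — narrow interior basins and
optima hugging the bounds (α near 0 or 1, near-zero roots) both occur.
The search therefore runs bounded L-BFGS-B from (a) a per-branch
initialization — each branch's isolated optimum (median of its
zero-padded matched branch multiset for the L1 scores, mean for SRBS)
combined children-first, flooring a parent at its tallest child — and
(b) the best `restarts` points of a screened random pool (default 16
starts from a pool of 768; root proposals squared-uniform on
[0, 1.5·max sampled root] to reach tiny trees, ratio proposals
Beta(0.3, 0.3) to cover the bounds).  The best endpoint gets a bounded
derivative-free (Powell) polish, which repairs quasi-Newton stalls on
kinks.  Grid-search audits on 3-taxon samples (2001×1001 points over
root × ratio) place this scheme within 1e-9 of the exhaustive optimum
on every trial; smaller restart counts (3, 8) measurably miss narrow
basins, which is why 16 is the default.  Candidate trees always include
the initialization and, at the topology-search level, every sampled
tree — so the returned tree is never worse than either.  A sample whose
trees all have height 0 returns the degenerate flat tree directly.
There is no global-optimality guarantee beyond these audits, and the
topology search is capped (most frequent first, default 1024 distinct
topologies).

## Synthetic data

The generator emulates the study conditions the toolkit is meant for:
Kingman coalescent genealogies (k lineages merge at rate
k(k−1)/(2·Ne)) on the grid n ∈ {8, 16, 32, 64, 128} tips,
Ne ∈ {1, 2, 4, 8} (defaults n = 8, Ne = 1); 800 bp Jukes-Cantor
alignments at mutation rate μ = 0.005 substitutions per site per
coalescent time unit, so typical root heights span ≈ 0.01–0.08
substitutions.  Coalescent ages are kept in population-size units;
multiplying by μ converts to substitution units.

An MCMC posterior is replaced by a **pseudo-posterior**: independent
jittered copies of a reference tree.  Topology noise is a
Poisson(topo_moves_mean)-distributed number of random NNI moves (ages
preserved where the swap leaves them valid, otherwise redrawn uniformly
in the feasible interval); height noise multiplies the root by
exp(N(0, cv)) and perturbs each age ratio by N(0, cv) on the logit
scale before decoding, so every replicate is valid by construction.
Defaults topo_moves_mean = 1.0, height_cv = 0.1 give a moderately
diffuse posterior (tens of distinct topologies at n = 8, 100 trees) of
the kind the summary methods are designed to disagree on.  What this
does **not** emulate: MCMC autocorrelation, multimodal posteriors,
model misspecification, or the coupling between sequence information
and posterior spread — so passing tests demonstrate correctness of the
constructions under unimodal, truth-centred uncertainty, not end-to-end
performance on real MCMC output.

## Ranking protocol

Per test case each method's error is dense-ranked (ties share a rank,
1-2-2-3) and, on a second track, standardized per case to mean 0 /
variance 1 (population convention; constant rows map to zeros).  Either
statistic is bootstrapped over cases (default 4000 resamples); method A
dominates B when A's mean beats B's in at least 90% of resamples, and a
method scores 0 if undominated, else one more than its best dominator.
Larger-is-better measures (the likelihoods) are negated before ranking.
Dominance at a >50% threshold is asymmetric, so the score recursion
terminates; a cycle would indicate a numerical tie pathology and raises.

## Problem sizes in the test suite

The full simulation study behind the method comparison is far larger
than a test suite should be, so the suite audits properties at reduced
scale: calibration on 1000 coalescent draws at (n=128, Ne=8); metric
axioms on 1000 random tree triples (n ≤ 8); index-vs-naive distance
identity on 200 probe/sample pairs (100 trees each); optimizer-vs-grid
audits on 50 three-taxon samples; truth recovery for every method on
concentrated samples at n = 8; validity of the always-valid
constructions on 1000 randomized pseudo-posteriors.  The experiment
driver runs the same pipeline at any scale from the CLI.

## Known limitations

* Contemporaneous tips only; no dated-tip generalization.
* Topology search never leaves the sampled topologies.
* The coalescent density is evaluated at the configured (true) Ne;
  integrating over a population-size posterior is out of scope.
* The NEXUS reader targets the BEAST dialect (trees block, translate
  table, bracketed metadata comments); data/characters blocks are
  ignored.
* `hs`/`srbs` are not metrics (the triangle inequality can fail);
  they are treated as semimetric scores throughout, and nothing in the
  toolkit relies on a triangle inequality.
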
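# Methods

This note documents the models, decision rules, numerical choices and known
limitations of `premito`, in the spirit of the model documentation shipped
with packages like statsmodels or msprime. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Candidate screening

Input is a BLAST-tabular-style hit table (only query, subject, e-value and
bit score are consumed). A query is retained when, after removing self-hits
and hits with e-value above the cutoff (default 10⁻⁴), at least one of its
top 5 remaining hits is alphaproteobacterial or mitochondrial. Two details
the rule itself does not fix are resolved as follows:

* the e-value cutoff is applied to **all** hits before ranking, not only to
  the qualifying hit — the stricter reading;
* ties in e-value are broken by descending bit score, then subject id, so
  ranking is deterministic;
* subjects missing from the taxonomy are treated as other-bacterial (never
  qualifying) and logged, rather than aborting a genome-scale run.

The filter is monotone: raising the cutoff or enlarging the rank window can
only add retained queries (property-tested).

## 2. Family clustering (MCL)

Candidates and their homologs (edges from hits at e ≤ 10⁻¹⁵) form an
undirected graph weighted by −log₁₀ e, capped at 200 (e = 0 maps to the
cap); the best e-value of the two directions is used. Markov clustering
alternates expansion (squaring the column-stochastic matrix) and inflation
(entry-wise power 2.0, column renormalization) to convergence (∞-norm change
< 10⁻⁸; hard iteration cap with an error naming the residual). Self-loops
equal each node's maximum incident weight, the common stabilisation. Clusters
are the supports of attractor rows; attractors with overlapping supports are
merged, residual multi-cluster nodes go to the larger cluster, ties broken
lexicographically. The partition is invariant to node input order and to
uniform weight scaling (tested). Families are kept for tree analysis when
their eukaryotic members span ≥ 2 distinct lineages.

## 3. Rooting cascade and bipartition scan

Each family tree is rooted up to three ways, in priority order: archaeal
outgroup, *Deinococcus–Thermus* outgroup (each skipped when absent or not
separable as a clade under any rooting), and midpoint (always attempted —
the guaranteed fallback). Midpoint ties between equally long leaf paths are
broken by the lexicographically smallest leaf pair, making the operation
deterministic. Outgroup rooting places the root at the middle of the
separating edge. Re-rooting never changes the leaf set or the unrooted
bipartition set (tested).

The scan reports every **maximal** clade whose leaves carry only the classes
{eukaryote-nuclear, mitochondrial, alphaproteobacterial} and contain ≥ 2
distinct eukaryotic lineages and ≥ 2 distinct alphaproteobacterial species.
This is the strictest reading of "eukaryotes clustering with
alphaproteobacterial/mitochondrial homologs": zero intruding leaves are
tolerated by default; `max_intruders` relaxes it. Counting lineages (not
sequences) is deliberate: it is what rejects lineage-specific transfers with
probability 1. Nested qualifying clades are subsumed by their maximal
ancestor.

Paralog handling: within one qualifying clade, the maximal all-eukaryotic
sub-clades are located; when two or more of them each span ≥ 2 lineages
(they are then necessarily separated by bacterial leaves), each founds its
own family, sharing the clade's bacterial context. Across rootings,
families are unioned and deduplicated by member set; nested member sets are
merged into the larger (flagged), conflicting overlaps are both kept and
flagged. The cross-rooting semantics are a package choice favouring recall
with explicit flags, since no canonical rule exists.

Polytomies and zero-length branches are accepted as-is; no collapsing is
performed by default (a collapse threshold would be a pre-processing choice,
not part of the scan).

## 4. Gain/loss CTMC and pruning likelihood

Presence/absence of family *i* in taxon *j* is a binary trait evolving along
the rooted species tree under rates q₀₁ (gain) and q₁₀ (loss) per unit
branch length. The transition matrix uses the closed form with
s = q₀₁ + q₁₀, P₀₁(t) = (q₀₁/s)(1 − e^(−st)), computed via `expm1` for
accuracy at small st; s = 0 degenerates to the identity. Likelihoods use
Felsenstein pruning with per-node rescaling by the maximum partial
likelihood (log-scale accumulator), so matrices with hundreds of taxa do not
underflow; impossible configurations return −∞ rather than raising. Missing
entries contribute a partial likelihood of 1 for both states. Matrix columns
must name tree leaves; tree leaves without a column are treated as missing
for every family — absence is evidence, lack of annotation is not.

The likelihood is vectorized across families (one partial-likelihood array
per node over all families), which is what makes global-chain MCMC on
1,000-family matrices affordable on one CPU.

Root prior: uniform (0.5, 0.5) by default; the stationary distribution
(q₁₀/s, q₀₁/s) is an option. Uniform is the default because the stationary
prior double-counts the rate information when rates are themselves being
estimated.

Model variants: `asymmetric` (two free rates, the default) and `symmetric`
(q₀₁ = q₁₀), since a one- or two-rate parameterisation is a genuine modelling
choice for binary traits.

## 5. Maximum likelihood

Rates are optimized on the log scale with L-BFGS-B inside bounds
log q ∈ [−10, 5], from three starting points to avoid the flat-corner local
optima of low-information matrices. Estimates pinned at a bound are flagged
(`at_bound`); a loss rate at the lower bound (~e⁻¹⁰ ≈ 0) is the correct
answer when, e.g., no loss is ever observed. A per-family fit loops the same
optimizer over single-row likelihoods.

## 6. MCMC and ancestral-state posterior

The sampler is random-walk Metropolis on (log q₀₁, log q₁₀) with a gamma
prior on each rate. Two moves per cycle:

1. a Gaussian step on the log rates (default SD 0.5; with `adapt=True` the
   step is tuned toward ~30 % acceptance during burn-in only, so the
   post-burn-in kernel is fixed and valid);
2. when `hyperprior=True`, an independence move resampling the gamma shape
   and scale from their uniform hyperprior ranges, accepted by the prior
   ratio at the current rates. Hyperprior bounds are shape ∈ (0, 10] and
   scale ∈ (0, 2·(ML rate)], seeded from the initial ML fit — reducing the
   arbitrariness of a fixed prior, which is the purpose of hyperpriors in
   this kind of reconstruction.

Default run length mirrors a production analysis: 1,050,000 cycles with
50,000 discarded as burn-in, and the posterior presence probability of a
family at the target node is the average over retained cycles of the node's
presence probability. Two numerical choices matter here:

* **Rao–Blackwellization.** Rather than sampling a node-state indicator per
  cycle, each retained cycle contributes the *exact* marginal
  P(node = present | data, sampled rates), computed from two clamped pruning
  passes (clamping partitions the likelihood: L = L₀ + L₁). The expectation
  is identical to indicator sampling; the Monte-Carlo variance is strictly
  smaller.
* **Chain scope.** `per-family` (default) runs an independent chain per
  family — matching per-family bookkeeping of the binary states — with
  per-family seeds spawned from the master seed; `global` shares one rate
  chain across all families and evaluates all marginals vectorized, which is
  the practical mode for 10³-family matrices.

Chains are bit-reproducible under a fixed seed (numpy PCG64 generators
only). Diagnostics: acceptance rate and an initial-positive-sequence ESS
for each rate.

The target node is the MRCA of user-supplied leaf sets — for the
pre-mitochondrial question, the mitochondrial leaves plus their Rickettsiales
sister clade. The presence-call threshold (default 0.5, recorded in output)
is exposed because no canonical cutoff exists for "present".

## 7. Genome-size extrapolation

Ordinary least squares of gene count on family count and of genome size (Mb)
on family count across extant genomes (statsmodels OLS), evaluated at the
ancestral family count with standard 95 % prediction intervals. Perfectly
collinear inputs yield zero-width intervals; fewer than 3 genomes or zero
variance in family counts is an error.

## 8. Synthetic data: what it emulates and what it does not

The generators exist to exercise decision rules against recorded truth, not
to model genome evolution realistically:

* **Species trees** are pure-birth (Yule) trees scaled to unit height —
  adequate for testing reconstruction machinery, not a model of
  alphaproteobacterial diversification.
* **Trait histories** are forward simulations of the same two-rate CTMC the
  inference assumes (defaults q₀₁ = 0.2, q₁₀ = 0.8: loss-dominated, as in
  endosymbiont genome reduction), with every internal-node state recorded.
  Because generator and inference share the model family, recovery tests
  validate the *machinery*, not the model's adequacy for real data.
* **Gene histories** come in four kinds — mitochondria-derived (a 2–4
  lineage eukaryotic clade nested inside the alphaproteobacterial clade),
  lineage-specific transfer (one eukaryotic lineage inside
  alphaproteobacteria; must be rejected), other-bacterial origin, and
  vertical-eukaryotic — mixed at fractions 0.4/0.2/0.2/0.2 by default, with
  archaeal and *Deinococcus–Thermus* leaves present so the full rooting
  cascade is exercised. Optional random NNI moves inject topology noise as a
  stand-in for phylogenetic error; no attempt is made to model long-branch
  attraction mechanistically.
* **Sequences** evolve under JC69 (branch lengths 0.01–0.08 subs/site per
  branch, 500 bp by default — pairwise distances stay far from saturation,
  so neighbor joining on JC69 distances recovers the generating topology
  with high probability).
* **Hit tables** map pairwise identity to e-values via
  e = 10^(−a·(identity − 0.35) + jitter) with a = 60 and Gaussian log₁₀
  jitter (SD 0.5); only the induced ranking matters to the screen. Hits are
  restricted to family members — cross-family noise hits are not emulated,
  so the clustering stage is exercised on connectivity, not on
  between-family separation.

Consequently, passing the end-to-end benchmark shows the decision rules are
implemented correctly and are robust to sequence-level noise at these
settings; it does not show field-realistic sensitivity/specificity, which
depend on alignment quality, rate heterogeneity and taxon sampling that the
generators deliberately omit.

## 9. Problem sizes in tests and acceptance runs

The shipped test and acceptance configurations use scaled problem sizes
chosen to probe each property well while staying desk-sized: 200 mixed
families for the end-to-end benchmark; 30 taxa × 1,000 families for rate and
ancestral-state recovery (global chain, 12,000 cycles, 2,000 burn-in,
thinning 10); 100,000 cycles for the four-tip MCMC-vs-quadrature comparison
(a 200–240 point per-axis product-grid quadrature of the gamma-weighted node
marginal is the deterministic oracle); exhaustive topology enumeration up to
5 tips for the pruning oracle; and trees up to 50 leaves for the scan
oracle. Production-scale defaults (the 1,050,000-cycle chain) remain the
package defaults.

## 10. Known limitations

* The scan's purity rule is strict; real trees with minor contamination or
  poorly resolved nodes will need `max_intruders` > 0 or pre-filtering, and
  the package deliberately leaves that judgement to the user.
* MCL on a dense matrix is O(n³) per iteration; graphs beyond ~10⁴ nodes
  need a sparse implementation.
* Per-family MCMC at production lengths over thousands of families is
  expensive; the global chain is the intended mode at that scale, at the
  cost of assuming shared rates across families.
* The hyperprior's uniform bounds are anchored at the ML estimates; with
  pathologically flat likelihoods the anchor itself is weakly determined.
* Newick round-tripping preserves topology and branch lengths, but internal
  node labels are carried only as annotations and ignored by all algorithms.
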
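# premito

Phylogenomic detection of **mitochondria-derived nuclear gene families** and
Bayesian reconstruction of the gene complement of the **pre-mitochondrial
ancestor** — the last common ancestor of mitochondria and their
alphaproteobacterial (Rickettsiales) sister clade.

## The scientific problem

Mitochondria descend from an alphaproteobacterial endosymbiont, and most of
the endosymbiont's genes were either lost or transferred to the host nucleus.
Reconstructing what the mitochondrial ancestor looked like therefore requires
two steps:

1. **Find the transferred genes.** A eukaryotic nuclear gene is
   mitochondria-derived when its gene tree places it inside, or sister to,
   alphaproteobacterial homologs. The pipeline screens every eukaryotic gene
   by homology search (retained if one of its top 5 hits at e ≤ 10⁻⁴ is
   alphaproteobacterial or mitochondrial), clusters candidates into families
   with the Markov Cluster Algorithm, roots each family's tree up to three
   ways (archaeal outgroup, *Deinococcus–Thermus* outgroup, midpoint), and
   scans each rooted tree for a clade containing only eukaryote-nuclear,
   mitochondrial and alphaproteobacterial leaves with ≥ 2 distinct eukaryotic
   lineages and ≥ 2 alphaproteobacterial species. Requiring two eukaryotic
   lineages rejects recent lineage-specific transfers; paralogous eukaryotic
   blocks inside one clade are split into separate families.

2. **Reconstruct the ancestral gene content.** The presence/absence of each
   gene family (COG) across taxa is a binary trait on a rooted species tree,
   evolving under a two-state continuous-time Markov chain with gain rate
   q₀₁ and loss rate q₁₀:

   P(t) = [[1, 0], [0, 1]] + (1 − e^(−(q₀₁+q₁₀)t)) / (q₀₁+q₁₀) ·
   [[−q₀₁, q₀₁], [q₁₀, −q₁₀]]

   Family likelihoods are computed by Felsenstein pruning; rates are
   estimated by maximum likelihood or sampled by MCMC under gamma priors
   (optionally with sampled hyperparameters). Each retained MCMC cycle
   contributes the exact marginal probability that the target ancestral node
   carried the family; the cycle average is the posterior presence
   probability, and families above a threshold (default 0.5) form the
   reconstructed gene complement. Linear regressions of gene count and
   genome size on family count across extant genomes extrapolate the
   ancestor's genome size with 95% prediction intervals.

Because the original genome-scale inputs (thousands of genomes and their
annotations) are external, the package ships a first-class synthetic-data
module that generates species trees, gain/loss histories with recorded
internal-node truth, gene trees with genuine nested mitochondria-derived
clades plus contaminant histories, JC69 alignments, and emulated hit tables
— so every decision rule is testable against known truth.

## Worked example

```bash
premito demo --seed 1 --out demo-out
```

prints (numbers produced by this exact command):

```
[screen+scan] candidates=738 detected=24 FP=0.00% FN=0.00%
[ml] q01=0.169 q10=0.888
Ancestral gene-content reconstruction (MCMC)
==============================================
target node: mrca(T10,T11,T12,T8)
families: 150   mode: global
iterations: 4000  burn-in: 500  thinning: 5
acceptance rate: 0.302
min ESS (rates): 243
posterior presence: median 0.008  quartiles [0.002, 0.347]
families called present at threshold 0.5: 36
```

Reading the output: of 60 simulated gene families (24 truly
mitochondria-derived), the screen+scan chain recovered all 24 with no false
positives. On an independent 16-taxon presence/absence simulation (150
families, true rates q₀₁ = 0.2, q₁₀ = 0.8) the ML fit recovers the rates,
and the MCMC assigns each family a posterior probability of presence at the
chosen ancestral node; 36 families exceed the 0.5 call threshold. With a loss
rate four times the gain rate most families are absent at any given node,
hence the low median posterior.

The same stages are available as a library:

```python
from premito import GainLossModel, McmcConfig, simulate

tree = simulate.simulate_species_tree(30, seed=5)
matrix, truth = simulate.simulate_presence_absence(tree, 0.2, 0.8, 1000, seed=7)
model = GainLossModel(matrix, tree)            # statsmodels-style model object
ml = model.fit()                               # maximum-likelihood rates
res = model.fit_mcmc([["T1", "T2"]],           # target = MRCA of these leaves
                     McmcConfig(iterations=12_000, burnin=2_000, thinning=10,
                                seed=11, hyperprior=True, adapt=True),
                     mode="global", ml_results=ml)
print(res.summary())
called, n = res.call_content(threshold=0.5)
```

Other subcommands: `premito simulate` (write a synthetic benchmark set),
`premito screen` / `premito scan` (run single stages on hit tables and
newick trees), `premito benchmark` (score the pipeline against generator
truth), `premito ancestor` (MCMC reconstruction from a matrix TSV and a
species tree). Every run writes a `manifest.json` recording its
configuration and seed.

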
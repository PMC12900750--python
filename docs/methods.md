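# Methods

This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic cohort does and does not
establish about real data.

## Synthetic cohort model

Counts are negative binomial with mean μ and dispersion φ
(variance μ + φμ²; φ = 0.1 by default, shared across genes).  Gene
baselines are log-normal: log μ ~ N(log 100, 1), a realistic spread of
bulk expression over a 2000-gene simulated transcriptome.  The
transcriptome size is a design choice: it is large enough for the DEG
screen's multiplicity behaviour to be visible while keeping the
conditional exact test's enumeration cheap.

Cases carry the planted dichotomous hub signature: four
erythroid/inflammatory genes up and four neurotrophic/remodeling genes
down, each at |log₂FC| = 2 (case-group mean multiplied by 2^FC; the NB
marginal is preserved exactly because counts are produced by quantile
transform).  Severity is an integer HAMD-17 score drawn uniformly on
19–33 (cases) and 0–6 (controls); ages are uniform on 12–17 and the sex
split is 8/7 vs 7/8, mirroring a matched design.

Gene–severity rank correlations are planted through a Gaussian copula:
the HAMD latent normal z and a gene's latent normal share correlation
ρ* = 2 sin(πρ_s/6) (the exact latent-Pearson ↔ Spearman map for
bivariate normals), and the gene's count is the NB quantile of Φ(z_g).
Defaults plant IL6 at ρ_s = +0.70 and MMP9 at −0.52 on the mRNA layer.
Because both the hub effect and the group separation of HAMD also induce
marker–severity association, pooled-cohort correlations are larger than
the planted within-group ρ — this mirrors (and illustrates) the caveat
that correlating a pooled case/control cohort with a group-separated
score inflates coefficients.

Protein levels are an affine transform of the latent log₂ signal plus
N(0, 0.5) noise; a per-gene sign (default: IL6 negative) lets
transcript/protein discordance be planted.  Ct values are built as
30 − log₂(count + 1) + N(0, 0.1) against a reference gene at
20.0 ± 0.1, so planted fold changes are recoverable by 2^−ΔΔCt.

Not modelled: read-level artifacts, batch effects, library-preparation
biases, and cell-type composition shifts (e.g. erythroid contamination
of PBMC preparations).  Passing tests therefore demonstrate the
statistical machinery under the assumed NB/copula model, not robustness
to those real-data failure modes.

## Differential expression

The two-group screen is a conditional exact test: for gene g with group
sums (S₁, S₂) and total T, the splits s = 0..T are weighted by
f₁(s)·f₂(T−s) where f_g is the pmf of a sum of n_g NB variables
(NB(n_g μ, n_g/φ)); the two-sided p-value sums the normalized weights of
every split no more probable than the observed one, which at φ = 0
reduces exactly to a binomial split test.  Unequal library sizes are
first equalized by scaling each sample to the geometric-mean library
size and rounding; exactness is then approximate, as with any
pseudo-count equalization.  Dispersion is a pooled method-of-moments
estimate φ̂ = max(0, (s² − m̄)/m̄²) on the equalized counts — noisy at
n = 15 per group but unbiased enough that the null type-I error at
α = 0.05 stays near nominal (measured ≈ 0.06 across seeded null
cohorts).  DEG calls use nominal p-values by design (the screen is a
discovery filter feeding a network stage); a Benjamini–Hochberg column
is available behind a flag.  The fold-change threshold defaults to
|log₂FC| > 1 with a prior count of 0.5 in both group means; thresholds
are strict inequalities.

## Network hubs

Subgraph centrality is computed exactly from the eigendecomposition
A = VΛVᵀ as SC(i) = Σ_j V²ᵢⱼ e^{λⱼ}; it is ≥ 1 for every node and the
ranking breaks ties lexicographically on the node id, making the top-k
set deterministic.  MCODE follows the published definition: a vertex is
weighted by k·density of the highest k-core of its closed neighborhood;
complexes grow greedily from the highest-weight unvisited seed,
admitting neighbors with weight > (1 − VWP)·w(seed) (VWP = 0.2, the
common plugin default); complexes lacking a 2-core are discarded;
haircut iteratively strips singly-connected members; fluff optionally
adds dense-neighborhood boundary vertices.  Each vertex belongs to at
most one complex and every tie-break is lexicographic, so the output is
invariant to input ordering.  Consensus hubs are the top-25 centrality
nodes that are also complex members, ordered by centrality.

The pipeline consumes a pre-built edge list (2-column TSV or SIF).  When
run fully synthetically it builds a planted interaction network — a hub
clique inside sparse Erdős–Rényi noise (mean degree 3) over the DEG
space — which emulates the one structural property the hub stage relies
on: a dense core module embedded in a sparse background.

## Clinical statistics

Group comparisons are gated on Shapiro–Wilk normality in both groups
(α = 0.05): Welch's unequal-variance t-test when both pass, otherwise a
two-sided Mann–Whitney U with tie correction (asymptotic by default,
exact available).  The 2×2 demographic test uses the Yates-corrected
χ² = Σ (max(|O−E| − 0.5, 0))²/E; the clamp matters — a matched 8/7 vs
7/8 sex table has |O−E| = 0.5 everywhere and yields exactly χ² = 0,
p = 1, which the uncorrected statistic would not.  Partial Spearman
correlation rank-transforms every variable (sex coded 0/1, then ranked
like any covariate), residualizes the x- and y-ranks on the covariate
ranks with an intercept, and tests the residual Pearson r with
t on n − 2 − k degrees of freedom; with k = 0 this is exactly Spearman's
ρ, and with one covariate it matches the closed-form recursion
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r²_xz)(1−r²_yz)).

## Machine-learning consensus

All features are z-scored internally.  The three selectors:

1. **LASSO stability selection.**  λ is tuned once on the full data by
   LOOCV binomial deviance over a 40-point log-spaced path from λ_max
   down three decades, then held fixed across B = 100 bootstraps drawn
   with replacement *within each class* (each resample keeps 15 vs 15).
   The deviance curve's *one-standard-error* point is the default λ: the
   minimizer is systematically too permissive here, letting chance-
   correlated noise features into > 60% of bootstraps, which defeats the
   purpose of a stability filter; the 1-SE rule is the standard
   parsimony convention for cross-validated lasso paths and behaves
   markedly better on planted-signal simulations.  ``lambda_rule="min"``
   and per-bootstrap re-tuning remain available.  A feature is stable if
   selected in strictly more than 60% of bootstraps.
2. **SVM-RFE + LOOCV.**  A linear soft-margin SVM (C = 1) repeatedly
   drops the feature with the smallest w²; the LOOCV accuracy at each
   subset size recomputes the elimination ranking inside each fold, so
   no information from the held-out sample reaches the ranking (the
   optimistic non-nested variant exists for comparison).  The optimal
   size maximizes the accuracy curve, ties resolved to the *smallest*
   size; the reported subset is the full-data ranking truncated there.
3. **Random forest.**  2000 CART trees, √p features per split, Gini
   impurity; importance is the per-tree unnormalized impurity decrease
   averaged over trees (the mean-decrease-Gini convention).  The default
   selection rule keeps every feature with importance > 0 — permissive
   on purpose, since a forest almost never assigns exactly zero to an
   informative feature, and the consensus intersection provides the
   actual filtering.

The panel is the exact three-way intersection in candidate order.  The
panel's logistic model carries a small L2 stabilizer (λ = 10⁻⁴) so the
fit converges even under complete separation; AUC is the Mann–Whitney
pair statistic (ties count ½).  The permutation test refits the
logistic model on B = 1000 permuted label vectors and reports
p = (1 + #{AUC\* ≥ AUC})/(1 + B), whose floor 1/(B+1) ≈ 0.000999 is the
smallest value the design can report.  Re-running the *entire* selection
per permutation is a config option; the default permutes around the
fixed panel, the cheaper and more common practice.

### Panel instability at n = 30

Simulations with three planted discriminative genes (standardized
effect 2.0) among eight candidates show the consensus recovers the exact planted trio only
in a minority of replicates: the LOOCV accuracy curve saturates at small
subset sizes, so the ties-to-smallest rule frequently truncates the
SVM-RFE subset below three, and bootstrap selection noise occasionally
pushes a noise feature over the 60% stability threshold.  The null
behaviour is clean (an empty panel in essentially all no-signal
replicates), but *which* informative genes survive the intersection is
highly seed-dependent.  This is a property of the design at this sample
size, documented deliberately rather than patched away; it is the
quantitative face of the usual warning that small-cohort panel
selections need external validation.

## Determinism and seeds

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds (< 2³¹) from one master seed via a seed sequence, logs
them, and records them in `report.json`.  Identical config + master seed
reproduces `report.json` byte-for-byte.  Problem sizes used by the test
suite (cohorts of 150–500 genes, 20-seed replicate batches, B = 200
permutations where full calibration curves are needed) are scaled-down
versions of the defaults chosen to keep the suite's Monte-Carlo error
well inside the asserted margins.

## Known limitations

- The exact test's library-size equalization is approximate for very
  unbalanced libraries; no TMM-style compositional normalization.
- Dispersion estimation has no empirical-Bayes shrinkage; per-gene
  method-of-moments only.
- MCODE parameter semantics follow the published algorithm; other
  plugin implementations differ in small post-processing details.
- The pooled-cohort partial correlations inherit the inflation discussed
  above; within-group correlation analysis is the conservative
  alternative.
- The generator does not model cell-composition or batch structure, so
  pipeline performance here is an upper bound on real-data behaviour.
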
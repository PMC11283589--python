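# Methods

## Scope and data model

`omicsfuse` clusters one cohort observed through several aligned
feature × subject omics blocks and characterises the resulting subgroups.
Blocks are either `continuous` (transcriptomics, GSVA pathway scores,
proteomics) or `counts` (16S and metagenomic taxa tables). Healthy controls
travel with the dataset but are excluded from clustering; they serve as the
reference group in differential comparisons. Subject order is canonicalised
by sorted ID at load time so block alignment is order-independent.

## Fusion and clustering

**Distances.** Continuous blocks use Euclidean distance on z-scored
features (the z-scoring prevents high-variance features from dominating; it
can be disabled via `standardize=False`). Count blocks use presence/absence
beta diversity: the *m* index `(2a+b+c)(b+c)/(a+b+c)` for 16S-style tables
and the *−2* index `min(b,c)/(max(b,c)+a)` for metagenomic tables, following
the community-ecology definitions of these one-letter indices. Both are 0
for identical presence patterns; *m* is unbounded above (the affinity
kernel's locally adaptive bandwidth absorbs the scale).

**Affinity kernel.** `W(i,j) = exp(−D²/(μ·ε))` with
`ε(i,j) = (mean K-NN distance of i + mean K-NN distance of j + D(i,j))/3`,
defaults `K = 20`, `μ = 0.5`. K-NN ties are broken by subject-ID order for
determinism.

**SNF.** Status matrices are the half-row-normalised affinities (diagonal
1/2, off-diagonal rows summing to 1/2); the sparse kernels are row-normalised
K-NN restrictions. Each of `T = 50` iterations updates every view by
`S_v · mean(P_u, u≠v) · S_vᵀ`, then re-symmetrises as `(P+Pᵀ)/2` and
re-normalises (a standard stabilisation). The fused network is the
symmetrised mean of the final status matrices. Fusion is invariant to view
order; with a single view the same diffusion operator is applied to that
view alone.

**Clustering.** Spectral clustering takes the top-k eigenvectors of the
symmetric normalised affinity, row-normalises them and runs k-means with 10
restarts. The GMM route fits a diagonal-covariance Gaussian mixture (5
restarts, EM re-seeded on degenerate fits) on the same spectral embedding —
the natural "fused-network-derived vectors". Disconnected networks with
more components than k are rejected with the component sizes.

**Consensus.** Each replicate subsamples 80% of subjects without
replacement, recomputes every block's affinity and the fusion on the
subsample (full-cohort distance matrices are computed once and sliced — a
pure speed optimisation, since pairwise distances do not depend on the
subsample), clusters at every k, and tallies co-clustering over co-sampling.
`M_k = co-cluster / co-sample` (0/0 → 0, diagonal 1 where sampled).
Consensus labels come from average-linkage hierarchical clustering of
`1 − M_k` cut at k. Defaults: 100 replicates (scaled-down from the common
1000-replicate convention to keep desk-scale runs in minutes; configurable),
fraction 0.8.

**Choosing k.** The area `A(k)` under the empirical CDF of the
upper-triangle consensus values is integrated with a left-Riemann rule
(so an all-ones consensus matrix has area 0); `Δ(2) = A(2)` and
`Δ(k) = (A(k) − A(k−1))/A(k−1)` thereafter. For every k and each of the
seven non-empty unions of the three omics types, the ARI between the
spectral and GMM consensus labellings is computed, sharing subsample draws
and fused networks between the two methods. Candidate k are those whose
consensus CDF has stabilised (`|Δ(k+1)| < 0.05`, measured on the all-blocks
combination with the two methods' areas averaged; the threshold is
configurable, and if no k qualifies all are candidates). Among candidates
the highest mean ARI wins; ties (within 1e-6) break to the lowest
across-combination ARI variance, then the smallest k. Final labels are the
spectral consensus labels of the all-blocks combination at the chosen k.

## Enrichment scoring (GSVA)

Per feature, a Gaussian-kernel CDF statistic across subjects with bandwidth
`sd/4`; per subject, features are ranked by the statistic and symmetrised as
`|p/2 − rank|`; a weighted KS-like walk (weight exponent τ = 1) steps up at
set members (weights normalised within the set) and down by `1/(p − m)`
elsewhere, in decreasing-statistic order. The default score is the maximum
deviation from zero (`mode="max_deviation"`); the two-tail difference
variant (`mode="diff"`) is available. Sets with fewer than 3 members in the
block are dropped and reported. A set covering every block feature has no
down-steps and scores identically across subjects — a degenerate input the
caller should avoid. Constant features must be removed upstream (the
zero-variance filter); a Poisson-kernel variant for counts is deliberately
not provided because count blocks never enter GSVA in this workflow.

Note that a constant shift of one subject's column does **not** leave that
subject's scores unchanged: the kernel-CDF statistic is bandwidth-dependent
per feature, so cross-feature ranks can reorder. Only subject-permutation
equivariance is guaranteed (and tested).

## Differential statistics

Cluster-vs-rest and cluster-vs-healthy set comparisons use two-sided
Mann–Whitney U per set; within one group comparison the p-values of **all**
sets from **all** datasets are pooled before one Benjamini–Hochberg
adjustment, with significance at q < 0.05. Because enrichment scores are
signed, effect size is reported as the median ES difference (a fold-change
is ill-defined for signed scores). Clinical variables route through a
Shapiro–Wilk gate at α = .05 — pairwise Welch t-tests when normal, otherwise
Mann–Whitney — and categorical variables use Pearson's chi-squared without
continuity correction; summaries mirror the median (IQR) / n (%) convention.
Covariate-adjusted differential analysis fits `feature ~ group + covariates`
by OLS per feature and reports the group coefficient with BH adjustment;
exactly collinear covariates are rejected by name.

## Microbiome metrics

GMPR size factors: `s_j = exp(mean_k log median_i c_ij/c_ik)` over taxa
positive in both subjects, rescaled to geometric mean 1; a subject pair
sharing no positive taxon is an error naming the pair. Shannon α-diversity
is `−Σ p ln p` in nats (base configurable); it is computed on raw counts
since per-subject proportions are scale-invariant. Differential abundance
applies Kruskal–Wallis (Mann–Whitney for two groups) per taxon on
GMPR-normalised counts with BH adjustment. A nonparametric test on
normalised counts is used rather than a negative-binomial GLM: the
within-cohort comparisons in this workflow are rank-based by design, and
the NB machinery adds assumptions the synthetic conditions do not need.

## Pathway integration

Brown's method per gene: `X = −2 Σ ln p` across datasets, `E[X] = 2m`,
`Var(X) = 4m + 2 Σ_{i<j} cov(−2 ln p_i, −2 ln p_j)` with covariances
estimated empirically across genes (the Kost–McDermott polynomial is noted
as future work); combined p is the upper tail of the scaled chi-squared
`X/c` at `df' = 2E²/Var`. Zero dependence reduces exactly to Fisher's
method. Genes below the combined threshold (default 0.1, configurable, as is
the background universe) form the query for an upper-tail hypergeometric
test per pathway, BH-adjusted; significant pathways are annotated with the
datasets whose single-omics evidence would support them alone.

## Drug repurposing (N method)

Four signature enrichment scores per subject — disease-down, disease-up,
drug-up, drug-down. A responder satisfies all four θ-inequalities
(`disease_down < θ < disease_up` and `drug_up < θ < drug_down`; θ = 0 by
default since GSVA scores are approximately centred, with a cohort-median θ
option because the decision boundary is not canonical). The same rule
applies to a cluster's mean-ES profile, whose ordered plot traces an "N"
for a responder cluster. The N-score
`[ES(disease_up) − ES(disease_down)] + [ES(drug_down) − ES(drug_up)]`
summarises pattern strength; the responder flag is invariant to uniform
positive rescaling of the four scores.

## Feature signatures

Nearest-shrunken-centroid models standardise class centroids as
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s₀))` with `m_k = sqrt(1/n_k − 1/n)` and
`s₀` the median pooled within-class SD, soft-threshold them by Δ, and
classify with the shrunken-centroid discriminant including log-prior terms.
Δ is chosen by stratified 10-fold cross-validation (fold count clipped to
the smallest class); ties in CV error break to the largest Δ — the standard
parsimony convention. On cleanly separable synthetic data the zero-error
plateau is wide, so this rule deliberately prunes the weakest planted
markers (recovery ≈ three quarters of planted features at a 2-SD effect,
with no decoy leakage); callers wanting maximal sensitivity can pass an
explicit `delta_grid`. Per-cluster signatures are the features with positive
shrunken contrast (one-vs-rest, positive class = the target cluster),
ranked by weight.

Signature matrices join into a Spearman correlation network keeping edges
with `r > 0.4` (signed, as is conventional for co-abundance displays; an
absolute-value option exists but is off by default). Communities come from
short-random-walk agglomeration (walktrap, walk length 4), deterministic
given ID-ordered input; edgeless graphs yield singletons.

## Synthetic cohort

The generator emulates the study conditions end to end: 72 asthmatic
subjects in five planted clusters of sizes 20/12/18/12/10 plus 13 healthy
controls, observed through six blocks (300 genes, a GSVA pathway block
computed from the synthetic transcriptomics — preserving the real pipeline's
dependency structure rather than simulating pathway scores independently —
150 + 120 proteins, 80 + 100 taxa).

* Continuous blocks are standard Gaussian with cluster-specific mean shifts
  of `effect_size` (default 2.0 SD) on planted marker sets (20 genes /
  15 proteins per cluster). Cluster 3's gene set is the T2/eosinophilic
  panel; clusters 2 and 4 carry distinct neutrophil signatures; cluster 4
  additionally carries the four disease/drug signature sets with the
  responder orientation (disease-up ↑, disease-down ↓, drug-up ↓,
  drug-down ↑, 15 genes each).
* Count blocks are gamma-Poisson (negative-binomial, dispersion 0.5)
  compositional counts with log-normal library sizes (median ≈ 30k). Two
  pathogen taxa sit at half the average abundance everywhere but are
  amplified by `exp(2.2 · effect)` in cluster 2, so they dominate the
  composition and depress Shannon diversity there; each cluster also gets
  six indicator taxa that are near-absent at baseline (10⁻⁴ of average
  abundance) and amplified by `exp(2.6 · effect)` in their cluster, giving
  the presence/absence beta-diversity metrics a cluster signal. All planted
  count effects scale with `effect_size`, so `effect_size = 0` produces
  fully exchangeable blocks.
* Clinical covariates are drawn conditionally on cluster: log-normal sputum
  eosinophil % with a cluster-3 shift, elevated sputum neutrophil % in
  clusters 2 (strongly) and 4, BMI slightly raised in cluster 4, and a
  severity mix leaning mild/moderate in clusters 1 and 5.

Everything derives from a single seeded generator, so a config is
byte-reproducible. What the synthetic cohort does **not** emulate: real
feature correlation structure (features are independent given cluster),
batch or platform effects, missingness (off by default), probe-level
microarray artefacts, and taxonomic phylogeny. Tests passing on this cohort
therefore demonstrate the machinery's correctness and its behaviour under
the stated effect sizes — not performance on real sputum data.

## Problem sizes and numerical choices

Default desk-scale runs use the full 72 + 13 cohort with 100 consensus
replicates; the complete model-selection scan (7 combinations × 2 methods ×
k = 2..8) runs in about two minutes on one CPU. Unit tests use a
proportionally scaled cohort (sizes 8/6/8/6/5). Other numerics: kernel
bandwidth floor at the smallest positive float; EM regularisation
`reg_covar = 1e-8`; p-values of exactly 0 entering Brown's method are
clamped to 1e-300 with a warning; consensus 0/0 cells are 0; ARI ties in
selection use a 1e-6 tolerance. All stochastic steps take explicit seeds and
the pipeline logs seed, parameters and package version.
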
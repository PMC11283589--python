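# omicsfuse

Multi-omics patient endotyping by Similarity Network Fusion (SNF) and Monti
consensus clustering, with the downstream characterisation toolkit a sputum
multi-omics asthma study needs: GSVA enrichment scoring, differential
pathway/abundance statistics, Brown's-method pathway integration,
GMPR/Shannon microbiome metrics, nearest-shrunken-centroid signatures, and a
four-signature drug-repurposing rule ("N method").

The package is aimed at systems-biology analysts who have several aligned
feature × subject omics blocks for one cohort — e.g. transcriptomics, a
GSVA pathway-score block, two proteomics panels, and 16S/metagenomic count
tables — and want robust, reproducible patient subgroups plus the statistics
to characterise them. A fully synthetic cohort generator makes every stage
testable without access data.

## The core model

Each omics block `X_v` (features × subjects) yields a subject distance
matrix — Euclidean on z-scored features for continuous blocks, the
presence/absence beta-diversity indices *m* and *−2* (with `a` shared taxa
and `b`, `c` taxa unique to either sample):

    m  = (2a + b + c)(b + c) / (a + b + c)
    −2 = min(b, c) / (max(b, c) + a)

for the count blocks. Distances become affinities through the scaled
exponential kernel

    W(i,j) = exp( −D(i,j)² / (μ · ε(i,j)) ),
    ε(i,j) = [ mean_K(i) + mean_K(j) + D(i,j) ] / 3,

with `K = 20` neighbours and `μ = 0.5`. SNF cross-diffuses the per-block
affinities for `T = 50` iterations — each view's status matrix is updated as
`P_v ← S_v · mean(P_u, u≠v) · S_vᵀ` with `S_v` the row-normalised K-NN
kernel — into one fused subject network.

Monti consensus clustering subsamples 80% of subjects 100 times, recomputes
affinities and fusion on each subsample, clusters (spectral normalised cuts
or a Gaussian mixture on the spectral embedding), and records the fraction
of co-sampled runs in which each pair co-clusters (`M_k`). The cluster
number is chosen where the relative change Δ(k) of the area under the
consensus CDF is small and the two clustering methods agree (highest mean
adjusted Rand index across the seven data-type combinations, ties broken by
the lowest across-combination variance, then the smallest k).

Downstream, GSVA scores gene sets per subject by a Gaussian-kernel-CDF /
weighted-KS random walk; cluster contrasts use Mann–Whitney U with
Benjamini–Hochberg pooling across all sets and datasets per comparison;
microbiome blocks get GMPR size factors and Shannon α-diversity; Brown's
method combines dependent per-gene p-values ahead of a hypergeometric
pathway test; and the N method flags likely drug responders when the four
signature enrichment scores satisfy
`ES(disease_down) < 0 < ES(disease_up)` and `ES(drug_up) < 0 < ES(drug_down)`.

## Worked example

```python
from omicsfuse import SimulationConfig, generate_dataset, select_optimal_k
from omicsfuse import adjusted_rand_index

dataset, truth = generate_dataset(SimulationConfig(rng_seed=1))
report = select_optimal_k(dataset, k_range=range(2, 9), reps=100, seed=1)
print("chosen k:", report.chosen_k)
print("mean ARI per k:")
print(report.mean_ari.round(3))
print("ARI vs planted labels:",
      adjusted_rand_index(report.final_labels,
                          truth.labels.loc[report.final_labels.index]))
```

prints

```
chosen k: 5
mean ARI per k:
k
2    1.000
3    0.910
4    0.995
5    1.000
6    0.978
7    0.973
8    0.916
Name: ari, dtype: float64
ARI vs planted labels: 1.0
```

The generator plants five clusters of sizes 20/12/18/12/10 among 72
asthmatic subjects; the selection rule lands on k = 5 because the consensus
CDF stabilises there while the spectral and GMM consensus labellings still
agree perfectly across all seven block combinations, and the final labels
recover the planted partition exactly (ARI = 1.0).

The same workflow is available from the shell:

```sh
omicsfuse simulate --seed 1 --out-dir data/
omicsfuse select-k --seed 1 --k-range 2 8 --out-dir results/
omicsfuse report --seed 1 --out-dir results/        # full pipeline
```

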
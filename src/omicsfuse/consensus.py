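"""Monti consensus clustering around SNF, with ARI/CDF cluster-number selection.

For each candidate k, subjects are repeatedly subsampled without
replacement; per-block affinities and the fused network are recomputed on
each subsample, clustered (spectral normalised-cuts or a Gaussian mixture on
the spectral embedding), and co-clustering is tallied. The consensus matrix
M_k(i,j) is the fraction of co-sampled runs in which i and j co-clustered.
Consensus labels come from average-linkage hierarchical clustering of
1 - M_k. The cluster number is chosen where the relative change of the
consensus-CDF area is small and the two clustering methods agree (high ARI)
consistently across data-block combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .affinity import (
    DistanceMatrix,
    FusedNetwork,
    default_metric,
    distance_matrix,
    scaled_exp_kernel,
    snf_fuse,
)
from .containers import MultiOmicsDataset, OmicsFuseError

SPECTRAL = "spectral"
GMM = "gmm"

#: the three omics types and the blocks that realise each
TYPE_BLOCKS = {
    "transcriptomics": ("transcriptomics", "pathways"),
    "proteomics": ("somascan_proteomics", "shotgun_proteomics"),
    "microbiome": ("microbiome_16s", "metagenomics"),
}


@dataclass
class ClusterAssignment:
    labels: pd.Series  # subject -> 1..k
    k: int
    method: str
    combo: str = ""


@dataclass
class ConsensusResult:
    subjects: pd.Index
    consensus: dict  # k -> n x n consensus matrix (np.ndarray)
    cosample: np.ndarray  # n x n co-sampling counts
    labels: dict  # k -> pd.Series consensus labels
    reps: int
    subsample_fraction: float
    method: str
    combo: str = ""


@dataclass
class KSelectionReport:
    table: pd.DataFrame  # columns: k, combo, ari
    mean_ari: pd.Series  # per k
    ari_variance: pd.Series  # per k, across combos
    delta_area: pd.Series  # per k
    areas: pd.Series  # per k
    chosen_k: int
    final_labels: pd.Series = field(default=None)


def adjusted_rand_index(labels1, labels2) -> float:
    """Chance-corrected agreement between two partitions of the same subjects."""
    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    if l1.shape != l2.shape:
        raise OmicsFuseError("label vectors differ in length")
    return float(adjusted_rand_score(l1, l2))


def spectral_embedding(w: np.ndarray, dim: int) -> np.ndarray:
    """Top eigenvectors of the symmetric normalised affinity (row-normalised)."""
    d = w.sum(axis=1)
    d[d == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(d)
    sym = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2)
    return vecs[:, ::-1][:, :dim]  # eigenvectors of largest eigenvalues


def _row_normalise(u: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return u / norms


def _check_connected(w: np.ndarray, k: int) -> None:
    n_comp, comp = connected_components((w > 0).astype(np.int8), directed=False)
    if n_comp > k:
        sizes = np.bincount(comp).tolist()
        raise OmicsFuseError(
            f"fused network has {n_comp} connected components (sizes {sizes}) "
            f"but k={k}; increase K or check the inputs"
        )


def _as_matrix(w) -> tuple:
    if isinstance(w, FusedNetwork):
        return w.values.to_numpy(dtype=float), w.values.columns
    if isinstance(w, pd.DataFrame):
        return w.to_numpy(dtype=float), w.columns
    arr = np.asarray(w, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def spectral_cluster(w, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalised-cuts spectral clustering of a fused network."""
    arr, ids = _as_matrix(w)
    if k < 2:
        raise OmicsFuseError("k must be >= 2")
    _check_connected(arr, k)
    u = _row_normalise(spectral_embedding(arr, k))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(u)
    return ClusterAssignment(pd.Series(km.labels_ + 1, index=ids), k, SPECTRAL)


def gmm_on_embedding(w, k: int, seed: int = 0, max_restarts: int = 5) -> ClusterAssignment:
    """Gaussian mixture (diagonal covariance) on the spectral embedding."""
    arr, ids = _as_matrix(w)
    if k < 2:
        raise OmicsFuseError("k must be >= 2")
    u = spectral_embedding(arr, k)
    last_err = None
    for attempt in range(max_restarts):
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=5,
                random_state=seed + attempt,
                reg_covar=1e-8,
            ).fit(u)
            return ClusterAssignment(pd.Series(gm.predict(u) + 1, index=ids), k, GMM)
        except Exception as err:  # degenerate EM fit: reseed and retry
            last_err = err
    raise OmicsFuseError(f"GMM failed after {max_restarts} restarts: {last_err}")


def combo_blocks(dataset: MultiOmicsDataset, combo) -> list:
    """Resolve a combination of omics types (or block names) to blocks."""
    names = []
    for item in combo:
        if item in TYPE_BLOCKS:
            names.extend(b for b in TYPE_BLOCKS[item] if b in dataset.block_names)
        elif item in dataset.block_names:
            names.append(item)
        else:
            raise OmicsFuseError(f"unknown omics type or block {item!r}")
    if not names:
        raise OmicsFuseError("combination resolves to no blocks")
    return [dataset.block(n) for n in names]


def type_combinations(types=("transcriptomics", "proteomics", "microbiome")) -> list:
    """The 2^t - 1 non-empty unions of the omics types (7 for three types)."""
    combos = []
    for r in range(1, len(types) + 1):
        combos.extend(itertools.combinations(types, r))
    return combos


def _precompute_distances(dataset: MultiOmicsDataset, blocks, standardize=True):
    subjects = dataset.asthmatic_subjects
    out = []
    for block in blocks:
        sub = block.subset_subjects(subjects)
        out.append(distance_matrix(sub, default_metric(sub), standardize=standardize).values.to_numpy())
    return subjects, out


def _fuse_subsample(dists, idx, K, mu, T):
    affs = []
    for d in dists:
        dm = pd.DataFrame(d[np.ix_(idx, idx)])
        affs.append(scaled_exp_kernel(DistanceMatrix(dm, "precomputed"), K=K, mu=mu))
    return snf_fuse(affs, K=K, T=T).values.to_numpy()


def _consensus_from_counts(cocluster, cosample):
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    m = (m + m.T) / 2
    np.fill_diagonal(m, np.where(np.diag(cosample) > 0, 1.0, 0.0))
    return m


def consensus_labels(m: np.ndarray, k: int, subjects) -> pd.Series:
    """Average-linkage hierarchical clustering of 1 - M, cut at k."""
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return pd.Series(fcluster(z, t=k, criterion="maxclust"), index=subjects)


def run_consensus(
    dataset: MultiOmicsDataset,
    combo,
    k_range,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    method: str = SPECTRAL,
    seed: int = 0,
    K: int = 20,
    mu: float = 0.5,
    T: int = 50,
) -> ConsensusResult:
    """Monti consensus clustering of one data combination with one method."""
    results = _consensus_multi(
        dataset, combo, k_range, reps, subsample_fraction, [method], seed, K, mu, T
    )
    return results[method]


def _consensus_multi(
    dataset, combo, k_range, reps, subsample_fraction, methods, seed, K, mu, T
):
    """Consensus runs sharing subsample draws and fused networks across methods."""
    if reps < 2:
        raise OmicsFuseError("reps must be >= 2")
    if not (0 < subsample_fraction < 1):
        raise OmicsFuseError("subsample fraction must be in (0, 1)")
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in k_range):
        raise OmicsFuseError("k must be >= 2")
    blocks = combo_blocks(dataset, combo)
    subjects, dists = _precompute_distances(dataset, blocks)
    n = len(subjects)
    m_sub = int(round(subsample_fraction * n))
    if m_sub <= K + 1:
        raise OmicsFuseError(
            f"subsample of {m_sub} subjects is too small for K={K} neighbours; "
            "use a smaller K"
        )
    rng = np.random.default_rng(seed)
    cosample = np.zeros((n, n))
    coclust = {meth: {k: np.zeros((n, n)) for k in k_range} for meth in methods}
    kmax = max(k_range)
    for rep in range(reps):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        cosample[np.ix_(idx, idx)] += 1
        fused = _fuse_subsample(dists, idx, K, mu, T)
        emb_full = spectral_embedding(fused, kmax)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        for k in k_range:
            emb = emb_full[:, :k]
            for meth in methods:
                if meth == SPECTRAL:
                    km = KMeans(n_clusters=k, n_init=10, random_state=rep_seed).fit(
                        _row_normalise(emb)
                    )
                    lab = km.labels_
                else:
                    gm = GaussianMixture(
                        n_components=k, covariance_type="diag", n_init=5,
                        random_state=rep_seed, reg_covar=1e-8,
                    ).fit(emb)
                    lab = gm.predict(emb)
                same = lab[:, None] == lab[None, :]
                coclust[meth][k][np.ix_(idx, idx)] += same
    out = {}
    for meth in methods:
        consensus = {k: _consensus_from_counts(coclust[meth][k], cosample) for k in k_range}
        labels = {k: consensus_labels(consensus[k], k, subjects) for k in k_range}
        out[meth] = ConsensusResult(
            subjects=subjects,
            consensus=consensus,
            cosample=cosample.copy(),
            labels=labels,
            reps=reps,
            subsample_fraction=subsample_fraction,
            method=meth,
            combo="+".join(combo),
        )
    return out


def consensus_cdf(m: np.ndarray):
    """Empirical CDF of the upper-triangle consensus values."""
    if m.size == 0:
        raise OmicsFuseError("empty consensus matrix")
    vals = m[np.triu_indices_from(m, k=1)]
    return np.sort(vals)


def cdf_area(m: np.ndarray) -> float:
    """Left-Riemann area under the consensus CDF on [0, 1]."""
    vals = consensus_cdf(m)
    grid = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    cdf_left = np.searchsorted(vals, grid[:-1], side="right") / vals.size
    return float(np.sum(cdf_left * np.diff(grid)))


def cdf_delta_area(result: ConsensusResult):
    """Per-k CDF, area A(k) and relative change Delta(k).

    Delta(2) = A(2); Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        raise OmicsFuseError("need at least two values of k")
    areas = {k: cdf_area(result.consensus[k]) for k in ks}
    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    cdfs = {k: consensus_cdf(result.consensus[k]) for k in ks}
    return cdfs, pd.Series(areas), pd.Series(deltas)


def select_optimal_k(
    dataset: MultiOmicsDataset,
    k_range=range(2, 9),
    combos=None,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    K: int = 20,
    mu: float = 0.5,
    T: int = 50,
    stability_threshold: float = 0.05,
    ari_tol: float = 1e-6,
) -> KSelectionReport:
    """Choose the cluster number from method agreement and CDF stability.

    For every k and data combination the ARI between the spectral and GMM
    consensus labellings is computed. Candidate k are those whose consensus
    CDF area changes by less than ``stability_threshold`` when moving to
    k + 1 (measured on the all-blocks combination); among candidates the k
    with the highest mean ARI wins, ties broken by the lowest across-combo
    ARI variance, then the smallest k.
    """
    if combos is None:
        combos = type_combinations()
    combos = [tuple(c) for c in combos]
    if not combos:
        raise OmicsFuseError("empty combination list")
    k_range = sorted(set(int(k) for k in k_range))
    rows = []
    full_results = None
    full_combo = max(combos, key=lambda c: len(combo_blocks(dataset, c)))
    for i, combo in enumerate(combos):
        both = _consensus_multi(
            dataset, combo, k_range, reps, subsample_fraction,
            [SPECTRAL, GMM], seed + i, K, mu, T,
        )
        if combo == full_combo:
            full_results = both
        for k in k_range:
            ari = adjusted_rand_index(both[SPECTRAL].labels[k], both[GMM].labels[k])
            rows.append({"k": k, "combo": "+".join(combo), "ari": ari})
    table = pd.DataFrame(rows)
    mean_ari = table.groupby("k")["ari"].mean()
    ari_var = table.groupby("k")["ari"].var(ddof=0)

    _, areas_s, deltas_s = cdf_delta_area(full_results[SPECTRAL])
    _, areas_g, deltas_g = cdf_delta_area(full_results[GMM])
    areas = (areas_s + areas_g) / 2
    deltas = (deltas_s + deltas_g) / 2

    candidates = [
        k for k in k_range if (k + 1) in deltas.index and abs(deltas[k + 1]) < stability_threshold
    ]
    if not candidates:
        candidates = list(k_range)
    best_ari = max(mean_ari[k] for k in candidates)
    tied = [k for k in candidates if mean_ari[k] >= best_ari - ari_tol]
    min_var = min(ari_var[k] for k in tied)
    tied = [k for k in tied if ari_var[k] <= min_var + ari_tol]
    chosen = min(tied)

    final_labels = full_results[SPECTRAL].labels[chosen]
    return KSelectionReport(
        table=table,
        mean_ari=mean_ari,
        ari_variance=ari_var,
        delta_area=deltas,
        areas=areas,
        chosen_k=int(chosen),
        final_labels=final_labels,
    )
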
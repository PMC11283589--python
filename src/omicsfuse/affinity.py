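"""Per-block distance matrices, affinity kernels and Similarity Network Fusion.

Continuous blocks use Euclidean distance on (optionally) z-scored features.
Count blocks use presence/absence beta-diversity indices named by their
one-letter labels in the community-ecology literature: with ``a`` = taxa
present in both samples, ``b`` and ``c`` = taxa unique to either sample,

* ``m``  : (2a + b + c) * (b + c) / (a + b + c)
* ``-2`` : min(b, c) / (max(b, c) + a)

Affinities come from the scaled exponential similarity kernel
W(i,j) = exp(-D(i,j)^2 / (mu * eps(i,j))) with a locally adaptive bandwidth
eps(i,j) = (mean K-NN distance of i + mean K-NN distance of j + D(i,j)) / 3.
SNF then cross-diffuses the per-block affinities into one fused network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CONTINUOUS, COUNTS, OmicsBlock, OmicsFuseError

EUCLIDEAN = "euclidean"
BETA_M = "beta_m"
BETA_MINUS2 = "beta_minus2"

_SYM_TOL = 1e-10


@dataclass
class DistanceMatrix:
    values: pd.DataFrame  # subject x subject
    metric: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise OmicsFuseError("negative distances")
        if not np.allclose(arr, arr.T, atol=_SYM_TOL):
            raise OmicsFuseError("distance matrix not symmetric")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class AffinityMatrix:
    values: pd.DataFrame
    K: int
    mu: float

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FusedNetwork:
    values: pd.DataFrame
    K: int
    T: int
    sources: list

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns


def betadiver_pair(counts_a, counts_b, index: str) -> float:
    """Presence/absence beta diversity between two count vectors."""
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    if counts_a.shape != counts_b.shape:
        raise OmicsFuseError("count vectors differ in length")
    pa, pb = counts_a > 0, counts_b > 0
    a = int(np.sum(pa & pb))
    b = int(np.sum(pa & ~pb))
    c = int(np.sum(~pa & pb))
    if index == "m":
        tot = a + b + c
        return 0.0 if tot == 0 else (2 * a + b + c) * (b + c) / tot
    if index == "-2":
        den = max(b, c) + a
        return 0.0 if den == 0 else min(b, c) / den
    raise OmicsFuseError(f"unknown beta-diversity index {index!r}")


def _beta_distance(block: OmicsBlock, index: str) -> np.ndarray:
    present = (block.values.to_numpy() > 0).astype(np.float64)
    a = present.T @ present  # shared presence counts, n x n
    totals = present.sum(axis=0)
    b = totals[:, None] - a
    c = totals[None, :] - a
    if index == "m":
        tot = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (2 * a + b + c) * (b + c) / tot
        d[tot == 0] = 0.0
    else:  # "-2"
        den = np.maximum(b, c) + a
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.minimum(b, c) / den
        d[den == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def distance_matrix(
    block: OmicsBlock, metric: str, standardize: bool = True
) -> DistanceMatrix:
    """Pairwise subject distances for one block.

    ``euclidean`` applies to continuous blocks (features z-scored by default
    to prevent scale dominance); ``beta_m`` / ``beta_minus2`` apply to count
    blocks and work on presence/absence.
    """
    if block.n_features == 0 or block.n_subjects == 0:
        raise OmicsFuseError("empty block")
    if metric == EUCLIDEAN:
        x = block.values.to_numpy(dtype=float)
        if standardize:
            sd = x.std(axis=1, ddof=0, keepdims=True)
            if (sd == 0).any():
                raise OmicsFuseError(
                    "zero-variance feature; run filter_zero_variance first"
                )
            x = (x - x.mean(axis=1, keepdims=True)) / sd
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x.T, metric="euclidean"))
    elif metric in (BETA_M, BETA_MINUS2):
        if block.kind != COUNTS:
            raise OmicsFuseError(
                f"beta-diversity metric {metric!r} requires a counts block"
            )
        d = _beta_distance(block, "m" if metric == BETA_M else "-2")
    else:
        raise OmicsFuseError(f"unknown metric {metric!r}")
    df = pd.DataFrame(d, index=block.subject_ids, columns=block.subject_ids)
    return DistanceMatrix(df, metric)


def default_metric(block: OmicsBlock) -> str:
    """Euclidean for continuous blocks; beta indices for the count blocks
    ('m' for 16S-style tables, '-2' for metagenomic tables, by block name)."""
    if block.kind == CONTINUOUS:
        return EUCLIDEAN
    return BETA_MINUS2 if "metagenom" in block.name.lower() else BETA_M


def scaled_exp_kernel(dist: DistanceMatrix, K: int = 20, mu: float = 0.5) -> AffinityMatrix:
    """Scaled exponential similarity kernel with locally adaptive bandwidth."""
    d = dist.values.to_numpy(dtype=float)
    n = d.shape[0]
    if K >= n:
        raise OmicsFuseError(f"K={K} must be smaller than the number of subjects ({n})")
    if mu <= 0:
        raise OmicsFuseError("mu must be positive")
    # mean distance to the K nearest neighbours, excluding self
    sorted_d = np.sort(d, axis=1)
    knn_mean = sorted_d[:, 1 : K + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    eps = np.maximum(eps, np.finfo(float).tiny)
    w = np.exp(-(d**2) / (mu * eps))
    w = (w + w.T) / 2
    df = pd.DataFrame(w, index=dist.values.index, columns=dist.values.columns)
    return AffinityMatrix(df, K=K, mu=mu)


def _full_kernel_normalise(w: np.ndarray) -> np.ndarray:
    """P with off-diagonal rows summing to 1/2 and diagonal 1/2."""
    off = w - np.diag(np.diag(w))
    rowsums = off.sum(axis=1)
    rowsums[rowsums == 0] = 1.0
    p = off / (2.0 * rowsums[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _sparse_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Row-normalised K-nearest-neighbour kernel (ties broken by index order)."""
    n = w.shape[0]
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        # stable sort on -row keeps lower subject index first on ties
        nbr = np.argsort(-row, kind="stable")[:K]
        vals = w[i, nbr]
        tot = vals.sum()
        if tot > 0:
            s[i, nbr] = vals / tot
    return s


def snf_fuse(affinities: list, K: int = 20, T: int = 50, sources: list | None = None) -> FusedNetwork:
    """Fuse per-block affinity matrices by SNF cross-diffusion.

    Each view's status matrix P is iteratively updated as
    P_v <- S_v @ mean(P_u, u != v) @ S_v.T, re-normalised and symmetrised;
    the output is the symmetrised average of the final status matrices.
    """
    if not affinities:
        raise OmicsFuseError("need at least one affinity matrix")
    ids = affinities[0].values.columns
    for aff in affinities[1:]:
        if not aff.values.columns.equals(ids):
            raise OmicsFuseError("affinity matrices have mismatched subjects")
    ws = [a.values.to_numpy(dtype=float) for a in affinities]
    ps = [_full_kernel_normalise(w) for w in ws]
    ss = [_sparse_kernel(w, K) for w in ws]
    m = len(ws)
    if m == 1:
        p = ps[0]
        for _ in range(T):
            p = ss[0] @ p @ ss[0].T
            p = _full_kernel_normalise((p + p.T) / 2)
        fused = (p + p.T) / 2
    else:
        for _ in range(T):
            new_ps = []
            total = np.sum(ps, axis=0)
            for v in range(m):
                mean_others = (total - ps[v]) / (m - 1)
                p = ss[v] @ mean_others @ ss[v].T
                p = _full_kernel_normalise((p + p.T) / 2)
                new_ps.append(p)
            ps = new_ps
        fused = np.mean(ps, axis=0)
        fused = (fused + fused.T) / 2
    df = pd.DataFrame(fused, index=ids, columns=ids)
    return FusedNetwork(df, K=K, T=T, sources=list(sources) if sources else [])


def block_affinity(
    block: OmicsBlock, K: int = 20, mu: float = 0.5, standardize: bool = True
) -> AffinityMatrix:
    """Convenience: distance with the block's default metric, then the kernel."""
    return scaled_exp_kernel(
        distance_matrix(block, default_metric(block), standardize=standardize), K=K, mu=mu
    )
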
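"""Gene set variation analysis: per-subject, rank-based set enrichment scores.

The score for a set in a subject follows the kernel-CDF / weighted
Kolmogorov-Smirnov construction:

1. per feature, a Gaussian-kernel cumulative density statistic across
   subjects (bandwidth = feature SD / 4);
2. per subject, features are ranked by that statistic and the rank is
   symmetrised around the middle, r~ = |p/2 - rank|;
3. a weighted KS-like random walk over the features ordered by decreasing
   statistic, stepping up by |r~|^tau (normalised within the set) at set
   members and down by 1/(p - set size) elsewhere;
4. the enrichment score is the maximum deviation from zero of the walk
   (``max_deviation``) or the sum of the largest positive and negative
   deviations (``diff``).

Scores live in (-1, 1); sets with fewer than ``min_overlap`` members in the
block are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import CONTINUOUS, GeneSetCollection, OmicsBlock, OmicsFuseError

MAX_DEVIATION = "max_deviation"
DIFF = "diff"


@dataclass
class ESMatrix:
    """Set x subject enrichment scores plus the post-filter set sizes."""

    values: pd.DataFrame
    set_sizes: dict
    dropped: dict = field(default_factory=dict)  # set name -> overlap that failed

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns


def _kernel_cdf_statistic(x: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry within its feature row."""
    p, n = x.shape
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise OmicsFuseError(
            "constant feature in GSVA input; run filter_zero_variance first"
        )
    h = sd / 4.0
    z = np.empty_like(x, dtype=float)
    for i in range(p):
        z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
    return z


def _walk_scores(
    order: np.ndarray, rank_stat: np.ndarray, in_set: np.ndarray, tau: float, mode: str
) -> np.ndarray:
    """Enrichment scores for one set across all subjects (vectorised walk)."""
    p, n = rank_stat.shape
    m = int(in_set.sum())
    # per subject: features sorted by decreasing kernel statistic;
    # in_set is 1-D (p,), order is p x n, so fancy indexing gives p x n
    set_sorted = in_set[order]
    w = np.abs(rank_stat) ** tau
    w_sorted = np.take_along_axis(w, order, axis=0)
    inc = np.where(set_sorted, w_sorted, 0.0)
    denom = inc.sum(axis=0)
    denom[denom == 0] = 1.0
    steps = inc / denom - (~set_sorted) / max(p - m, 1)
    walk = np.cumsum(steps, axis=0)
    if mode == MAX_DEVIATION:
        idx = np.argmax(np.abs(walk), axis=0)
        return walk[idx, np.arange(n)]
    if mode == DIFF:
        return np.maximum(walk, 0.0).max(axis=0) + np.minimum(walk, 0.0).min(axis=0)
    raise OmicsFuseError(f"unknown GSVA mode {mode!r}")


def gsva_es(
    block: OmicsBlock,
    sets: GeneSetCollection,
    min_overlap: int = 3,
    mode: str = MAX_DEVIATION,
    tau: float = 1.0,
) -> ESMatrix:
    """Enrichment scores for every set with >= ``min_overlap`` block features."""
    if block.kind != CONTINUOUS:
        raise OmicsFuseError("GSVA requires a continuous block")
    if len(sets) == 0:
        raise OmicsFuseError("empty gene set collection")
    features = block.feature_ids
    feat_pos = {f: i for i, f in enumerate(features)}
    kept, dropped = {}, {}
    for name in sets.names():
        members = np.array(sorted(feat_pos[f] for f in sets[name] if f in feat_pos))
        if len(members) < min_overlap:
            dropped[name] = len(members)
        else:
            kept[name] = members
    if not kept:
        raise OmicsFuseError("all gene sets dropped by the overlap filter")

    x = block.values.to_numpy(dtype=float)
    p, n = x.shape
    z = _kernel_cdf_statistic(x)
    # rank 1 = largest statistic; symmetrise around the middle
    order = np.argsort(-z, axis=0, kind="stable")  # walk order per subject
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, p + 1)[:, None].repeat(n, axis=1), axis=0)
    rank_stat = np.abs(p / 2.0 - ranks)

    es = np.empty((len(kept), n))
    in_set = np.zeros(p, dtype=bool)
    for row, (name, members) in enumerate(kept.items()):
        in_set[:] = False
        in_set[members] = True
        es[row] = _walk_scores(order, rank_stat, in_set, tau, mode)
    df = pd.DataFrame(es, index=list(kept), columns=block.subject_ids)
    return ESMatrix(df, {name: len(m) for name, m in kept.items()}, dropped)


def score_signature_panel(
    block: OmicsBlock,
    panels: GeneSetCollection,
    labels: pd.Series,
    min_overlap: int = 3,
    mode: str = MAX_DEVIATION,
) -> dict:
    """Per-subject panel ES plus per-cluster medians and cluster-vs-rest tests."""
    from .stats import cluster_vs_rest_dep

    es = gsva_es(block, panels, min_overlap=min_overlap, mode=mode)
    unknown = set(labels.index) - set(es.subject_ids)
    if unknown:
        raise OmicsFuseError(f"labels for unknown subjects: {sorted(unknown)[:5]}")
    labelled = es.values.loc[:, labels.index]
    medians = labelled.T.groupby(labels).median().T
    medians.columns.name = "cluster"
    sub_es = ESMatrix(labelled, es.set_sizes, es.dropped)
    tests = cluster_vs_rest_dep(sub_es, labels, reference="rest")
    return {"es": es, "cluster_medians": medians, "tests": tests}
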
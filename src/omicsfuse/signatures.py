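"""Per-cluster molecular signatures and their cross-omics network.

Nearest-shrunken-centroid (NSC) classification: class centroids are
standardised against the pooled within-class spread, soft-thresholded by a
shrinkage Delta chosen by stratified 10-fold cross-validation, and the
surviving positive components form each cluster's signature. Signatures from
all blocks are then joined into a Spearman correlation network (edges with
r above a threshold) whose communities are found by short-random-walk
(walktrap-style) agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import OmicsBlock, OmicsFuseError


@dataclass
class NSCModel:
    classes: list
    overall_centroid: np.ndarray  # p
    class_centroids: np.ndarray  # p x K
    pooled_sd: np.ndarray  # p
    s0: float
    priors: np.ndarray  # K
    mk: np.ndarray  # K
    dik: np.ndarray  # p x K, unshrunken standardised differences
    delta_grid: np.ndarray
    cv_error: np.ndarray  # per delta
    chosen_delta: float
    feature_ids: pd.Index

    def shrunken_d(self, delta: float | None = None) -> np.ndarray:
        d = self.dik
        delta = self.chosen_delta if delta is None else delta
        return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

    def shrunken_centroids(self, delta: float | None = None) -> np.ndarray:
        dprime = self.shrunken_d(delta)
        return self.overall_centroid[:, None] + self.mk[None, :] * (
            (self.pooled_sd + self.s0)[:, None] * dprime
        )

    def predict(self, x: np.ndarray, delta: float | None = None) -> np.ndarray:
        """Classify columns of ``x`` (p x n) by the shrunken-centroid discriminant."""
        cent = self.shrunken_centroids(delta)
        s = (self.pooled_sd + self.s0)[:, None]
        scores = np.empty((x.shape[1], len(self.classes)))
        for k in range(len(self.classes)):
            resid = (x - cent[:, [k]]) / s
            scores[:, k] = (resid**2).sum(axis=0) - 2.0 * np.log(self.priors[k])
        return np.array([self.classes[i] for i in scores.argmin(axis=1)])


def _fit_centroids(x: np.ndarray, y: np.ndarray, classes):
    n = x.shape[1]
    overall = x.mean(axis=1)
    cents, counts = [], []
    ss_within = np.zeros(x.shape[0])
    for c in classes:
        cols = x[:, y == c]
        cents.append(cols.mean(axis=1))
        counts.append(cols.shape[1])
        ss_within += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    cents = np.column_stack(cents)
    counts = np.asarray(counts)
    pooled_sd = np.sqrt(ss_within / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    mk = np.sqrt(1.0 / counts - 1.0 / n)
    dik = (cents - overall[:, None]) / (mk[None, :] * (pooled_sd + s0)[:, None])
    priors = counts / n
    return overall, cents, pooled_sd, s0, mk, dik, priors


def nsc_fit_cv(
    block: OmicsBlock,
    labels: pd.Series,
    delta_grid=None,
    folds: int = 10,
    seed: int = 0,
) -> NSCModel:
    """Fit an NSC model and choose the shrinkage by stratified k-fold CV.

    Ties in CV error are broken towards the largest Delta (the sparsest
    surviving signature).
    """
    subjects = [s for s in labels.index if s in block.subject_ids]
    x = block.values.loc[:, subjects].to_numpy(dtype=float)
    y = labels.loc[subjects].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise OmicsFuseError("need at least two classes")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise OmicsFuseError(f"class of size 1: {counts[counts < 2].index.tolist()}")
    overall, cents, pooled_sd, s0, mk, dik, priors = _fit_centroids(x, y, classes)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, np.abs(dik).max(), 30)
    delta_grid = np.asarray(sorted(delta_grid))

    n_folds = min(folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(delta_grid))
    for train, test in skf.split(x.T, y):
        o, ce, sd, s0f, mkf, dikf, pri = _fit_centroids(x[:, train], y[train], classes)
        fold_model = NSCModel(
            classes, o, ce, sd, s0f, pri, mkf, dikf,
            delta_grid, np.zeros(len(delta_grid)), 0.0, block.feature_ids,
        )
        for i, delta in enumerate(delta_grid):
            pred = fold_model.predict(x[:, test], delta=delta)
            errors[i] += (pred != y[test]).sum()
    errors /= len(y)
    best = errors.min()
    chosen = float(delta_grid[np.where(errors <= best + 1e-12)[0].max()])
    return NSCModel(
        classes, overall, cents, pooled_sd, s0, priors, mk, dik,
        delta_grid, errors, chosen, block.values.index,
    )


def nsc_select_features(model: NSCModel, cls, contrast: str = "positive") -> pd.Series:
    """Features with positive shrunken contrast for ``cls``, ranked by weight."""
    if cls not in model.classes:
        raise OmicsFuseError(f"unknown class {cls!r}")
    k = model.classes.index(cls)
    dprime = model.shrunken_d()[:, k]
    if contrast == "positive":
        keep = dprime > 0
    elif contrast == "negative":
        keep = dprime < 0
    else:
        raise OmicsFuseError(f"unknown contrast {contrast!r}")
    sel = pd.Series(dprime[keep], index=model.feature_ids[keep])
    return sel.sort_values(ascending=False)


def correlation_network(
    signature_blocks: dict,
    r_threshold: float = 0.4,
    absolute: bool = False,
) -> nx.Graph:
    """Spearman correlation graph over signature features from several blocks.

    ``signature_blocks`` maps omics-layer name -> feature x subject frame
    (all sharing subjects). Edges keep pairs with r > threshold (or
    |r| > threshold with ``absolute=True``); nodes carry their layer.
    """
    frames, layers = [], {}
    subjects = None
    for layer, df in signature_blocks.items():
        df = df.values if isinstance(df, OmicsBlock) else df
        if (df.std(axis=1, ddof=0) == 0).any():
            bad = df.index[df.std(axis=1, ddof=0) == 0][0]
            raise OmicsFuseError(f"zero-variance feature {bad!r} in layer {layer!r}")
        subjects = df.columns if subjects is None else subjects
        frames.append(df.loc[:, subjects])
        for f in df.index:
            layers[f] = layer
    stacked = pd.concat(frames, axis=0)
    if stacked.shape[0] < 2:
        raise OmicsFuseError("need at least two features")
    corr = stacked.T.corr(method="spearman")
    g = nx.Graph()
    for f in stacked.index:
        g.add_node(f, layer=layers[f])
    feats = list(stacked.index)
    arr = corr.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = arr[i, j]
            val = abs(r) if absolute else r
            if val > r_threshold:
                g.add_edge(feats[i], feats[j], weight=float(r))
    return g


def random_walk_communities(graph: nx.Graph, seed: int = 0, steps: int = 4) -> pd.Series:
    """Walktrap-style communities (short random walks, modularity cut).

    Deterministic for a given graph; nodes in edgeless graphs become
    singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise OmicsFuseError("empty graph")
    nodes = sorted(graph.nodes())
    if graph.number_of_edges() == 0:
        return pd.Series(range(1, len(nodes) + 1), index=nodes, name="community")
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    weights = [abs(graph[u][v].get("weight", 1.0)) for u, v in graph.edges()]
    g = ig.Graph(n=len(nodes), edges=edges)
    dendrogram = g.community_walktrap(weights=weights, steps=steps)
    membership = dendrogram.as_clustering().membership
    return pd.Series(
        [m + 1 for m in membership], index=nodes, name="community"
    )
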
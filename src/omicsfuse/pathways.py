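"""Multi-omics pathway prioritisation: Brown's combination + hypergeometric test.

Per gene, p-values from several omics datasets are combined with Brown's
method — Fisher's statistic X = -2 sum ln p referred to a scaled chi-squared
whose scale and degrees of freedom come from the empirical covariance of
-2 ln p across datasets. Genes passing the combined threshold form the query
list for a hypergeometric over-representation test per pathway, with BH
adjustment and per-dataset support annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection, OmicsFuseError
from .stats import bh_fdr

P_FLOOR = 1e-300


def _clean_evidence(evidence: pd.DataFrame, p_floor: float) -> pd.DataFrame:
    arr = evidence.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise OmicsFuseError(
            "evidence p-values must lie in (0, 1]; code missing evidence as 1"
        )
    if (arr == 0).any():
        import warnings

        warnings.warn(f"p-values of exactly 0 clamped to {p_floor}", stacklevel=3)
        arr = np.maximum(arr, p_floor)
    return pd.DataFrame(arr, index=evidence.index, columns=evidence.columns)


def browns_combine(
    evidence: pd.DataFrame, dependence=None, p_floor: float = P_FLOOR
) -> pd.Series:
    """Brown's dependent-p combination per gene (rows) across datasets (columns).

    E[X] = 2m and Var(X) = 4m + 2 * sum_{i<j} cov(-2 ln p_i, -2 ln p_j),
    with the covariances estimated empirically across genes (or supplied as
    ``dependence``, a dataset x dataset covariance matrix of -2 ln p); the
    combined p is the upper tail of chi2(df') evaluated at X / c with
    c = Var/(2E), df' = 2E^2/Var. Zero dependence reduces to Fisher's method.
    """
    if evidence.shape[1] < 2:
        raise OmicsFuseError("Brown's method needs at least two datasets")
    ev = _clean_evidence(evidence, p_floor)
    neg2ln = -2.0 * np.log(ev.to_numpy())
    x = neg2ln.sum(axis=1)
    m = ev.shape[1]
    expected = 2.0 * m
    cov = np.cov(neg2ln, rowvar=False) if dependence is None else np.asarray(dependence, float)
    off_diag_sum = cov.sum() - np.trace(cov)
    variance = 4.0 * m + off_diag_sum  # 2 * sum_{i<j} cov = full off-diagonal sum
    if variance <= 0:
        variance = 4.0 * m
    c = variance / (2.0 * expected)
    df = 2.0 * expected**2 / variance
    p = sps.chi2.sf(x / c, df)
    return pd.Series(p, index=evidence.index, name="brown_p")


def hypergeom_enrichment(gene_list, pathway, background) -> float:
    """Upper-tail hypergeometric p of the observed overlap or greater."""
    background = set(background)
    gene_list = set(gene_list)
    pathway = set(pathway)
    if not gene_list <= background or not pathway <= background:
        raise OmicsFuseError("gene list and pathway must be subsets of the background")
    if len(gene_list) > len(background):
        raise OmicsFuseError("gene list larger than background")
    overlap = len(gene_list & pathway)
    return float(
        sps.hypergeom.sf(overlap - 1, len(background), len(pathway), len(gene_list))
    )


def active_pathways(
    evidence: pd.DataFrame,
    pathways: GeneSetCollection,
    threshold: float = 0.1,
    significance: float = 0.05,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Ranked pathway table from Brown-combined gene evidence.

    Genes with combined p below ``threshold`` form the query list; each
    pathway gets a hypergeometric over-representation p against the evidence
    universe, BH-adjusted. Significant pathways are annotated with the
    datasets whose single-omics evidence alone would support them at the
    same thresholds.
    """
    combined = browns_combine(evidence, p_floor=p_floor)
    background = list(evidence.index)
    query = set(combined.index[combined < threshold])
    rows = []
    for name in pathways.names():
        members = set(pathways[name]) & set(background)
        if not members:
            continue
        if query:
            p = hypergeom_enrichment(query, members, background)
        else:
            p = 1.0
        rows.append(
            {
                "pathway": name,
                "pathway_size": len(members),
                "overlap": len(query & members),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["pathway", "pathway_size", "overlap", "p", "q", "supporting_datasets"]
        )
    out["q"] = bh_fdr(out["p"].to_numpy())
    support = []
    path_members = {name: set(pathways[name]) & set(background) for name in pathways.names()}
    single_queries = {
        col: set(evidence.index[evidence[col] < threshold]) for col in evidence.columns
    }
    for _, row in out.iterrows():
        if row["q"] >= significance:
            support.append("")
            continue
        names = []
        for col, q_genes in single_queries.items():
            if q_genes and hypergeom_enrichment(
                q_genes, path_members[row["pathway"]], background
            ) < significance:
                names.append(col)
        support.append(",".join(names))
    out["supporting_datasets"] = support
    return out.sort_values(["q", "p"]).reset_index(drop=True)
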
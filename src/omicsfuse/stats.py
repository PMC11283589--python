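"""Differential enrichment, clinical-table statistics and correlations.

Numeric clinical variables are routed by a Shapiro-Wilk normality gate
(alpha = .05) to pairwise t-tests (normal) or Mann-Whitney U (non-normal);
categorical variables use Pearson's chi-squared without continuity
correction. Pathway-level comparisons use two-sided Mann-Whitney U per set,
with p-values pooled across all sets and datasets of one group comparison
before Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import OmicsBlock, OmicsFuseError
from .gsva import ESMatrix

SIGNIFICANCE = 0.05


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise OmicsFuseError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pearson_chi2(table) -> tuple:
    """Pearson chi-squared without continuity correction: (stat, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise OmicsFuseError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise OmicsFuseError("negative counts in contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise OmicsFuseError("contingency table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def spearman_corr(x, y) -> tuple:
    """Spearman rank correlation with tie handling; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise OmicsFuseError("paired vectors differ in length")
    if x.size < 4:
        raise OmicsFuseError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise OmicsFuseError("constant vector in correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _mwu(a, b) -> tuple:
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def cluster_vs_rest_dep(
    es, labels: pd.Series, reference: str = "rest", healthy_es=None
) -> pd.DataFrame:
    """Differentially enriched sets per cluster, BH-pooled per comparison.

    ``es`` may be one :class:`ESMatrix` or a list of them (one per omics
    dataset); per the pooling rule, all sets from all datasets of one group
    comparison share a single BH adjustment. ``reference="rest"`` contrasts
    each cluster against the remaining clustered subjects;
    ``reference="healthy"`` contrasts it against the columns of
    ``healthy_es`` (same sets, healthy subjects).
    """
    es_list = es if isinstance(es, (list, tuple)) else [es]
    if reference not in ("rest", "healthy"):
        raise OmicsFuseError(f"unknown reference {reference!r}")
    if reference == "healthy":
        healthy_list = healthy_es if isinstance(healthy_es, (list, tuple)) else [healthy_es]
        if healthy_list is None or any(h is None for h in healthy_list):
            raise OmicsFuseError("reference='healthy' needs healthy_es")
    rows = []
    clusters = sorted(labels.unique())
    for c in clusters:
        in_c = labels.index[labels == c]
        out_c = labels.index[labels != c]
        for d, mat in enumerate(es_list):
            block_name = getattr(mat, "name", None) or f"dataset{d + 1}"
            values = mat.values if isinstance(mat, ESMatrix) else mat
            a = values.loc[:, [s for s in in_c if s in values.columns]]
            if reference == "rest":
                b = values.loc[:, [s for s in out_c if s in values.columns]]
            else:
                b = (healthy_list[d].values if isinstance(healthy_list[d], ESMatrix)
                     else healthy_list[d])
            if a.shape[1] < 2 or b.shape[1] < 2:
                raise OmicsFuseError(
                    f"comparison for cluster {c} has a side with <2 subjects"
                )
            for set_name in values.index:
                av, bv = a.loc[set_name].to_numpy(), b.loc[set_name].to_numpy()
                stat, p = _mwu(av, bv)
                diff = float(np.median(av) - np.median(bv))
                rows.append(
                    {
                        "set": set_name,
                        "block": block_name,
                        "contrast": f"cluster{c}_vs_{reference}",
                        "cluster": c,
                        "stat": stat,
                        "p": p,
                        "median_diff": diff,
                        "direction": "up" if diff > 0 else ("down" if diff < 0 else "flat"),
                    }
                )
    out = pd.DataFrame(rows)
    # pool p-values across all sets and datasets within each group comparison
    out["q"] = np.nan
    for c in clusters:
        mask = out["cluster"] == c
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["q"] < SIGNIFICANCE
    return out


def clinical_compare(
    clinical: pd.DataFrame, labels: pd.Series, alpha: float = SIGNIFICANCE
) -> pd.DataFrame:
    """Pairwise cluster comparisons for each clinical variable.

    Numeric variables: Shapiro-Wilk gate, then pairwise t-test or
    Mann-Whitney. Categorical: Pearson chi-squared on the pairwise 2 x c
    table. One BH adjustment across all (variable, pair) comparisons.
    Summary strings are median (IQR) for numeric and n (%) for categorical.
    """
    subjects = [s for s in labels.index if s in clinical.index]
    clin = clinical.loc[subjects]
    labs = labels.loc[subjects]
    clusters = sorted(labs.unique())
    rows = []
    for var in clin.columns:
        col = clin[var]
        numeric = pd.api.types.is_numeric_dtype(col)
        if not numeric and col.nunique() < 2:
            raise OmicsFuseError(f"variable {var!r} has a single level")
        if numeric:
            vals = col.dropna()
            normal = sps.shapiro(vals).pvalue >= alpha if 3 <= len(vals) <= 5000 else False
            test_name = "t-test" if normal else "mann-whitney"
        else:
            test_name = "chi-squared"
        summaries = {}
        for c in clusters:
            v = col[labs == c].dropna()
            if numeric:
                q1, med, q3 = np.percentile(v, [25, 50, 75]) if len(v) else (np.nan,) * 3
                summaries[c] = f"{med:.3g} ({q1:.3g}-{q3:.3g})"
            else:
                top = v.value_counts().index[0] if len(v) else ""
                n_top = int((v == top).sum())
                pct = 100.0 * n_top / len(v) if len(v) else 0.0
                summaries[c] = f"{top}: {n_top} ({pct:.0f}%)"
        for c1, c2 in itertools.combinations(clusters, 2):
            v1 = col[labs == c1].dropna()
            v2 = col[labs == c2].dropna()
            if numeric:
                if normal:
                    stat, p = sps.ttest_ind(v1, v2, equal_var=False)
                else:
                    stat, p = _mwu(v1.to_numpy(), v2.to_numpy())
            else:
                levels = sorted(col.dropna().unique())
                tab = np.array(
                    [[(v == lv).sum() for lv in levels] for v in (v1, v2)], dtype=float
                )
                tab = tab[:, tab.sum(axis=0) > 0]
                if tab.shape[1] < 2:
                    stat, p = 0.0, 1.0
                else:
                    stat, _, p = pearson_chi2(tab)
            rows.append(
                {
                    "variable": var,
                    "test": test_name,
                    "cluster_a": c1,
                    "cluster_b": c2,
                    "summary_a": summaries[c1],
                    "summary_b": summaries[c2],
                    "stat": float(stat),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def covariate_adjusted_diff(
    block: OmicsBlock, group: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature linear model ``feature ~ group + covariates``.

    ``group`` must be binary (two levels); returns the group coefficient,
    its p-value and BH q per feature, ranked by q then p.
    """
    subjects = [s for s in group.index if s in block.subject_ids]
    if covariates.loc[subjects].isna().any().any():
        raise OmicsFuseError("covariates contain missing values for included subjects")
    levels = sorted(pd.Series(group.loc[subjects]).unique())
    if len(levels) != 2:
        raise OmicsFuseError("group must have exactly two levels")
    g = (group.loc[subjects] == levels[1]).astype(float).to_numpy()
    cov = pd.get_dummies(covariates.loc[subjects], drop_first=True).astype(float)
    design = np.column_stack([np.ones(len(subjects)), g, cov.to_numpy()])
    names = ["intercept", "group"] + list(cov.columns)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(design[:, 1:].T)
        for i in range(corr.shape[0]):
            for j in range(i + 1, corr.shape[1]):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise OmicsFuseError(
                        f"collinear covariates: {names[i + 1]!r} and {names[j + 1]!r}"
                    )
        raise OmicsFuseError("design matrix is rank deficient")
    y = block.values.loc[:, subjects].to_numpy(dtype=float).T  # n x p
    n, q = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y  # q x p
    resid = y - design @ beta
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta[1] / se
    pvals = 2 * sps.t.sf(np.abs(tstat), dof)
    out = pd.DataFrame(
        {
            "feature": block.feature_ids,
            "coef": beta[1],
            "t": tstat,
            "p": pvals,
            "direction": np.where(beta[1] > 0, f"up_in_{levels[1]}", f"up_in_{levels[0]}"),
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["q", "p"]).reset_index(drop=True)
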
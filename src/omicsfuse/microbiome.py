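"""Microbiome metrics: GMPR normalisation, Shannon diversity, differential abundance.

GMPR (geometric mean of pairwise ratios) gives zero-robust per-subject size
factors for sparse count tables: the factor of subject j is the geometric
mean over other subjects k of the median count ratio c_ij / c_ik over taxa
positive in both, rescaled so the factors have geometric mean 1. Shannon
alpha diversity is H = -sum p ln p in nats. Differential abundance applies
Kruskal-Wallis (or Mann-Whitney for two groups) per taxon on GMPR-normalised
counts with BH adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import COUNTS, OmicsBlock, OmicsFuseError
from .stats import bh_fdr


def gmpr_size_factors(block: OmicsBlock) -> pd.Series:
    """Per-subject GMPR size factors, rescaled to geometric mean 1."""
    if block.kind != COUNTS:
        raise OmicsFuseError("GMPR requires a counts block")
    counts = block.values.to_numpy(dtype=float)
    n = counts.shape[1]
    if n < 2:
        raise OmicsFuseError("GMPR needs at least two subjects")
    subjects = list(block.subject_ids)
    log_medians = np.full((n, n), np.nan)
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            shared = (counts[:, j] > 0) & (counts[:, k] > 0)
            if not shared.any():
                raise OmicsFuseError(
                    f"subjects {subjects[j]!r} and {subjects[k]!r} share no "
                    "positive taxa; GMPR is undefined"
                )
            log_medians[j, k] = np.log(
                np.median(counts[shared, j] / counts[shared, k])
            )
    log_s = np.nanmean(log_medians, axis=1)
    log_s -= log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=block.subject_ids, name="gmpr_size_factor")


def shannon_alpha(block: OmicsBlock, base: float = np.e) -> pd.Series:
    """Shannon diversity per subject (natural log by default)."""
    if block.kind != COUNTS:
        raise OmicsFuseError("Shannon diversity requires a counts block")
    counts = block.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = block.subject_ids[totals == 0][0]
        raise OmicsFuseError(f"subject {bad!r} has an all-zero count column")
    h = np.array([sps.entropy(counts[:, j]) for j in range(counts.shape[1])])
    if base != np.e:
        h = h / np.log(base)
    return pd.Series(h, index=block.subject_ids, name="shannon")


def diff_abundance(block: OmicsBlock, labels: pd.Series) -> pd.DataFrame:
    """Per-taxon differential abundance across clusters on GMPR-normalised counts."""
    subjects = [s for s in labels.index if s in block.subject_ids]
    sub = block.subset_subjects(subjects)
    labs = labels.loc[subjects]
    groups = sorted(labs.unique())
    if len(groups) < 2:
        raise OmicsFuseError("need at least two groups")
    sizes = labs.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise OmicsFuseError(f"groups with fewer than 2 subjects: {small}")
    factors = gmpr_size_factors(sub)
    norm = sub.values.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    masks = {g: (labs == g).to_numpy() for g in groups}
    rows = []
    for i, taxon in enumerate(sub.feature_ids):
        samples = [norm[i, masks[g]] for g in groups]
        if np.ptp(norm[i]) == 0:
            stat, p = 0.0, 1.0
        elif len(groups) == 2:
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.kruskal(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
        medians = {f"median_{g}": float(np.median(s)) for g, s in zip(groups, samples)}
        rows.append({"taxon": taxon, "stat": stat, "p": p, **medians})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["q", "p"]).reset_index(drop=True)
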
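"""Readers and writers for the plain-text formats the pipeline uses.

Matrices travel as feature x subject TSV (first column = feature ID, header
row = subject IDs), clinical tables as CSV keyed by subject ID, gene sets as
GMT, and label assignments as two-column TSV.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import COUNTS, GeneSetCollection, OmicsBlock, OmicsFuseError

log = logging.getLogger("omicsfuse")


def read_matrix(path, kind: str, name: str | None = None) -> OmicsBlock:
    """Read a feature x subject TSV into an :class:`OmicsBlock`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise OmicsFuseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {n_cols})"
                )
            index.append(parts[0])
            rows.append(parts[1:])
    subjects = header[1:]
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError:
        for i, row in enumerate(rows):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except ValueError:
                    raise OmicsFuseError(
                        f"{path}: non-numeric value {cell!r} at feature "
                        f"{index[i]!r}, subject {subjects[j]!r}"
                    ) from None
        raise
    df = pd.DataFrame(values, index=index, columns=subjects)
    if kind == COUNTS and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise OmicsFuseError(
            f"{path}: negative count at feature {index[i]!r}, subject {subjects[j]!r}"
        )
    return OmicsBlock(name or str(path), kind, df)


def write_matrix(block_or_df, path) -> None:
    df = block_or_df.values if isinstance(block_or_df, OmicsBlock) else block_or_df
    df.to_csv(path, sep="\t", index_label="feature_id")


def filter_zero_variance(block: OmicsBlock):
    """Drop features with zero variance across subjects.

    Returns the filtered block and the list of removed feature IDs.
    """
    var = block.values.var(axis=1, ddof=0)
    keep = var > 0
    removed = list(block.values.index[~keep])
    if not keep.any():
        raise OmicsFuseError(f"block {block.name!r}: all features have zero variance")
    if removed:
        log.info("block %s: removed %d zero-variance features", block.name, len(removed))
    return OmicsBlock(block.name, block.kind, block.values.loc[keep]), removed


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[2:] or all(p == "" for p in parts[2:]):
                raise OmicsFuseError(f"{path}: line {lineno}: gene set with no members")
            name = parts[0]
            if not name:
                raise OmicsFuseError(f"{path}: line {lineno}: blank set name")
            if name in sets:
                raise OmicsFuseError(f"{path}: duplicate set name {name!r}")
            members = [p for p in parts[2:] if p]
            if not members:
                raise OmicsFuseError(f"{path}: line {lineno}: gene set with no members")
            sets[name] = frozenset(members)
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="subject_id")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path, value_name: str = "cluster") -> None:
    labels.rename(value_name).to_csv(path, sep="\t", index_label="subject_id")
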
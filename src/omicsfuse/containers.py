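"""Core data containers shared across the pipeline.

Matrices follow the omics convention of features x subjects. Blocks carry a
``kind`` tag so that count-only operations (beta diversity, GMPR, Shannon)
can refuse continuous input and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
COUNTS = "counts"

#: Subject group labels: healthy volunteers, mild/moderate asthma, severe
#: asthma non-smokers and severe asthma (ex-)smokers.
GROUPS = ("HV", "MMA", "SA-nonsmoker", "SA-smoker")


class OmicsFuseError(Exception):
    """Base error for invalid inputs or degenerate states."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise OmicsFuseError(f"duplicate {what} IDs: {dup[:5]}")


@dataclass
class OmicsBlock:
    """One feature x subject matrix with identity and a kind tag."""

    name: str
    kind: str
    values: pd.DataFrame  # index: feature IDs, columns: subject IDs

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, COUNTS):
            raise OmicsFuseError(f"unknown block kind {self.kind!r}")
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "subject")
        if self.kind == COUNTS:
            arr = self.values.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise OmicsFuseError(
                        f"block {self.name!r}: counts must be integers"
                    )
                self.values = self.values.round().astype(np.int64)
                arr = self.values.to_numpy()
            if (arr < 0).any():
                raise OmicsFuseError(f"block {self.name!r}: negative counts")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, subjects) -> "OmicsBlock":
        return OmicsBlock(self.name, self.kind, self.values.loc[:, list(subjects)])


@dataclass
class MultiOmicsDataset:
    """Aligned omics blocks plus the clinical table and group labels.

    Healthy volunteers (group ``HV``) are carried in the blocks and clinical
    table but excluded from the clustering input.
    """

    blocks: list  # list[OmicsBlock]
    clinical: pd.DataFrame  # index: subject IDs
    group: pd.Series  # subject -> one of GROUPS
    truth: pd.Series | None = None  # subject -> planted cluster (synthetic only)

    def __post_init__(self) -> None:
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise OmicsFuseError(f"unknown group labels: {sorted(bad)}")
        subjects = None
        for b in self.blocks:
            s = set(b.subject_ids)
            subjects = s if subjects is None else subjects & s
        if subjects is not None:
            for b in self.blocks:
                if set(b.subject_ids) != subjects:
                    raise OmicsFuseError(
                        f"block {b.name!r} subjects not aligned with the others"
                    )

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise OmicsFuseError(f"no block named {name!r}")

    @property
    def block_names(self) -> list:
        return [b.name for b in self.blocks]

    @property
    def asthmatic_subjects(self) -> pd.Index:
        ids = self.group.index[self.group != "HV"]
        # canonical sorted order so alignment is order-independent
        return pd.Index(sorted(ids))

    @property
    def healthy_subjects(self) -> pd.Index:
        return pd.Index(sorted(self.group.index[self.group == "HV"]))


@dataclass
class GeneSetCollection:
    """Named gene/feature sets with optional descriptions."""

    sets: dict  # name -> frozenset of feature IDs
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise OmicsFuseError("blank set name")
            if len(members) == 0:
                raise OmicsFuseError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )
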
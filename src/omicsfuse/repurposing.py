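"""Drug-response stratification by the four-signature N-shape rule.

Given per-subject enrichment scores for four signatures — disease-down,
disease-up, drug-up, drug-down — a subject (or a cluster, via its mean ES
profile) is a likely responder when the disease signatures point with the
disease and the drug-response signatures point against it:

    ES(disease_down) < theta,  ES(disease_up) > theta,
    ES(drug_up)      < theta,  ES(drug_down)  > theta.

Joining the four mean scores in that order traces an "N" for a responder
cluster. The N-score [ES(disease_up) - ES(disease_down)] +
[ES(drug_down) - ES(drug_up)] summarises the strength of the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, OmicsFuseError

TAGS = ("disease_down", "disease_up", "drug_up", "drug_down")


@dataclass
class SignatureQuad:
    """Four tagged gene sets: disease up/down and drug-response up/down."""

    disease_up: frozenset
    disease_down: frozenset
    drug_up: frozenset
    drug_down: frozenset

    def __post_init__(self) -> None:
        for tag in TAGS:
            members = getattr(self, tag)
            if not members:
                raise OmicsFuseError(f"signature {tag!r} is empty")
            setattr(self, tag, frozenset(members))

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection({tag: getattr(self, tag) for tag in TAGS})

    @classmethod
    def from_collection(cls, sets: GeneSetCollection, suffix_map=None) -> "SignatureQuad":
        """Build from a collection with ``_disease_up`` etc. name suffixes."""
        found = {}
        for name in sets.names():
            lower = name.lower()
            for tag in TAGS:
                if lower.endswith(tag):
                    found[tag] = sets[name]
        missing = [t for t in TAGS if t not in found]
        if missing:
            raise OmicsFuseError(f"missing signature tags: {missing}")
        return cls(**found)


def _quad_frame(es: pd.DataFrame) -> pd.DataFrame:
    missing = [t for t in TAGS if t not in es.index]
    if missing:
        raise OmicsFuseError(f"missing signature ES rows: {missing}")
    return es.loc[list(TAGS)]


def n_score(es: pd.DataFrame, theta: float = 0.0) -> pd.DataFrame:
    """Per-subject N-scores and responder flags.

    ``es`` is a 4 x subjects frame indexed by the signature tags (an
    :class:`~omicsfuse.gsva.ESMatrix` over a quad collection qualifies).
    """
    q = _quad_frame(es)
    d_down, d_up = q.loc["disease_down"], q.loc["disease_up"]
    g_up, g_down = q.loc["drug_up"], q.loc["drug_down"]
    responder = (d_down < theta) & (d_up > theta) & (g_up < theta) & (g_down > theta)
    score = (d_up - d_down) + (g_down - g_up)
    out = q.T.copy()
    out["n_score"] = score
    out["responder"] = responder
    if not np.isfinite(out["n_score"].to_numpy()).all():
        raise OmicsFuseError("non-finite N-score")
    return out


def cluster_n_pattern(es: pd.DataFrame, labels: pd.Series, theta: float = 0.0) -> pd.DataFrame:
    """Per-cluster mean-ES profile, N-shape flag and responder counts."""
    q = _quad_frame(es)
    subjects = [s for s in labels.index if s in q.columns]
    if not subjects:
        raise OmicsFuseError("no labelled subjects in the ES matrix")
    labs = labels.loc[subjects]
    per_subject = n_score(q.loc[:, subjects], theta=theta)
    rows = []
    for c in sorted(labs.unique()):
        members = labs.index[labs == c]
        if len(members) == 0:
            raise OmicsFuseError(f"cluster {c} is empty")
        means = q.loc[:, members].mean(axis=1)
        flagged = bool(
            (means["disease_down"] < theta)
            and (means["disease_up"] > theta)
            and (means["drug_up"] < theta)
            and (means["drug_down"] > theta)
        )
        rows.append(
            {
                "cluster": c,
                **{f"mean_{t}": float(means[t]) for t in TAGS},
                "n_shape": flagged,
                "n_responders": int(per_subject.loc[members, "responder"].sum()),
                "n_subjects": int(len(members)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
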
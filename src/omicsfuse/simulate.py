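"""Synthetic multi-omics cohort generator.

Emulates a sputum multi-omics study: 72 asthmatic subjects in five planted
clusters (default sizes 20/12/18/12/10) plus 13 healthy controls, observed
through six aligned blocks — microarray-style transcriptomics, a GSVA
pathway-score block derived from it, two proteomics panels, and two
overdispersed compositional count blocks (16S and metagenomics).

Planted biology, scaled by ``effect_size`` (standardised mean shift):

* cluster 3 carries an up-shifted T2/eosinophilic gene panel and elevated
  sputum eosinophil percentages;
* clusters 2 and 4 carry distinct neutrophil gene signatures and elevated
  sputum neutrophil percentages;
* cluster 2 additionally shows microbial dysbiosis: two pathogen taxa
  dominate both count blocks, depressing Shannon alpha diversity;
* cluster 4 is the planted drug-responder group: disease-up genes up,
  disease-down genes down, drug-response genes reversed (the N-shaped
  profile);
* every cluster also gets its own marker sets in each block plus a set of
  low-abundance indicator taxa, so all omics types carry cluster signal;
* healthy controls are drawn from the baseline with no planted shifts.

Everything is drawn from one ``numpy`` generator seeded by ``rng_seed``, so
a given config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONTINUOUS,
    COUNTS,
    GeneSetCollection,
    MultiOmicsDataset,
    OmicsBlock,
    OmicsFuseError,
)

TRANSCRIPTOMICS = "transcriptomics"
PATHWAYS = "pathways"
SOMASCAN = "somascan_proteomics"
SHOTGUN = "shotgun_proteomics"
MICROBIOME_16S = "microbiome_16s"
METAGENOMICS = "metagenomics"

BLOCK_NAMES = (TRANSCRIPTOMICS, PATHWAYS, SOMASCAN, SHOTGUN, MICROBIOME_16S, METAGENOMICS)

T2_SET = "T2_SIGNATURE"
NEUTROPHIL_SETS = {2: "NEUTROPHIL_SIG_A", 4: "NEUTROPHIL_SIG_B"}
QUAD_SETS = ("DISEASE_UP", "DISEASE_DOWN", "DRUG_UP", "DRUG_DOWN")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    cluster_sizes: tuple = (20, 12, 18, 12, 10)
    n_healthy: int = 13
    n_genes: int = 300
    n_somascan: int = 150
    n_shotgun: int = 120
    n_taxa_16s: int = 80
    n_taxa_meta: int = 100
    effect_size: float = 2.0  # standardised mean shift per planted signal
    marker_genes_per_cluster: int = 20
    marker_proteins_per_cluster: int = 15
    quad_set_size: int = 15
    indicator_taxa_per_cluster: int = 6
    n_pathogen_taxa: int = 2
    n_decoy_sets: int = 30
    dispersion: float = 0.5  # NB dispersion (gamma-Poisson)
    library_size_log_mean: float = np.log(3e4)
    library_size_log_sd: float = 0.35
    missingness: float = 0.0  # fraction of continuous entries set missing
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        if any(s < 2 for s in self.cluster_sizes) or not self.cluster_sizes:
            raise OmicsFuseError("cluster sizes must all be >= 2")
        if self.n_healthy < 0:
            raise OmicsFuseError("n_healthy must be non-negative")
        if self.effect_size < 0:
            raise OmicsFuseError("effect_size must be non-negative")

    @property
    def n_asthma(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


@dataclass
class GroundTruth:
    """Planted structure: labels, signal feature sets, pathogen taxa."""

    labels: pd.Series  # asthmatic subject -> cluster 1..n
    planted_sets: dict  # block name -> {set name -> (cluster, frozenset, sign)}
    pathogen_taxa: dict = field(default_factory=dict)  # block name -> list of taxa


def _subject_ids(config: SimulationConfig):
    asthma = [f"A{i:03d}" for i in range(1, config.n_asthma + 1)]
    healthy = [f"H{i:03d}" for i in range(1, config.n_healthy + 1)]
    return asthma, healthy


def _plan(config: SimulationConfig):
    """Deterministic layout of feature IDs and planted set membership.

    Both :func:`generate_dataset` and :func:`generate_gene_sets` derive
    their planted sets from this shared plan, so the gene-set collection
    always matches the dataset generated from the same config.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    nc = config.n_clusters

    need = nc * config.marker_genes_per_cluster + 4 * config.quad_set_size
    if need > config.n_genes:
        raise OmicsFuseError(
            f"planted gene sets need {need} genes but only {config.n_genes} exist"
        )
    pool = rng.permutation(config.n_genes)
    cursor = 0
    gene_sets = {}  # set name -> (cluster, members, sign)
    for c in range(1, nc + 1):
        members = frozenset(genes[i] for i in pool[cursor : cursor + config.marker_genes_per_cluster])
        cursor += config.marker_genes_per_cluster
        if c == 3:
            name = T2_SET
        elif c in NEUTROPHIL_SETS:
            name = NEUTROPHIL_SETS[c]
        else:
            name = f"CLUSTER{c}_MARKERS"
        gene_sets[name] = (c, members, +1)
    # drug/disease quad, planted in cluster 4 when it exists
    responder = 4 if nc >= 4 else None
    quad_signs = {"DISEASE_UP": +1, "DISEASE_DOWN": -1, "DRUG_UP": -1, "DRUG_DOWN": +1}
    for name in QUAD_SETS:
        members = frozenset(genes[i] for i in pool[cursor : cursor + config.quad_set_size])
        cursor += config.quad_set_size
        gene_sets[name] = (responder, members, quad_signs[name])

    def protein_sets(prefix, n_feat, per_cluster):
        ids = [f"{prefix}{i:04d}" for i in range(1, n_feat + 1)]
        if nc * per_cluster > n_feat:
            raise OmicsFuseError(f"planted {prefix} sets exceed feature count {n_feat}")
        perm = rng.permutation(n_feat)
        out = {}
        for c in range(1, nc + 1):
            sel = perm[(c - 1) * per_cluster : c * per_cluster]
            out[f"{prefix}_CLUSTER{c}"] = (c, frozenset(ids[i] for i in sel), +1)
        return ids, out

    soma_ids, soma_sets = protein_sets("PROT_S", config.n_somascan, config.marker_proteins_per_cluster)
    shot_ids, shot_sets = protein_sets("PROT_M", config.n_shotgun, config.marker_proteins_per_cluster)

    def taxa_plan(prefix, n_taxa):
        ids = [f"{prefix}{i:04d}" for i in range(1, n_taxa + 1)]
        perm = rng.permutation(n_taxa)
        pathogens = [ids[i] for i in perm[: config.n_pathogen_taxa]]
        cursor = config.n_pathogen_taxa
        indicators = {}
        for c in range(1, nc + 1):
            sel = perm[cursor : cursor + config.indicator_taxa_per_cluster]
            cursor += config.indicator_taxa_per_cluster
            indicators[c] = [ids[i] for i in sel]
        if cursor > n_taxa:
            raise OmicsFuseError(f"planted taxa sets exceed taxon count {n_taxa}")
        return ids, pathogens, indicators

    taxa16, path16, ind16 = taxa_plan("TAXON_S", config.n_taxa_16s)
    taxam, pathm, indm = taxa_plan("TAXON_M", config.n_taxa_meta)

    # decoy gene sets, sizes 5..50, drawn after the planted layout
    decoys = {}
    for d in range(1, config.n_decoy_sets + 1):
        size = int(rng.integers(5, min(51, config.n_genes + 1)))
        members = frozenset(genes[i] for i in rng.choice(config.n_genes, size=size, replace=False))
        decoys[f"DECOY{d:03d}"] = members

    return {
        "genes": genes,
        "gene_sets": gene_sets,
        "soma_ids": soma_ids,
        "soma_sets": soma_sets,
        "shot_ids": shot_ids,
        "shot_sets": shot_sets,
        "taxa16": taxa16,
        "pathogens16": path16,
        "indicators16": ind16,
        "taxam": taxam,
        "pathogensm": pathm,
        "indicatorsm": indm,
        "decoys": decoys,
    }


def generate_gene_sets(config: SimulationConfig, min_size: int = 3) -> GeneSetCollection:
    """Planted signal sets plus random decoy sets over the transcriptomics IDs."""
    plan = _plan(config)
    sets, desc = {}, {}
    for name, (cluster, members, sign) in plan["gene_sets"].items():
        sets[name] = members
        desc[name] = f"planted (cluster {cluster}, sign {sign:+d})"
    for name, members in plan["decoys"].items():
        sets[name] = members
        desc[name] = "decoy"
    for name, members in sets.items():
        if len(members) < min_size:
            raise OmicsFuseError(f"set {name!r} smaller than min size {min_size}")
    return GeneSetCollection(sets, desc)


def _continuous_block(name, feature_ids, subjects, shifts, rng, missingness):
    x = rng.normal(size=(len(feature_ids), len(subjects)))
    x += shifts
    df = pd.DataFrame(x, index=feature_ids, columns=subjects)
    if missingness > 0:
        mask = rng.random(df.shape) < missingness
        df = df.mask(mask)
    return OmicsBlock(name, CONTINUOUS, df)


def _count_block(name, taxa, subjects, weights, rng, config):
    """Gamma-Poisson (negative-binomial) compositional counts.

    ``weights`` is taxa x subjects of unnormalised relative abundances;
    each subject's expected profile is its column normalised and scaled by
    a log-normal library size.
    """
    props = weights / weights.sum(axis=0, keepdims=True)
    lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, len(subjects))
    mean = props * lib[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    return OmicsBlock(name, COUNTS, pd.DataFrame(counts, index=taxa, columns=subjects))


def generate_dataset(config: SimulationConfig, include_pathway_block: bool = True):
    """Generate the aligned six-block synthetic cohort and its ground truth."""
    plan = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 1)))
    asthma, healthy = _subject_ids(config)
    subjects = asthma + healthy
    n_sub = len(subjects)
    eff = config.effect_size

    labels = pd.Series(
        np.repeat(np.arange(1, config.n_clusters + 1), config.cluster_sizes),
        index=asthma,
        name="cluster",
    )
    # subject x 1 indicator of cluster membership, healthy rows all zero
    memb = {c: np.array([labels.get(s, 0) == c for s in subjects]) for c in range(1, config.n_clusters + 1)}

    def shift_matrix(feature_ids, planted):
        pos = {f: i for i, f in enumerate(feature_ids)}
        shifts = np.zeros((len(feature_ids), n_sub))
        for _name, (cluster, members, sign) in planted.items():
            if cluster is None:
                continue
            rows = [pos[f] for f in members]
            shifts[np.ix_(rows, np.where(memb[cluster])[0])] += sign * eff
        return shifts

    tx = _continuous_block(
        TRANSCRIPTOMICS, plan["genes"], subjects,
        shift_matrix(plan["genes"], plan["gene_sets"]), rng, config.missingness,
    )
    soma = _continuous_block(
        SOMASCAN, plan["soma_ids"], subjects,
        shift_matrix(plan["soma_ids"], plan["soma_sets"]), rng, config.missingness,
    )
    shot = _continuous_block(
        SHOTGUN, plan["shot_ids"], subjects,
        shift_matrix(plan["shot_ids"], plan["shot_sets"]), rng, config.missingness,
    )

    def taxa_weights(taxa, pathogens, indicators):
        base = rng.lognormal(0.0, 1.2, len(taxa))
        pos = {t: i for i, t in enumerate(taxa)}
        # indicator taxa are near-absent at baseline so presence itself is a signal
        rare = np.concatenate([[pos[t] for t in ind] for ind in indicators.values()]).astype(int)
        base[rare] *= 1e-4
        # pathogens sit at half the average abundance outside cluster 2;
        # anchoring to the mean keeps the planted dominance scale stable
        for t in pathogens:
            base[pos[t]] = 0.5 * base.mean()
        w = np.tile(base[:, None], (1, n_sub))
        if 2 in memb:
            rows = [pos[t] for t in pathogens]
            w[np.ix_(rows, np.where(memb[2])[0])] *= np.exp(2.2 * eff)
        for c, ind in indicators.items():
            rows = [pos[t] for t in ind]
            w[np.ix_(rows, np.where(memb[c])[0])] *= np.exp(2.6 * eff)
        return w

    b16 = _count_block(
        MICROBIOME_16S, plan["taxa16"], subjects,
        taxa_weights(plan["taxa16"], plan["pathogens16"], plan["indicators16"]), rng, config,
    )
    bmeta = _count_block(
        METAGENOMICS, plan["taxam"], subjects,
        taxa_weights(plan["taxam"], plan["pathogensm"], plan["indicatorsm"]), rng, config,
    )

    clinical = _clinical_table(config, labels, subjects, rng)
    group = clinical["group"].copy()

    blocks = [tx]
    if include_pathway_block:
        from .gsva import gsva_es

        sets = generate_gene_sets(config)
        es = gsva_es(tx, sets, min_overlap=3)
        blocks.append(OmicsBlock(PATHWAYS, CONTINUOUS, es.values))
    blocks += [soma, shot, b16, bmeta]

    dataset = MultiOmicsDataset(blocks, clinical.drop(columns=["group"]), group, truth=labels)
    planted_sets = {
        TRANSCRIPTOMICS: dict(plan["gene_sets"]),
        SOMASCAN: dict(plan["soma_sets"]),
        SHOTGUN: dict(plan["shot_sets"]),
    }
    truth = GroundTruth(
        labels=labels,
        planted_sets=planted_sets,
        pathogen_taxa={MICROBIOME_16S: plan["pathogens16"], METAGENOMICS: plan["pathogensm"]},
    )
    return dataset, truth


def _clinical_table(config, labels, subjects, rng):
    """Covariates drawn conditionally on cluster.

    Sputum eosinophil % is log-normal with a cluster-3 shift; sputum
    neutrophil % is elevated in clusters 2 (strongly) and 4; severity mix
    leans mild/moderate in clusters 1 and 5.
    """
    eff = config.effect_size
    rows = []
    for s in subjects:
        c = int(labels[s]) if s in labels.index else 0
        if c == 0:
            group = "HV"
        else:
            p_mma = {1: 0.5, 5: 0.3}.get(c, 0.04)
            if rng.random() < p_mma:
                group = "MMA"
            else:
                p_smoker = 0.45 if c == 4 else 0.2
                group = "SA-smoker" if rng.random() < p_smoker else "SA-nonsmoker"
        eos = float(np.exp(rng.normal(np.log(1.5) + (1.6 * eff if c == 3 else 0.0), 0.8)))
        neut_mu = {2: 40 + 24 * eff, 4: 40 + 13 * eff}.get(c, 40.0)
        neut = float(np.clip(rng.normal(neut_mu, 9.0), 0.0, 98.0))
        rows.append(
            {
                "subject_id": s,
                "group": group,
                "age": float(np.clip(rng.normal(50, 12), 18, 80)),
                "sex": "F" if rng.random() < 0.55 else "M",
                "bmi": float(np.clip(rng.normal(27 + (2.0 if c == 4 else 0.0), 4), 16, 45)),
                "sputum_eosinophils_pct": min(eos, 90.0),
                "sputum_neutrophils_pct": neut,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def write_dataset(dataset: MultiOmicsDataset, truth: GroundTruth, out_dir) -> None:
    """Write blocks (TSV), the clinical table (CSV) and ground truth (TSV)."""
    import os

    from .io import write_clinical, write_labels, write_matrix

    os.makedirs(out_dir, exist_ok=True)
    for block in dataset.blocks:
        write_matrix(block, os.path.join(out_dir, f"{block.name}.tsv"))
    clinical = dataset.clinical.copy()
    clinical["group"] = dataset.group
    write_clinical(clinical, os.path.join(out_dir, "clinical.csv"))
    write_labels(truth.labels, os.path.join(out_dir, "ground_truth.tsv"))
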
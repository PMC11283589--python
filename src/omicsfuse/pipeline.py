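"""End-to-end pipeline driver: simulate -> cluster -> select-k -> characterise.

The pipeline is configured by a nested mapping (typically loaded from YAML);
every stage writes its result tables under ``out_dir`` and a run log records
the seed, parameters and package version. Any stage failure aborts with the
stage name.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd

from . import __version__
from .consensus import select_optimal_k, type_combinations
from .containers import OmicsFuseError
from .gsva import gsva_es
from .io import (
    filter_zero_variance,
    read_clinical,
    read_gmt,
    read_matrix,
    write_labels,
    write_matrix,
)
from .microbiome import diff_abundance, shannon_alpha
from .repurposing import cluster_n_pattern, n_score
from .simulate import (
    METAGENOMICS,
    MICROBIOME_16S,
    PATHWAYS,
    QUAD_SETS,
    TRANSCRIPTOMICS,
    SimulationConfig,
    generate_dataset,
    generate_gene_sets,
    write_dataset,
)
from .stats import clinical_compare, cluster_vs_rest_dep

log = logging.getLogger("omicsfuse")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "omicsfuse_results",
    "simulate": {},  # SimulationConfig overrides
    "cluster": {
        "k_range": [2, 8],
        "reps": 100,
        "subsample_fraction": 0.8,
        "K": 20,
        "mu": 0.5,
        "T": 50,
    },
    "inputs": {},  # block name -> path, for pre-generated data
}


class PipelineError(OmicsFuseError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def load_dataset(cfg: dict):
    """Simulate a dataset, or read one from configured block paths."""
    inputs = cfg.get("inputs") or {}
    if inputs:
        from .containers import MultiOmicsDataset

        blocks = []
        for name, spec in inputs.items():
            if name in ("clinical", "labels"):
                continue
            path, kind = (spec["path"], spec["kind"]) if isinstance(spec, dict) else (spec, "continuous")
            if not os.path.exists(path):
                raise OmicsFuseError(f"configured block path missing: {path}")
            block, _ = filter_zero_variance(read_matrix(path, kind, name=name))
            blocks.append(block)
        clin_path = inputs.get("clinical")
        if not clin_path or not os.path.exists(clin_path):
            raise OmicsFuseError("inputs require a 'clinical' CSV with a 'group' column")
        clinical = read_clinical(clin_path)
        group = clinical["group"]
        return MultiOmicsDataset(blocks, clinical.drop(columns=["group"]), group), None
    sim = SimulationConfig(rng_seed=cfg["seed"], **cfg.get("simulate", {}))
    return generate_dataset(sim)


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full workflow; returns the result bundle in memory."""
    cfg = merge_config(config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    bundle = {"config": cfg}

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise PipelineError(name, err) from err

    def _simulate():
        dataset, truth = load_dataset(cfg)
        if truth is not None:
            write_dataset(dataset, truth, os.path.join(out_dir, "data"))
        return dataset, truth

    dataset, truth = stage("simulate", _simulate)
    bundle["dataset"] = dataset

    def _select_k():
        cc = cfg["cluster"]
        lo, hi = cc["k_range"]
        report = select_optimal_k(
            dataset,
            k_range=range(lo, hi + 1),
            combos=type_combinations(),
            reps=cc["reps"],
            subsample_fraction=cc["subsample_fraction"],
            seed=cfg["seed"],
            K=cc["K"],
            mu=cc["mu"],
            T=cc["T"],
        )
        report.table.to_csv(os.path.join(out_dir, "k_selection.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"area": report.areas, "delta_area": report.delta_area}
        ).to_csv(os.path.join(out_dir, "cdf_delta_area.tsv"), sep="\t", index_label="k")
        write_labels(report.final_labels, os.path.join(out_dir, "cluster_labels.tsv"))
        return report

    report = stage("select_k", _select_k)
    bundle["k_selection"] = report
    labels = report.final_labels

    def _characterise():
        out = {}
        sim = SimulationConfig(rng_seed=cfg["seed"], **cfg.get("simulate", {}))
        tx = dataset.block(TRANSCRIPTOMICS)
        sets = generate_gene_sets(sim)
        es = gsva_es(tx, sets, min_overlap=3)
        write_matrix(es.values, os.path.join(out_dir, "gsva_es.tsv"))
        dep = cluster_vs_rest_dep(es, labels, reference="rest")
        dep.to_csv(os.path.join(out_dir, "dep_cluster_vs_rest.tsv"), sep="\t", index=False)
        out["dep"] = dep
        clin = clinical_compare(dataset.clinical, labels)
        clin.to_csv(os.path.join(out_dir, "clinical_compare.tsv"), sep="\t", index=False)
        out["clinical"] = clin
        diversity = []
        for name in (MICROBIOME_16S, METAGENOMICS):
            blk = dataset.block(name)
            h = shannon_alpha(blk.subset_subjects(labels.index))
            diversity.append(pd.DataFrame({"block": name, "shannon": h}))
            da = diff_abundance(blk, labels)
            da.to_csv(os.path.join(out_dir, f"diff_abundance_{name}.tsv"), sep="\t", index=False)
        pd.concat(diversity).to_csv(
            os.path.join(out_dir, "alpha_diversity.tsv"), sep="\t", index_label="subject_id"
        )
        quad_es = es.values.reindex([q for q in QUAD_SETS if q in es.values.index])
        quad_es = quad_es.rename(index=str.lower)
        if quad_es.shape[0] == 4:
            scores = n_score(quad_es.loc[:, labels.index])
            scores.to_csv(os.path.join(out_dir, "n_method_subjects.tsv"), sep="\t")
            pattern = cluster_n_pattern(quad_es, labels)
            pattern.to_csv(os.path.join(out_dir, "n_method_clusters.tsv"), sep="\t")
            out["n_method"] = pattern
        return out

    bundle["characterise"] = stage("characterise", _characterise)

    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(
            {
                "seed": cfg["seed"],
                "version": __version__,
                "chosen_k": int(report.chosen_k),
                "cluster_params": cfg["cluster"],
                "simulate_params": cfg.get("simulate", {}),
            },
            fh,
            indent=2,
        )
    log.info("pipeline complete: chosen k=%d, results in %s", report.chosen_k, out_dir)
    return bundle
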
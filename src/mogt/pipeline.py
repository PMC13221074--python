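"""End-to-end run configuration, orchestration and report assembly.

A single YAML run-config drives the whole pipeline: build the gene graph
from GWAS/interaction/omics files, split, train with 5-fold CV, select the
best fold, set the Youden threshold, evaluate on the hold-out set, classify
all scored genes, and write every artifact (resolved config, logs with
input checksums, history, report, predictions) under one output directory.
All randomness flows from the one global seed via per-stage derived seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .estimator import MOGT
from .graph_build import (
    LabelSet,
    assemble_graph,
    build_gene_edges,
    filter_top_fraction,
    map_snps_to_genes,
    select_candidate_genes,
)
from .model import LossConfig, ModelConfig
from .training import SplitSpec, TrainConfig, stratified_holdout

__all__ = ["RunConfig", "run_pipeline", "write_report", "validate_report"]


_GRAPH_DEFAULTS = {
    "gwas": None,
    "genes": None,
    "interactions": None,
    "omics": [],
    "labels": None,
    "window_mb": 1.0,
    "snp_gene_kb": 1.0,
    "p_threshold": 5e-8,
    "top_fraction": 0.01,
}


class RunConfig:
    """Validated run configuration with sections graph/model/loss/train/split.

    Unknown sections or keys are rejected; every defaulted value is echoed
    into the resolved config written to the output directory.
    """

    _SECTIONS = ("graph", "model", "loss", "train", "split")

    def __init__(self, raw: dict | None = None, seed: int | None = None):
        raw = dict(raw or {})
        unknown = set(raw) - set(self._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.seed = int(raw.pop("seed", 0) if seed is None else seed)

        graph_raw = dict(raw.get("graph") or {})
        bad = set(graph_raw) - set(_GRAPH_DEFAULTS)
        if bad:
            raise ValueError(f"unknown graph config keys: {sorted(bad)}")
        self.graph = {**_GRAPH_DEFAULTS, **graph_raw}

        def build(cls, section):
            data = dict(raw.get(section) or {})
            allowed = {f.name for f in fields(cls)}
            bad = set(data) - allowed
            if bad:
                raise ValueError(f"unknown {section} config keys: {sorted(bad)}")
            if "seed" in allowed:
                data.setdefault("seed", self.seed)
            return cls(**data)

        self.model = build(ModelConfig, "model")
        self.loss = build(LossConfig, "loss")
        self.train = build(TrainConfig, "train")
        self.split = build(SplitSpec, "split")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {}, seed=seed)

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "graph": self.graph,
            "model": asdict(self.model),
            "loss": asdict(self.loss),
            "train": asdict(self.train),
            "split": asdict(self.split),
        }


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def build_graph_from_files(cfg: dict, log: list | None = None):
    """Run the graph-construction stage of a run config; returns a GeneGraph."""
    for key in ("gwas", "genes", "interactions", "labels"):
        if not cfg.get(key):
            raise ValueError(f"graph config requires '{key}'")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input file not found: {cfg[key]}")
    snps = mio.read_gwas(cfg["gwas"])
    genes = mio.read_genes_bed(cfg["genes"])
    interactions = mio.read_interactions(cfg["interactions"])
    labels = mio.read_labels(cfg["labels"])
    omics = [mio.read_omics(p) for p in cfg["omics"]]

    window_bp = int(round(float(cfg["window_mb"]) * 1_000_000))
    snp_gene_bp = int(round(float(cfg["snp_gene_kb"]) * 1_000))
    candidates = select_candidate_genes(
        snps, genes, p_threshold=float(cfg["p_threshold"]), window_bp=window_bp
    )
    snp_map = map_snps_to_genes(snps, genes, window_bp=snp_gene_bp)
    edges = build_gene_edges(interactions, snp_map)
    if edges:
        edges = filter_top_fraction(edges, float(cfg["top_fraction"]))
    if log is not None:
        log.append(f"candidate genes: {len(candidates)}")
        log.append(f"gene-gene edges kept: {len(edges)}")
    # provisional masks: hold-out test vs training pool (folds come later)
    labeled = {g: 1 for g in labels.positives}
    labeled.update({g: 0 for g in labels.negatives})
    return labels, candidates, edges, omics, labeled


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute build-graph → split → CV train → threshold → evaluate → classify.

    Writes all artifacts under ``out_dir`` and returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}"]
    resolved = config.resolved()
    cfg_text = yaml.safe_dump(resolved, sort_keys=True)
    log.append(
        "config sha256: "
        + hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    )
    for key in ("gwas", "genes", "interactions", "labels"):
        log.append(f"input {key}: {config.graph[key]} sha256 {_checksum(config.graph[key])}")
    for p in config.graph["omics"]:
        log.append(f"input omics: {p} sha256 {_checksum(p)}")
    (out / "resolved_config.yaml").write_text(cfg_text)

    try:
        labels, candidates, edges, omics, labeled = build_graph_from_files(
            config.graph, log
        )
        train_ids, test_ids = stratified_holdout(
            labeled, train_fraction=1.0 - config.split.holdout_fraction,
            seed=config.split.seed,
        )
        masks = {g: "train" for g in train_ids}
        masks.update({g: "test" for g in test_ids})
        graph = assemble_graph(candidates, labels, edges, omics, masks)
        mio.save_graph(graph, out / "graph")
        log.append(f"graph: {graph.n_nodes} nodes, {len(graph.edges)} edges, "
                   f"{graph.n_features} features")
    except Exception as exc:
        log.append(f"FAILED at stage build-graph: {exc}")
        (out / "log.txt").write_text("\n".join(log) + "\n")
        raise

    try:
        res = MOGT(graph, config.model, config.loss).fit(
            train_config=config.train, split=config.split
        )
    except Exception as exc:
        log.append(f"FAILED at stage train: {exc}")
        (out / "log.txt").write_text("\n".join(log) + "\n")
        raise

    res.save(out)
    report = res.report_dict()
    write_report(report, res.history, out)
    log.append(f"best fold: {report['best_fold']}  threshold: {report['threshold']:.4f}")
    log.append(
        f"hold-out AUROC {report['auroc']:.4f}  AUPRC {report['auprc']:.4f}  "
        f"F1 {report['f1']:.4f}"
    )
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return report


#: required top-level keys and types of a pipeline report
REPORT_SCHEMA = {
    "auroc": float,
    "auprc": float,
    "f1": float,
    "threshold": float,
    "best_fold": int,
    "fold_metrics": list,
    "val_auprc_mean": float,
    "val_auprc_sd": float,
    "test_n_pos": int,
    "test_n_neg": int,
    "random_baseline_auprc": (float, type(None)),
    "ablation": dict,
    "config": dict,
}


def validate_report(report: dict) -> None:
    """Check a report dict against :data:`REPORT_SCHEMA`; raises on mismatch."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key '{key}'")
        if not isinstance(report[key], typ):
            raise TypeError(
                f"report key '{key}' has type {type(report[key]).__name__}"
            )
    for rec in report["fold_metrics"]:
        if not {"fold", "val_auprc", "val_auroc"} <= set(rec):
            raise ValueError("fold_metrics records incomplete")


def write_report(report: dict, history: pd.DataFrame, out_dir) -> None:
    """Write report.json (schema-validated) and eval_report.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    flat = {
        k: report[k]
        for k in (
            "auroc", "auprc", "f1", "threshold", "best_fold",
            "val_auprc_mean", "val_auprc_sd", "test_n_pos", "test_n_neg",
            "random_baseline_auprc",
        )
    }
    pd.DataFrame([flat]).to_csv(out / "eval_report.tsv", sep="\t", index=False)
    history.to_csv(out / "history.tsv", sep="\t", index=False)
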
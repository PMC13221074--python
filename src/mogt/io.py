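"""Readers and writers for the plain-text formats used across the pipeline.

All tabular inputs are tab-separated with a header row, except gene
coordinates which use headerless 4-column BED (chrom, start, end, gene_id).
A fitted graph is persisted as a directory of three TSVs (nodes, features,
edges) so every artifact stays human-inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_build import (
    GeneEdge,
    GeneGraph,
    GenomicInterval,
    LabelSet,
    SnpInteraction,
    SnpRecord,
    MASK_NONE,
    UNLABELED,
)

__all__ = [
    "read_gwas",
    "read_genes_bed",
    "read_interactions",
    "read_omics",
    "read_labels",
    "read_gene_pairs",
    "read_gene_list",
    "write_edges",
    "read_edges",
    "save_graph",
    "load_graph",
    "read_expression",
    "read_sample_groups",
]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_gwas(path) -> list:
    """GWAS summary TSV with columns SNP, CHR, BP, P."""
    df = _read_tsv(path, ["SNP", "CHR", "BP", "P"])
    return [
        SnpRecord(str(r.SNP), str(r.CHR), int(r.BP), float(r.P))
        for r in df.itertuples(index=False)
    ]


def read_genes_bed(path) -> list:
    """Headerless BED4: chrom, start (0-based), end (half-open), gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"])
    return [
        GenomicInterval(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_interactions(path) -> list:
    """SNP–SNP interaction TSV with columns snp_a, snp_b, p."""
    df = _read_tsv(path, ["snp_a", "snp_b", "p"])
    return [
        SnpInteraction(str(r.snp_a), str(r.snp_b), float(r.p))
        for r in df.itertuples(index=False)
    ]


def read_omics(path) -> pd.DataFrame:
    """Per-gene feature table: gene_id column plus numeric columns.

    Empty cells are missing values (NaN after parsing).
    """
    df = _read_tsv(path, ["gene_id"])
    df = df.set_index("gene_id")
    return df.astype(float)


def read_labels(path) -> LabelSet:
    """Label TSV with columns gene_id, label (1 positive / 0 negative)."""
    df = _read_tsv(path, ["gene_id", "label"])
    pos = set(df.loc[df["label"] == 1, "gene_id"].astype(str))
    neg = set(df.loc[df["label"] == 0, "gene_id"].astype(str))
    return LabelSet(positives=pos, negatives=neg)


def read_gene_pairs(path) -> set:
    """Generic unordered gene-pair TSV with columns gene_a, gene_b."""
    df = _read_tsv(path, ["gene_a", "gene_b"])
    return {
        tuple(sorted((str(r.gene_a), str(r.gene_b))))
        for r in df.itertuples(index=False)
    }


def read_gene_list(path) -> list:
    """One gene id per line (no header)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_edges(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.weight:.6f}\n")


def read_edges(path) -> list:
    df = _read_tsv(path, ["gene_a", "gene_b", "weight"])
    return [
        GeneEdge(str(r.gene_a), str(r.gene_b), float(r.weight))
        for r in df.itertuples(index=False)
    ]


def save_graph(graph: GeneGraph, out_dir) -> None:
    """Persist a graph as nodes.tsv / features.tsv / edges.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "gene_id": graph.node_ids,
            "label": graph.labels,
            "mask": graph.masks,
        }
    )
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    feat = pd.DataFrame(
        graph.features,
        index=pd.Index(graph.node_ids, name="gene_id"),
        columns=[f"f{i}" for i in range(graph.n_features)],
    )
    feat.to_csv(out / "features.tsv", sep="\t", float_format="%.10g")
    if graph.raw_features is not None:
        raw = pd.DataFrame(
            graph.raw_features,
            index=pd.Index(graph.node_ids, name="gene_id"),
            columns=[f"f{i}" for i in range(graph.raw_features.shape[1])],
        )
        raw.to_csv(out / "raw_features.tsv", sep="\t", float_format="%.10g")
    write_edges(graph.edges, out / "edges.tsv")


def load_graph(graph_dir) -> GeneGraph:
    d = Path(graph_dir)
    nodes = pd.read_csv(d / "nodes.tsv", sep="\t")
    feat = pd.read_csv(d / "features.tsv", sep="\t", index_col="gene_id")
    edges = read_edges(d / "edges.tsv")
    node_ids = [str(g) for g in nodes["gene_id"]]
    raw = None
    raw_path = d / "raw_features.tsv"
    if raw_path.exists():
        raw = (
            pd.read_csv(raw_path, sep="\t", index_col="gene_id")
            .loc[node_ids]
            .to_numpy(dtype=np.float64)
        )
    return GeneGraph(
        node_ids=node_ids,
        features=feat.loc[node_ids].to_numpy(dtype=np.float64),
        edges=edges,
        labels=nodes["label"].to_numpy(dtype=np.int64),
        masks=nodes["mask"].to_numpy(dtype=object),
        raw_features=raw,
    )


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: gene_id column plus one numeric column per sample."""
    df = _read_tsv(path, ["gene_id"]).set_index("gene_id")
    return df.astype(float)


def read_sample_groups(path) -> dict:
    """Sample→group map TSV with columns sample, group."""
    df = _read_tsv(path, ["sample", "group"])
    return {str(r.sample): str(r.group) for r in df.itertuples(index=False)}
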
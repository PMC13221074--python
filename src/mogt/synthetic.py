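"""Seeded generators for GWAS-style inputs, labeled gene graphs and
expression matrices with planted ground truth.

These fixtures emulate the statistical structure the classifier assumes —
informative node features, class-assortative (homophilous) edges, and
GWAS hits concentrated near planted risk genes — without claiming to match
the marginal distributions of real omics data. Every generator is a pure
function of its config (the seed included): identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_build import (
    GeneEdge,
    GeneGraph,
    GenomicInterval,
    MASK_NONE,
    SnpInteraction,
    SnpRecord,
    UNLABELED,
)
from .specificity import ExpressionMatrix

__all__ = [
    "SimGraphConfig",
    "SimSnpConfig",
    "SimExprConfig",
    "simulate_gene_graph",
    "simulate_snp_inputs",
    "simulate_expression",
    "simulate_pipeline_inputs",
]


@dataclass
class SimGraphConfig:
    """Planted-signal gene graph: Gaussian features + homophilous edges.

    ``class_separation`` is the mean shift (in SD units) between classes on
    a random half of the features; ``homophily`` is the probability that a
    random edge joins a same-class pair, holding overall ``edge_density``
    fixed.
    """

    n_genes: int = 500
    n_features: int = 20
    pos_fraction: float = 0.15
    class_separation: float = 1.5
    homophily: float = 0.8
    edge_density: float = 0.02
    label_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("pos_fraction", "edge_density", "label_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0.0 <= self.homophily <= 1.0):
            raise ValueError("homophily must be in [0, 1]")
        if self.n_genes < 20:
            raise ValueError("n_genes must be >= 20")


@dataclass
class SimSnpConfig:
    """Synthetic GWAS fixture: tiled genes, SNPs, and epistasis pairs."""

    n_snps: int = 200
    n_genes: int = 50
    chrom_length_bp: int = 50_000_000
    risk_gene_ids: frozenset = frozenset()
    significant_p_range: tuple = (1e-10, 1e-9)
    interaction_enrichment: float = 4.0
    n_interactions: int = 800
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be >= n_genes")
        if self.interaction_enrichment < 1.0:
            raise ValueError("interaction_enrichment must be >= 1")


@dataclass
class SimExprConfig:
    """Expression matrix with a planted fraction of group-specific genes."""

    n_genes: int = 200
    groups: tuple = ("grp1", "grp2", "grp3", "grp4", "grp5")
    samples_per_group: int = 20
    specific_fraction: float = 0.1
    fold_change: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.specific_fraction < 1.0):
            raise ValueError("specific_fraction must be in (0, 1)")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if len(self.groups) < 2:
            raise ValueError("at least two groups required")


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def simulate_gene_graph(cfg: SimGraphConfig) -> tuple[GeneGraph, np.ndarray]:
    """Generate a labeled gene graph with controllable signal strength.

    Returns the graph (labels on a ``label_fraction`` subset, the rest
    unlabeled; no split masks yet) and the full ground-truth class vector.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    y = (rng.random(n) < cfg.pos_fraction).astype(np.int64)
    # guarantee both classes exist
    if y.sum() < 2:
        y[rng.choice(n, 2, replace=False)] = 1
    if (1 - y).sum() < 2:
        y[rng.choice(n, 2, replace=False)] = 0

    informative = rng.choice(cfg.n_features, cfg.n_features // 2, replace=False)
    x = rng.standard_normal((n, cfg.n_features))
    x[:, informative] += cfg.class_separation * y[:, None]

    iu, ju = np.triu_indices(n, 1)
    same = y[iu] == y[ju]
    n_within = int(same.sum())
    n_between = int((~same).sum())
    h = cfg.homophily
    if h >= 1.0 and n_within == 0:
        raise ValueError("homophily = 1 but no within-class pairs exist")
    total_edges = cfg.edge_density * (n_within + n_between)
    # p_within / p_between = h / (1 - h) at the target overall density
    if h >= 1.0:
        p_within = min(1.0, total_edges / n_within)
        p_between = 0.0
    else:
        r = h / (1.0 - h)
        p_between = total_edges / (n_between + r * n_within)
        p_within = min(1.0, r * p_between)
        p_between = min(1.0, p_between)
    prob = np.where(same, p_within, p_between)
    picked = rng.random(len(iu)) < prob
    weights = rng.uniform(2.0, 8.0, size=int(picked.sum()))
    edges = [
        GeneEdge(_gene_id(a), _gene_id(b), float(w))
        for a, b, w in zip(iu[picked], ju[picked], weights)
    ]

    labels = np.full(n, UNLABELED, dtype=np.int64)
    n_labeled = int(round(cfg.label_fraction * n))
    labeled_idx = rng.choice(n, n_labeled, replace=False)
    labels[labeled_idx] = y[labeled_idx]
    # both classes must appear among labeled nodes
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            extra = np.flatnonzero((y == cls) & (labels == UNLABELED))[:2]
            labels[extra] = cls

    graph = GeneGraph(
        node_ids=[_gene_id(i) for i in range(n)],
        features=x,
        edges=edges,
        labels=labels,
        masks=np.full(n, MASK_NONE, dtype=object),
        raw_features=x.copy(),
    )
    return graph, y


def simulate_snp_inputs(
    cfg: SimSnpConfig,
) -> tuple[list, list, list, dict]:
    """Generate SNPs, gene intervals and interaction pairs on one chromosome.

    Genes are tiled evenly; every planted risk gene receives one SNP inside
    its body with an association p drawn from ``significant_p_range`` (and
    any other SNP landing within 1 kb of a risk gene is likewise
    significant), so the candidate-gene window is guaranteed to recover the
    planted genes when the range lies below the genome-wide threshold.
    Interaction p-values between risk-adjacent SNP pairs are divided by
    ``interaction_enrichment``. Returns (snps, genes, interactions, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.chrom_length_bp // cfg.n_genes
    gene_len = spacing // 2
    if gene_len < 1:
        raise ValueError("gene tiling exceeds chromosome length")
    genes = [
        GenomicInterval(_gene_id(i), "chr1", i * spacing, i * spacing + gene_len)
        for i in range(cfg.n_genes)
    ]
    gene_by_id = {g.gene_id: g for g in genes}
    risk = sorted(cfg.risk_gene_ids) or sorted(
        rng.choice([g.gene_id for g in genes], max(2, cfg.n_genes // 10), replace=False)
    )
    for rg in risk:
        if rg not in gene_by_id:
            raise ValueError(f"unknown risk gene {rg}")

    lo, hi = cfg.significant_p_range
    positions = []
    for rg in risk:
        g = gene_by_id[rg]
        positions.append((g.start + g.end) // 2)
    n_rest = cfg.n_snps - len(positions)
    positions.extend(int(p) for p in rng.integers(1, cfg.chrom_length_bp, n_rest))

    def near_risk(pos: int) -> bool:
        return any(
            max(gene_by_id[rg].start - pos, pos - gene_by_id[rg].end, 0) <= 1_000
            for rg in risk
        )

    snps = []
    for i, pos in enumerate(positions):
        if near_risk(pos):
            p = float(rng.uniform(lo, hi))
        else:
            p = float(rng.uniform(1e-6, 1.0))
        snps.append(SnpRecord(f"rs{i:05d}", "chr1", pos, p))

    snp_near_risk = np.array([near_risk(s.pos) for s in snps])
    interactions = []
    seen = set()
    while len(interactions) < cfg.n_interactions:
        a, b = rng.integers(0, cfg.n_snps, 2)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        p = float(rng.uniform(0.0001, 1.0))
        if snp_near_risk[a] and snp_near_risk[b]:
            p /= cfg.interaction_enrichment
        interactions.append(SnpInteraction(snps[key[0]].snp_id, snps[key[1]].snp_id, p))

    truth = {
        "risk_genes": list(risk),
        "n_snps": cfg.n_snps,
        "n_genes": cfg.n_genes,
        "significant_p_range": [lo, hi],
        "interaction_enrichment": cfg.interaction_enrichment,
    }
    return snps, genes, interactions, truth


def simulate_pipeline_inputs(
    cfg: SimSnpConfig,
    n_features: int = 10,
    class_separation: float = 1.5,
    label_fraction_nonrisk: float = 0.5,
) -> dict:
    """Full input bundle for an end-to-end run: GWAS fixture plus per-gene
    omics features (risk genes shifted by ``class_separation`` SD on half
    the features) and labels (risk genes positive; a seeded fraction of the
    remaining genes negative; the rest unlabeled).
    """
    snps, genes, interactions, truth = simulate_snp_inputs(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = [g.gene_id for g in genes]
    risk = set(truth["risk_genes"])
    y = np.array([1 if g in risk else 0 for g in gene_ids])
    informative = rng.choice(n_features, max(1, n_features // 2), replace=False)
    x = rng.standard_normal((len(gene_ids), n_features))
    x[:, informative] += class_separation * y[:, None]
    omics = pd.DataFrame(
        x,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"feat{i}" for i in range(n_features)],
    )
    nonrisk = [g for g in gene_ids if g not in risk]
    n_neg = int(round(label_fraction_nonrisk * len(nonrisk)))
    negatives = sorted(rng.choice(nonrisk, n_neg, replace=False))
    labels = pd.DataFrame(
        [(g, 1) for g in sorted(risk)] + [(g, 0) for g in negatives],
        columns=["gene_id", "label"],
    )
    return {
        "snps": snps,
        "genes": genes,
        "interactions": interactions,
        "omics": omics,
        "labels": labels,
        "truth": truth,
    }


def simulate_expression(cfg: SimExprConfig) -> tuple[ExpressionMatrix, dict]:
    """Log-normal expression with group-specific genes planted.

    A ``specific_fraction`` of genes is assigned a group (round-robin over
    a seeded shuffle) and their mean is multiplied by ``fold_change`` in
    that group. Gaussian noise of SD ``noise_sd`` acts on the log scale.
    Returns the matrix and the planted gene → group map.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    groups = list(cfg.groups)
    gene_ids = [_gene_id(i) for i in range(n)]
    samples = [f"{g}_s{j:02d}" for g in groups for j in range(cfg.samples_per_group)]
    sample_group = {s: s.rsplit("_s", 1)[0] for s in samples}

    base_log = rng.normal(1.0, 0.5, size=n)
    n_spec = int(round(cfg.specific_fraction * n))
    chosen = rng.choice(n, n_spec, replace=False)
    planted = {
        gene_ids[g]: groups[k % len(groups)] for k, g in enumerate(sorted(chosen))
    }

    log_fc = np.log(cfg.fold_change)
    mat = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        grp = sample_group[s]
        shift = np.array(
            [log_fc if planted.get(g) == grp else 0.0 for g in gene_ids]
        )
        noise = rng.normal(0.0, cfg.noise_sd, size=n)
        mat[:, j] = np.exp(base_log + shift + noise)

    values = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return ExpressionMatrix(values=values, sample_group=sample_group), planted
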
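"""Build a labeled gene graph from GWAS hits, SNP–SNP interactions and omics tables.

The pipeline implemented here turns genome-wide association results into the
attributed graph the classifier consumes:

1. genes within a fixed window (default ±1 Mb) of a genome-wide-significant
   SNP (p < 5e-8) become *candidate genes*;
2. every SNP is mapped to the genes whose body lies within a small window
   (default ±1 kb);
3. pairwise SNP–SNP epistasis scores are aggregated to gene–gene edges — an
   unordered gene pair receives the strongest interaction (max of
   −log10 p) among SNP pairs bridging the two genes;
4. only the top fraction (default 1%) of edges by weight is kept;
5. multi-omics feature tables are concatenated per gene, imputed and
   z-scored with parameters fitted on training-mask nodes only, so that no
   information from validation or test nodes leaks into preprocessing.

Coordinate conventions: gene intervals are BED-style (0-based, half-open);
SNP positions are 1-based. Window distances are computed by direct
coordinate subtraction, ``d = max(start − pos, pos − end, 0)``, and windows
are inclusive (``d ≤ window``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "GenomicInterval",
    "SnpInteraction",
    "GeneEdge",
    "LabelSet",
    "GeneGraph",
    "select_candidate_genes",
    "map_snps_to_genes",
    "build_gene_edges",
    "filter_top_fraction",
    "derive_negative_set",
    "assemble_graph",
    "normalize_features",
]

MASK_NONE = "none"
MASK_TRAIN = "train"
MASK_VAL = "val"
MASK_TEST = "test"
UNLABELED = -1


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class SnpRecord:
    """A GWAS SNP: identifier, chromosome, 1-based position, association p."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"SNP {self.snp_id}: p-value must be in (0, 1]")


@dataclass(frozen=True)
class GenomicInterval:
    """A gene body in BED convention (0-based start, half-open end)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass(frozen=True)
class SnpInteraction:
    """An unordered SNP pair with an epistasis p-value, stored canonically."""

    snp_a: str
    snp_b: str
    p_interaction: float

    def __post_init__(self):
        if self.snp_a == self.snp_b:
            raise ValueError("interaction endpoints must differ")
        if self.snp_a > self.snp_b:
            a, b = self.snp_b, self.snp_a
            object.__setattr__(self, "snp_a", a)
            object.__setattr__(self, "snp_b", b)
        if not (0.0 < self.p_interaction <= 1.0):
            raise ValueError("interaction p-value must be in (0, 1]")


@dataclass(frozen=True)
class GeneEdge:
    """An undirected gene–gene edge weighted by −log10 interaction p."""

    gene_a: str
    gene_b: str
    weight: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("self-edges are not allowed")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)
        if self.weight < 0:
            raise ValueError("edge weight must be nonnegative")


@dataclass
class LabelSet:
    """Disjoint positive / negative / unlabeled gene-id sets."""

    positives: set
    negatives: set
    unlabeled: set = field(default_factory=set)

    def __post_init__(self):
        self.positives = set(self.positives)
        self.negatives = set(self.negatives)
        self.unlabeled = set(self.unlabeled)
        if (
            self.positives & self.negatives
            or self.positives & self.unlabeled
            or self.negatives & self.unlabeled
        ):
            raise ValueError("label sets must be pairwise disjoint")


@dataclass
class GeneGraph:
    """An attributed gene graph with labels and train/val/test masks.

    Attributes
    ----------
    node_ids : ordered gene identifiers (defines row order of ``features``).
    features : float matrix, nodes × features, no missing entries.
    edges : undirected weighted :class:`GeneEdge` list.
    labels : int array; 1 positive, 0 negative, −1 unlabeled.
    masks : string array over {"train", "val", "test", "none"}.
    """

    node_ids: list
    features: np.ndarray
    edges: list
    labels: np.ndarray
    masks: np.ndarray
    #: pre-normalization feature matrix (NaN = missing), kept so that
    #: cross-validation can refit imputation/scaling on each fold's
    #: training rows; ``None`` when the graph was loaded without it.
    raw_features: np.ndarray | None = None

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.masks = np.asarray(self.masks, dtype=object)
        idx = self.index
        for e in self.edges:
            if e.gene_a not in idx or e.gene_b not in idx:
                raise ValueError(f"edge endpoint not in node set: {e}")
        if np.isnan(self.features).any():
            raise ValueError("feature matrix contains missing entries")
        labeled = self.labels != UNLABELED
        if np.any((self.masks != MASK_NONE) & ~labeled):
            raise ValueError("only labeled nodes may carry a split mask")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def index(self) -> dict:
        return {g: i for i, g in enumerate(self.node_ids)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (src, dst, weight) index arrays for the undirected edges."""
        idx = self.index
        if not self.edges:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), np.zeros(0)
        src = np.array([idx[e.gene_a] for e in self.edges], dtype=np.int64)
        dst = np.array([idx[e.gene_b] for e in self.edges], dtype=np.int64)
        w = np.array([e.weight for e in self.edges], dtype=np.float64)
        return src, dst, w

    def mask_indices(self, mask: str) -> np.ndarray:
        return np.flatnonzero(self.masks == mask)

    def adjacency(self) -> list:
        """Neighbor lists (undirected) as a list of int arrays."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        src, dst, _ = self.edge_arrays()
        for s, d in zip(src, dst):
            nbrs[s].append(d)
            nbrs[d].append(s)
        return [np.array(sorted(set(n)), dtype=np.int64) for n in nbrs]


# ----------------------------------------------------------------- distances
def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a SNP position to a gene body by coordinate subtraction.

    Zero inside the body; upstream/downstream gaps are measured directly on
    the stored coordinates (1-based SNP vs BED start/end).
    """
    return max(start - pos, pos - end, 0)


# ---------------------------------------------------------------- operations
def select_candidate_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GenomicInterval],
    p_threshold: float = 5e-8,
    window_bp: int = 1_000_000,
) -> set:
    """Genes within ``window_bp`` (inclusive) of a significant SNP.

    A gene is a candidate if at least one SNP with ``p_value < p_threshold``
    on the same chromosome lies within ``window_bp`` of the gene body.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not genes:
        warnings.warn("empty gene list: no candidate genes can be selected")
        return set()
    sig = [s for s in snps if s.p_value < p_threshold]
    out = set()
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in sig:
        by_chrom.setdefault(s.chrom, []).append(s)
    for g in genes:
        for s in by_chrom.get(g.chrom, ()):
            if _interval_distance(s.pos, g.start, g.end) <= window_bp:
                out.add(g.gene_id)
                break
    return out


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GenomicInterval],
    window_bp: int = 1_000,
) -> dict:
    """Assign each SNP to every gene whose body lies within ``window_bp``.

    Returns a mapping gene_id → set of snp_ids; a SNP may map to several
    genes and genes with no nearby SNP are omitted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    mapping: dict[str, set] = {}
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for g in genes:
        hits = {
            s.snp_id
            for s in by_chrom.get(g.chrom, ())
            if _interval_distance(s.pos, g.start, g.end) <= window_bp
        }
        if hits:
            mapping[g.gene_id] = hits
    return mapping


def build_gene_edges(
    interactions: Sequence[SnpInteraction],
    snp_gene_map: Mapping[str, Iterable[str]],
) -> list:
    """Aggregate SNP-pair epistasis to gene-pair edges.

    For each unordered gene pair bridged by at least one interaction the
    edge weight is the maximum −log10(p) over bridging SNP pairs. SNPs
    absent from the map are skipped (counted in a warning summary);
    self-pairs are never emitted.
    """
    snp_to_genes: dict[str, set] = {}
    for gene, snp_ids in snp_gene_map.items():
        for sid in snp_ids:
            snp_to_genes.setdefault(sid, set()).add(gene)
    best: dict[tuple, float] = {}
    n_unmapped = 0
    for it in interactions:
        genes_a = snp_to_genes.get(it.snp_a)
        genes_b = snp_to_genes.get(it.snp_b)
        if not genes_a or not genes_b:
            n_unmapped += 1
            continue
        w = -np.log10(it.p_interaction)
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue
                key = (ga, gb) if ga < gb else (gb, ga)
                if w > best.get(key, -1.0):
                    best[key] = w
    if n_unmapped:
        warnings.warn(f"skipped {n_unmapped} interactions with unmapped SNPs")
    return [GeneEdge(a, b, w) for (a, b), w in sorted(best.items())]


def filter_top_fraction(edges: Sequence[GeneEdge], fraction: float) -> list:
    """Keep the ``max(1, floor(fraction·|E|))`` heaviest edges.

    Ties at the cutoff are broken by canonical (gene_a, gene_b) order so the
    result is deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if not edges:
        raise ValueError("edge list must be non-empty")
    k = max(1, int(np.floor(fraction * len(edges))))
    ranked = sorted(edges, key=lambda e: (-e.weight, e.gene_a, e.gene_b))
    return ranked[:k]


def derive_negative_set(
    low_expression_genes: Iterable[str],
    positives: Iterable[str],
    interaction_pairs: Iterable[tuple],
) -> set:
    """Negative training genes: low-expression genes that neither are
    positives nor share a protein-interaction pair with any positive."""
    low = set(low_expression_genes)
    pos = set(positives)
    partners: set = set()
    for a, b in interaction_pairs:
        if a in pos:
            partners.add(b)
        if b in pos:
            partners.add(a)
    return low - pos - partners


def assemble_graph(
    candidates: Iterable[str],
    labels: LabelSet,
    edges: Sequence[GeneEdge],
    omics_tables: Sequence[pd.DataFrame],
    split_masks: Mapping[str, str],
) -> GeneGraph:
    """Assemble the final :class:`GeneGraph` with leakage-free preprocessing.

    Nodes are the union of candidate genes and labeled genes (sorted for
    determinism); labeled genes absent from the edge list are retained as
    isolated nodes. Features are the column-concatenation of the omics
    tables (indexed by gene_id); each column is imputed with the median of
    its observed training-mask values and then z-scored with the mean/SD of
    its (imputed) training-mask values. Validation and test rows never
    influence the fitted parameters.
    """
    labeled = set(labels.positives) | set(labels.negatives)
    node_ids = sorted(set(candidates) | labeled)
    if not node_ids:
        raise ValueError("empty node set")
    n = len(node_ids)
    pos = set(labels.positives)
    neg = set(labels.negatives)
    label_arr = np.full(n, UNLABELED, dtype=np.int64)
    mask_arr = np.full(n, MASK_NONE, dtype=object)
    for i, g in enumerate(node_ids):
        if g in pos:
            label_arr[i] = 1
        elif g in neg:
            label_arr[i] = 0
        m = split_masks.get(g, MASK_NONE)
        if label_arr[i] != UNLABELED and m != MASK_NONE:
            mask_arr[i] = m

    if omics_tables:
        frames = []
        for t, tab in enumerate(omics_tables):
            tab = tab.copy()
            tab.columns = [f"t{t}:{c}" for c in tab.columns]
            frames.append(tab.reindex(node_ids).astype(float))
        raw = pd.concat(frames, axis=1).to_numpy(dtype=np.float64)
    else:
        raw = np.zeros((n, 0))

    train_rows = np.flatnonzero(mask_arr == MASK_TRAIN)
    feats, _ = normalize_features(raw, train_rows)

    all_missing = np.isnan(raw).all(axis=1) if raw.shape[1] else np.zeros(n, bool)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} genes had all features missing; imputed rows")

    node_set = set(node_ids)
    kept_edges = [e for e in edges if e.gene_a in node_set and e.gene_b in node_set]
    return GeneGraph(node_ids, feats, kept_edges, label_arr, mask_arr, raw_features=raw)


def normalize_features(
    raw: np.ndarray, train_rows: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Impute and z-score a raw feature matrix using training rows only.

    Each column's missing entries are filled with the median of its observed
    training values, then the column is standardized with the mean/SD of its
    (imputed) training rows. Columns that are constant (SD = 0) or entirely
    missing on the training rows fall back to SD 1 / median 0 with a
    warning. Returns the normalized matrix and the fitted parameters
    (``median``, ``mean``, ``sd`` per column) so leakage can be audited.
    """
    raw = np.asarray(raw, dtype=np.float64)
    train_rows = np.asarray(train_rows, dtype=np.int64)
    feats = raw.copy()
    d = feats.shape[1]
    params = {"median": np.zeros(d), "mean": np.zeros(d), "sd": np.ones(d)}
    for j in range(d):
        col = feats[:, j]
        train_vals = col[train_rows]
        observed = train_vals[~np.isnan(train_vals)]
        if observed.size == 0:
            warnings.warn(f"feature column {j}: no observed training values; using 0")
            med, mu, sd = 0.0, 0.0, 1.0
            col[np.isnan(col)] = med
        else:
            med = float(np.median(observed))
            col[np.isnan(col)] = med
            imputed_train = col[train_rows]
            mu = float(imputed_train.mean())
            sd = float(imputed_train.std())
            if sd == 0.0:
                warnings.warn(f"feature column {j}: constant on training nodes; SD set to 1")
                sd = 1.0
        feats[:, j] = (col - mu) / sd
        params["median"][j], params["mean"][j], params["sd"][j] = med, mu, sd
    return feats, params
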
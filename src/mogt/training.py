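"""Splitting, mini-batch training with masked supervision, and evaluation.

Labeled genes are first divided into a training pool and a hold-out test
set by stratified sampling; the pool is then split into stratified
cross-validation folds. Training iterates mini-batches of train-mask
centers; each batch is the induced subgraph on the centers' first- and
second-order neighborhoods, so unlabeled, validation and test genes
participate as context but never contribute labels or gradients. Early
stopping monitors validation average precision (AUPRC); the checkpoint with
the best validation AUPRC is returned. The operating threshold for calling
high-risk genes (HRGs) is chosen by Youden's index on the selected model's
validation scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .graph_build import (
    GeneGraph,
    MASK_NONE,
    MASK_TEST,
    MASK_TRAIN,
    MASK_VAL,
    UNLABELED,
    normalize_features,
)
from .model import LossConfig, ModelConfig, MOGTModule, SubgraphBatch
from .nn import Adam

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "EvalReport",
    "stratified_holdout",
    "kfold_assign",
    "sample_subgraph",
    "two_hop_ego_nets",
    "train_model",
    "predict_probabilities",
    "single_fold_masks",
    "youden_threshold",
    "evaluate",
    "random_baseline_auprc",
    "classify_genes",
    "cross_validate",
    "CVResult",
]


# -------------------------------------------------------------------- configs
@dataclass
class SplitSpec:
    """Hold-out fraction, number of CV folds and the split seed."""

    holdout_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    max_epochs: int = 500
    patience: int = 50
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class EvalReport:
    """Hold-out metrics plus the per-gene probability/class table."""

    auroc: float
    auprc: float
    f1: float
    threshold: float
    per_gene: pd.DataFrame | None = None


# --------------------------------------------------------------------- splits
def stratified_holdout(
    labels: Mapping[str, int], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Split labeled gene ids into train/test preserving class proportions."""
    ids = sorted(labels)
    y = np.array([labels[g] for g in ids])
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
    train_ids, test_ids = train_test_split(
        ids, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return sorted(train_ids), sorted(test_ids)


def kfold_assign(
    train_ids: Sequence[str], labels: Mapping[str, int], k: int = 5, seed: int = 0
) -> dict:
    """Stratified fold index per gene; folds are near-equal in size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = sorted(train_ids)
    y = np.array([labels[g] for g in ids])
    min_class = min(np.bincount(y).min(), len(ids))
    k_eff = k
    if min_class < k:
        warnings.warn(
            f"smallest class has {min_class} members < {k} folds; using {min_class} folds"
        )
        k_eff = max(2, int(min_class))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(ids)), y)):
        for i in val_idx:
            fold_of[ids[i]] = fold
    return fold_of


# ------------------------------------------------------------------- batching
def two_hop_ego_nets(graph: GeneGraph) -> list:
    """Sorted node-index array of every node's {self} ∪ 1-hop ∪ 2-hop set."""
    adj = graph.adjacency()
    egos = []
    for c in range(graph.n_nodes):
        parts = [np.array([c], dtype=np.int64), adj[c]]
        parts.extend(adj[int(nb)] for nb in adj[c])
        egos.append(np.unique(np.concatenate(parts)))
    return egos


def sample_subgraph(
    graph: GeneGraph,
    centers: Sequence[int],
    adjacency: list | None = None,
    ego_cache: list | None = None,
) -> SubgraphBatch:
    """Induced subgraph on the centers' ∪ 1-hop ∪ 2-hop neighborhoods.

    Center nodes are tagged; each center's pooling domain is its own 2-hop
    ego net. Edge weights are preserved as attention biases, and every
    batch node receives a zero-bias self-loop. ``ego_cache`` (from
    :func:`two_hop_ego_nets`) avoids recomputing neighborhoods across
    batches.
    """
    centers = np.asarray(sorted(set(int(c) for c in centers)), dtype=np.int64)
    if centers.size == 0:
        raise ValueError("no centers given")
    if ego_cache is not None:
        ego_lists = [ego_cache[int(c)] for c in centers]
    else:
        adj = adjacency if adjacency is not None else graph.adjacency()
        ego_lists = []
        for c in centers:
            parts = [np.array([int(c)], dtype=np.int64), adj[c]]
            parts.extend(adj[int(nb)] for nb in adj[c])
            ego_lists.append(np.unique(np.concatenate(parts)))
    nodes = np.unique(np.concatenate(ego_lists))

    src, dst, w = graph.edge_arrays()
    keep = np.isin(src, nodes) & np.isin(dst, nodes)
    es = np.searchsorted(nodes, src[keep])
    ed = np.searchsorted(nodes, dst[keep])
    ew = w[keep]
    loops = np.arange(len(nodes), dtype=np.int64)
    d_src = np.concatenate([es, ed, loops])
    d_dst = np.concatenate([ed, es, loops])
    d_w = np.concatenate([ew, ew, np.zeros(len(nodes))])
    # sort by destination: every node has a self-loop, so the sorted dst
    # array covers all batch nodes and supports reduceat-based softmax
    order = np.argsort(d_dst, kind="stable")
    d_src, d_dst, d_w = d_src[order], d_dst[order], d_w[order]

    member_node = np.concatenate(
        [np.searchsorted(nodes, ego) for ego in ego_lists]
    )
    member_center = np.concatenate(
        [np.full(len(ego), j, dtype=np.int64) for j, ego in enumerate(ego_lists)]
    )
    return SubgraphBatch(
        node_index=nodes,
        features=graph.features[nodes],
        src=d_src,
        dst=d_dst,
        edge_bias=d_w,
        centers=centers,
        member_node=member_node,
        member_center=member_center,
    )


# ------------------------------------------------------------------- training
def train_model(
    graph: GeneGraph,
    model_cfg: ModelConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[MOGTModule, pd.DataFrame]:
    """Train on the graph's train mask, early-stopping on validation AUPRC.

    Returns the best-validation checkpoint and the epoch history
    (epoch, train_loss, val_auprc, val_auroc). Fully deterministic given
    the configs (all randomness derives from ``train_cfg.seed``); test-mask
    labels are never read.
    """
    model_cfg = model_cfg or ModelConfig()
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()

    train_idx = graph.mask_indices(MASK_TRAIN)
    val_idx = graph.mask_indices(MASK_VAL)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("graph must carry non-empty train and val masks")

    ss = np.random.SeedSequence(train_cfg.seed)
    init_seed, shuffle_seed, dropout_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    module = MOGTModule(graph.n_features, model_cfg, seed=init_seed)
    opt = Adam(
        module.parameters(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    shuffle_rng = np.random.default_rng(shuffle_seed)
    dropout_rng = np.random.default_rng(dropout_seed)

    egos = two_hop_ego_nets(graph)
    val_batch = sample_subgraph(graph, val_idx, ego_cache=egos)
    val_labels = graph.labels[val_batch.centers]
    if len(np.unique(val_labels)) < 2:
        raise ValueError("validation fold must contain both classes")

    best_state = module.state_dict()
    best_auprc = -np.inf
    best_epoch = -1
    rows = []
    for epoch in range(train_cfg.max_epochs):
        order = shuffle_rng.permutation(train_idx)
        losses, weights = [], []
        for start in range(0, len(order), train_cfg.batch_size):
            chunk = order[start : start + train_cfg.batch_size]
            batch = sample_subgraph(graph, chunk, ego_cache=egos)
            out = module.forward(batch, training=True, rng=dropout_rng)
            labels = graph.labels[batch.centers]
            loss = module.loss(out, labels, np.arange(batch.n_centers), loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch of {batch.n_centers} centers)"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            weights.append(batch.n_centers)
        train_loss = float(np.average(losses, weights=weights))

        val_out = module.forward(val_batch, training=False)
        val_scores = val_out.probabilities.data
        val_auprc = float(average_precision_score(val_labels, val_scores))
        val_auroc = float(roc_auc_score(val_labels, val_scores))
        rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_auprc": val_auprc,
                "val_auroc": val_auroc,
            }
        )
        if val_auprc > best_auprc:
            best_auprc = val_auprc
            best_epoch = epoch
            best_state = module.state_dict()
        elif epoch - best_epoch >= train_cfg.patience:
            break

    module.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_auprc"] = float(best_auprc)
    return module, history


def predict_probabilities(
    module: MOGTModule, graph: GeneGraph, nodes: Sequence[int] | None = None
) -> np.ndarray:
    """Deterministic per-node positive-class probabilities."""
    idx = np.arange(graph.n_nodes) if nodes is None else np.asarray(sorted(nodes))
    batch = sample_subgraph(graph, idx)
    out = module.forward(batch, training=False)
    order = {int(c): i for i, c in enumerate(batch.centers)}
    return np.array([out.probabilities.data[order[int(i)]] for i in idx])


# ----------------------------------------------------------------- evaluation
def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the unique observed scores and the decision
    rule is ``score >= threshold``. Ties are broken by higher sensitivity,
    then by the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum()) / n_pos
        spec = float((~pred & (labels == 0)).sum()) / n_neg
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1]


def evaluate(scores, labels, threshold: float, gene_ids=None) -> EvalReport:
    """AUROC (rank statistic, ties averaged), AUPRC (average precision) and
    positive-class F1 at the given threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    pred = (scores >= threshold).astype(int)
    report = EvalReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, pred, zero_division=0.0)),
        threshold=float(threshold),
    )
    if gene_ids is not None:
        report.per_gene = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "probability": scores,
                "class": np.where(pred == 1, "HRG", "LRG"),
            }
        )
    return report


def random_baseline_auprc(n_pos: int, n_neg: int) -> float:
    """Expected AUPRC of an uninformative ranker: the positive prevalence."""
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if n_neg < 0:
        raise ValueError("n_neg must be >= 0")
    return n_pos / (n_pos + n_neg)


def classify_genes(probabilities: Mapping[str, float], threshold: float) -> tuple[list, list]:
    """Partition scored genes into HRGs (p ≥ threshold) and LRGs."""
    hrg = sorted(g for g, p in probabilities.items() if p >= threshold)
    lrg = sorted(g for g, p in probabilities.items() if p < threshold)
    return hrg, lrg


# ------------------------------------------------------------ cross-validation
@dataclass
class CVResult:
    """Best-fold model plus fold-level metrics and the hold-out report."""

    module: MOGTModule
    best_fold: int
    threshold: float
    fold_metrics: pd.DataFrame
    report: EvalReport
    history: pd.DataFrame
    probabilities: pd.DataFrame = field(default_factory=pd.DataFrame)


def _fold_masks(graph: GeneGraph, fold_of: Mapping[str, int], fold: int, test_ids) -> np.ndarray:
    masks = np.full(graph.n_nodes, MASK_NONE, dtype=object)
    test = set(test_ids)
    for i, g in enumerate(graph.node_ids):
        if graph.labels[i] == UNLABELED:
            continue
        if g in test:
            masks[i] = MASK_TEST
        elif g in fold_of:
            masks[i] = MASK_VAL if fold_of[g] == fold else MASK_TRAIN
    return masks


def single_fold_masks(graph: GeneGraph, split: SplitSpec | None = None) -> np.ndarray:
    """Masks for one train/val/test split: stratified hold-out plus fold 0
    of the stratified k-fold assignment as the validation set."""
    split = split or SplitSpec()
    labeled = {
        g: int(l) for g, l in zip(graph.node_ids, graph.labels) if l != UNLABELED
    }
    train_ids, test_ids = stratified_holdout(
        labeled, train_fraction=1.0 - split.holdout_fraction, seed=split.seed
    )
    fold_of = kfold_assign(train_ids, labeled, k=split.n_folds, seed=split.seed)
    return _fold_masks(graph, fold_of, 0, test_ids)


def cross_validate(
    graph: GeneGraph,
    model_cfg: ModelConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    split: SplitSpec | None = None,
) -> CVResult:
    """Stratified hold-out + k-fold CV; returns the best-fold model.

    For every fold the train/val/test masks are reassigned and — when the
    graph carries its raw feature matrix — imputation and z-scoring are
    refitted on that fold's training rows only. The fold with the highest
    validation AUPRC supplies the final model; its validation scores set
    the Youden threshold, and performance is reported on the hold-out set.
    """
    model_cfg = model_cfg or ModelConfig()
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    split = split or SplitSpec()

    labeled = {
        g: int(l)
        for g, l in zip(graph.node_ids, graph.labels)
        if l != UNLABELED
    }
    train_ids, test_ids = stratified_holdout(
        labeled, train_fraction=1.0 - split.holdout_fraction, seed=split.seed
    )
    fold_of = kfold_assign(train_ids, labeled, k=split.n_folds, seed=split.seed)
    n_folds = max(fold_of.values()) + 1

    best = None
    fold_rows = []
    for fold in range(n_folds):
        g_fold = GeneGraph(
            node_ids=graph.node_ids,
            features=graph.features,
            edges=graph.edges,
            labels=graph.labels,
            masks=_fold_masks(graph, fold_of, fold, test_ids),
            raw_features=graph.raw_features,
        )
        if graph.raw_features is not None:
            g_fold.features, _ = normalize_features(
                graph.raw_features, g_fold.mask_indices(MASK_TRAIN)
            )
        fold_seed = (train_cfg.seed * 10007 + fold) % (2**31)
        cfg = TrainConfig(**{**train_cfg.__dict__, "seed": fold_seed})
        module, history = train_model(g_fold, model_cfg, loss_cfg, cfg)
        val_auprc = history.attrs["best_val_auprc"]
        val_idx = g_fold.mask_indices(MASK_VAL)
        val_scores = predict_probabilities(module, g_fold, val_idx)
        val_auroc = float(roc_auc_score(graph.labels[val_idx], val_scores))
        fold_rows.append(
            {"fold": fold, "val_auprc": val_auprc, "val_auroc": val_auroc}
        )
        if best is None or val_auprc > best["val_auprc"]:
            best = {
                "fold": fold,
                "val_auprc": val_auprc,
                "module": module,
                "graph": g_fold,
                "history": history,
                "val_idx": val_idx,
                "val_scores": val_scores,
            }

    threshold = youden_threshold(
        best["val_scores"], graph.labels[best["val_idx"]]
    )
    g_best = best["graph"]
    test_idx = g_best.mask_indices(MASK_TEST)
    test_scores = predict_probabilities(best["module"], g_best, test_idx)
    report = evaluate(
        test_scores,
        graph.labels[test_idx],
        threshold,
        gene_ids=[graph.node_ids[i] for i in test_idx],
    )
    all_scores = predict_probabilities(best["module"], g_best)
    probs = pd.DataFrame(
        {
            "gene_id": graph.node_ids,
            "probability": all_scores,
            "class": np.where(all_scores >= threshold, "HRG", "LRG"),
        }
    )
    return CVResult(
        module=best["module"],
        best_fold=best["fold"],
        threshold=threshold,
        fold_metrics=pd.DataFrame(fold_rows),
        report=report,
        history=best["history"],
        probabilities=probs,
    )
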
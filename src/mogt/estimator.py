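"""High-level modelling interface: ``MOGT`` (model) and ``MOGTResults``.

Mirrors the convention of statistical modelling libraries: a model object
is built from data (a :class:`~mogt.graph_build.GeneGraph`), ``fit()``
performs the stratified hold-out split, k-fold cross-validation, best-fold
selection, Youden thresholding and hold-out evaluation, and returns a
results object carrying the fitted weights, fold-level metrics, the
operating threshold and the per-gene risk table, with a ``summary()``.

Example
-------
>>> from mogt import MOGT, SimGraphConfig, simulate_gene_graph
>>> graph, _ = simulate_gene_graph(SimGraphConfig(seed=0))
>>> res = MOGT(graph).fit(seed=0)
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_build import GeneGraph, UNLABELED
from .model import LossConfig, ModelConfig, MOGTModule
from .training import (
    CVResult,
    SplitSpec,
    TrainConfig,
    classify_genes,
    cross_validate,
    predict_probabilities,
    random_baseline_auprc,
)

__all__ = ["MOGT", "MOGTResults"]


class MOGT:
    """Prototype-augmented graph-transformer risk-gene classifier.

    Parameters
    ----------
    graph : GeneGraph
        Attributed gene graph with binary labels on a subset of nodes.
    model_config, loss_config : optional
        Encoder and loss hyperparameters; defaults follow the reference
        setting (2 attention layers, hidden 64, 4 heads, dropout 0.4,
        7 prototypes per class, focal α = 0.25, γ = 2).
    """

    def __init__(
        self,
        graph: GeneGraph,
        model_config: ModelConfig | None = None,
        loss_config: LossConfig | None = None,
    ):
        labels = graph.labels[graph.labels != UNLABELED]
        if len(np.unique(labels)) < 2:
            raise ValueError("graph must contain labeled genes of both classes")
        self.graph = graph
        self.model_config = model_config or ModelConfig()
        self.loss_config = loss_config or LossConfig()

    @classmethod
    def from_graph_dir(cls, graph_dir, **kwargs) -> "MOGT":
        """Build a model from a persisted graph directory (see mogt.io)."""
        from .io import load_graph

        return cls(load_graph(graph_dir), **kwargs)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        split: SplitSpec | None = None,
        seed: int | None = None,
    ) -> "MOGTResults":
        """Run CV training and hold-out evaluation; return the results.

        ``seed``, when given, overrides both the split seed and the
        training seed so one integer reproduces the whole fit.
        """
        train_config = train_config or TrainConfig()
        split = split or SplitSpec()
        if seed is not None:
            train_config = TrainConfig(**{**train_config.__dict__, "seed": int(seed)})
            split = SplitSpec(**{**split.__dict__, "seed": int(seed)})
        cv = cross_validate(
            self.graph, self.model_config, self.loss_config, train_config, split
        )
        return MOGTResults(self, cv, train_config, split)


class MOGTResults:
    """Fitted-model results: weights, metrics, threshold, per-gene risks."""

    def __init__(self, model: MOGT, cv: CVResult, train_config: TrainConfig, split: SplitSpec):
        self.model = model
        self.cv = cv
        self.train_config = train_config
        self.split = split

    # ------------------------------------------------------------- accessors
    @property
    def module(self) -> MOGTModule:
        return self.cv.module

    @property
    def threshold(self) -> float:
        return self.cv.threshold

    @property
    def auroc(self) -> float:
        return self.cv.report.auroc

    @property
    def auprc(self) -> float:
        return self.cv.report.auprc

    @property
    def f1(self) -> float:
        return self.cv.report.f1

    @property
    def fold_metrics(self) -> pd.DataFrame:
        return self.cv.fold_metrics

    @property
    def history(self) -> pd.DataFrame:
        return self.cv.history

    def predict(self, graph: GeneGraph | None = None) -> pd.DataFrame:
        """Per-gene probabilities and HRG/LRG calls for ``graph`` (default:
        the training graph, all nodes)."""
        if graph is None:
            return self.cv.probabilities.copy()
        scores = predict_probabilities(self.module, graph)
        return pd.DataFrame(
            {
                "gene_id": graph.node_ids,
                "probability": scores,
                "class": np.where(scores >= self.threshold, "HRG", "LRG"),
            }
        )

    def classify(self) -> tuple[list, list]:
        """HRG and LRG gene lists over all scored nodes."""
        probs = dict(
            zip(self.cv.probabilities["gene_id"], self.cv.probabilities["probability"])
        )
        return classify_genes(probs, self.threshold)

    # --------------------------------------------------------------- reports
    def report_dict(self) -> dict:
        """JSON-serializable evaluation report."""
        rep = self.cv.report
        test = rep.per_gene
        n_pos = n_neg = 0
        if test is not None:
            test_labels = self.model.graph.labels[
                [self.model.graph.index[g] for g in test["gene_id"]]
            ]
            n_pos = int((test_labels == 1).sum())
            n_neg = int((test_labels == 0).sum())
        folds = self.fold_metrics
        return {
            "auroc": rep.auroc,
            "auprc": rep.auprc,
            "f1": rep.f1,
            "threshold": rep.threshold,
            "best_fold": int(self.cv.best_fold),
            "fold_metrics": folds.to_dict(orient="records"),
            "val_auprc_mean": float(folds["val_auprc"].mean()),
            "val_auprc_sd": float(folds["val_auprc"].std(ddof=1)),
            "test_n_pos": n_pos,
            "test_n_neg": n_neg,
            "random_baseline_auprc": (
                random_baseline_auprc(n_pos, n_neg) if n_pos else None
            ),
            "ablation": {
                "use_prototype_loss": self.model.loss_config.use_prototype_loss,
                "n_edges": len(self.model.graph.edges),
            },
            "config": {
                "model": asdict(self.model.model_config),
                "loss": asdict(self.model.loss_config),
                "train": asdict(self.train_config),
                "split": asdict(self.split),
            },
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        d = self.report_dict()
        hrg, lrg = self.classify()
        lines = [
            "MOGT risk-gene classification results",
            "=" * 53,
            f"nodes: {self.model.graph.n_nodes}   "
            f"edges: {len(self.model.graph.edges)}   "
            f"features: {self.model.graph.n_features}",
            f"folds: {len(d['fold_metrics'])} (best fold {d['best_fold']})   "
            f"val AUPRC {d['val_auprc_mean']:.4f} ± {d['val_auprc_sd']:.4f}",
            "-" * 53,
            f"hold-out AUROC      {d['auroc']:.4f}",
            f"hold-out AUPRC      {d['auprc']:.4f}"
            + (
                f"   (random baseline {d['random_baseline_auprc']:.4f})"
                if d["random_baseline_auprc"] is not None
                else ""
            ),
            f"hold-out F1         {d['f1']:.4f}",
            f"Youden threshold    {d['threshold']:.4f}",
            f"HRGs / LRGs         {len(hrg)} / {len(lrg)}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write checkpoint, history, fold metrics, report and predictions."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.module.save(out / "checkpoint.npz")
        self.history.to_csv(out / "history.tsv", sep="\t", index=False)
        self.fold_metrics.to_csv(out / "fold_metrics.tsv", sep="\t", index=False)
        self.cv.probabilities.to_csv(out / "predictions.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report_dict(), fh, indent=2)
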
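"""The MOGT network: graph-transformer encoder, prototype layer and losses.

Architecture (per mini-batch of sampled subgraphs):

    graph-transformer layer 1 → layer-norm → graph-transformer layer 2 →
    layer-norm → per-center elementwise max-pool over the center's sampled
    subgraph → dropout → FC1 (ReLU) → FC2 → logit → sigmoid probability

Each graph-transformer layer is multi-head scaled dot-product attention
restricted to graph edges (plus a self-loop per node); the edge weight
(−log10 of the SNP–SNP interaction p-value) is added as a bias to the
pre-softmax attention score, so strong epistatic links attract attention.

The prototype layer holds K = J × M learnable vectors (M per class) in the
pooled-embedding space. Training combines a focal classification loss —
cross-entropy reweighted by α_t(1−p_t)^γ to counter the heavy class
imbalance of disease-gene labels — with a prototype contrastive loss that
pulls each labeled embedding toward prototypes of its own class and away
from the other class's prototypes. The total objective is their unweighted
sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Tensor, gather, layer_norm, scatter_matrix, segment_max, segment_sum

__all__ = [
    "ModelConfig",
    "LossConfig",
    "PrototypeSet",
    "ForwardOutput",
    "SubgraphBatch",
    "MOGTModule",
    "prototype_similarity",
    "prototype_contrastive_loss",
    "focal_loss",
    "total_loss",
]

_PROB_CLIP = 1e-7
_CHECKPOINT_FORMAT = "mogt-checkpoint-v1"


# -------------------------------------------------------------------- configs
@dataclass
class ModelConfig:
    """Encoder hyperparameters."""

    n_layers: int = 2
    hidden_dim: int = 64
    n_heads: int = 4
    dropout: float = 0.4
    n_classes: int = 2
    prototypes_per_class: int = 7

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.prototypes_per_class < 1:
            raise ValueError("prototypes_per_class must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_prototypes(self) -> int:
        return self.n_classes * self.prototypes_per_class


@dataclass
class LossConfig:
    """Loss hyperparameters: contrastive temperature/eps, focal α and γ."""

    temperature: float = 0.5
    epsilon: float = 1e-4
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    prototype_denominator: str = "nonclass"  # or "all"
    use_prototype_loss: bool = True

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")
        if not (0.0 <= self.focal_alpha <= 1.0):
            raise ValueError("focal_alpha must be in [0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be nonnegative")
        if self.prototype_denominator not in ("nonclass", "all"):
            raise ValueError("prototype_denominator must be 'nonclass' or 'all'")


@dataclass
class PrototypeSet:
    """K = J×M learnable prototype vectors with their class assignment."""

    vectors: Tensor
    class_of: np.ndarray

    @classmethod
    def initialize(cls, n_classes: int, per_class: int, dim: int, rng: np.random.Generator):
        k = n_classes * per_class
        vec = rng.standard_normal((k, dim)) / np.sqrt(dim)
        class_of = np.repeat(np.arange(n_classes), per_class)
        return cls(vectors=Tensor(vec, requires_grad=True), class_of=class_of)

    def __post_init__(self):
        self.class_of = np.asarray(self.class_of, dtype=np.int64)
        counts = np.bincount(self.class_of)
        if len(set(counts)) != 1:
            raise ValueError("each class must have the same number of prototypes")


@dataclass
class ForwardOutput:
    """Per-node embeddings, logits and positive-class probabilities.

    ``embeddings``/``logits``/``probabilities`` are autodiff tensors during
    training; ``.data`` exposes the numpy values.
    """

    embeddings: Tensor
    logits: Tensor
    probabilities: Tensor


@dataclass
class SubgraphBatch:
    """An induced subgraph over the union of the centers' 2-hop ego nets.

    ``src``/``dst``/``edge_bias`` are directed edges within the batch (both
    directions of each undirected edge plus one zero-bias self-loop per
    node). ``member_node``/``member_center`` list, sorted by center, the
    batch-local rows belonging to each center's own ego net — the pooling
    domain of that center.
    """

    node_index: np.ndarray   # batch row -> original graph node index
    features: np.ndarray     # (B, d)
    src: np.ndarray
    dst: np.ndarray
    edge_bias: np.ndarray
    centers: np.ndarray      # original graph node index per center
    member_node: np.ndarray
    member_center: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    def scatters(self) -> dict:
        """Cached sparse scatter matrices for src/dst/member index arrays."""
        cache = getattr(self, "_scatters", None)
        if cache is None:
            cache = {
                "src": scatter_matrix(self.src, self.n_nodes),
                "dst": scatter_matrix(self.dst, self.n_nodes),
                "member": scatter_matrix(self.member_node, self.n_nodes),
            }
            object.__setattr__(self, "_scatters", cache)
        return cache

    def dst_starts(self) -> np.ndarray:
        """First edge row of each destination node (dst is sorted and every
        node has a self-loop, so all nodes appear)."""
        cached = getattr(self, "_dst_starts", None)
        if cached is None:
            cached = np.searchsorted(self.dst, np.arange(self.n_nodes))
            object.__setattr__(self, "_dst_starts", cached)
        return cached

    def member_starts(self) -> np.ndarray:
        """First membership row of each center (each center's ego net
        contains the center itself, so all centers appear)."""
        cached = getattr(self, "_member_starts", None)
        if cached is None:
            cached = np.searchsorted(self.member_center, np.arange(self.n_centers))
            object.__setattr__(self, "_member_starts", cached)
        return cached


# --------------------------------------------------------------------- losses
def prototype_similarity(v_n, v_p, epsilon: float = 1e-4):
    """Similarity g(v_n, v_p) = ln((D + 1) / (D + ε)), D = Σ(v_n − v_p)².

    Strictly decreasing in the squared distance D; equals ln(1/ε) when the
    embedding coincides with the prototype and decays to 0 as D → ∞.
    Accepts numpy arrays (returns a float) or autodiff tensors.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if isinstance(v_n, Tensor) or isinstance(v_p, Tensor):
        diff = (v_n if isinstance(v_n, Tensor) else Tensor(v_n)) - v_p
        d = (diff * diff).sum()
        return ((d + 1.0) / (d + epsilon)).log()
    v_n = np.asarray(v_n, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    if not (np.isfinite(v_n).all() and np.isfinite(v_p).all()):
        raise ValueError("non-finite inputs")
    d = float(((v_n - v_p) ** 2).sum())
    return float(np.log((d + 1.0) / (d + epsilon)))


def _pairwise_similarity(embeddings: Tensor, prototypes: Tensor, epsilon: float) -> Tensor:
    """g(v_i, v_k) for every embedding/prototype pair, shape (N, K)."""
    e2 = (embeddings * embeddings).sum(axis=1, keepdims=True)
    p2 = (prototypes * prototypes).sum(axis=1, keepdims=True).reshape(1, -1)
    # squared distances, clamped at 0 against floating-point cancellation
    cross = embeddings @ _transpose(prototypes)
    d = (e2 + p2 - 2.0 * cross).relu()
    return ((d + 1.0) / (d + epsilon)).log()


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g.T)

    out._backward = bw
    return out


def _masked_logsumexp(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise log Σ_{k∈mask} exp(scores[., k]), numerically stabilized."""
    neg = np.where(mask, 0.0, -np.inf)
    shifted = scores.data + neg
    row_max = shifted.max(axis=1, keepdims=True)
    if not np.isfinite(row_max).all():
        raise ValueError("a row has no prototypes in the required set")
    ex = ((scores + neg) - row_max).exp()
    return (ex.sum(axis=1)).log() + Tensor(row_max.ravel())


def prototype_contrastive_loss(
    embeddings,
    labels,
    prototypes: PrototypeSet,
    temperature: float = 0.5,
    epsilon: float = 1e-4,
    denominator: str = "nonclass",
):
    """Prototype contrastive loss over a batch of labeled embeddings.

    L = −(1/N) Σ_i log [ Σ_{m: class(m)=y_i} exp(g_i,m / T)
                        / Σ_{j: class(j)≠y_i} exp(g_i,j / T) ]

    The denominator runs over prototypes *not* of the node's class (set
    ``denominator="all"`` for the conventional InfoNCE normalization). The
    value may be negative.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    emb = embeddings if isinstance(embeddings, Tensor) else Tensor(np.atleast_2d(embeddings))
    labels = np.asarray(labels, dtype=np.int64)
    if emb.shape[0] == 0:
        raise ValueError("empty batch")
    if labels.shape[0] != emb.shape[0]:
        raise ValueError("labels and embeddings disagree in length")
    g = _pairwise_similarity(emb, prototypes.vectors, epsilon) * (1.0 / temperature)
    pos_mask = prototypes.class_of[None, :] == labels[:, None]
    if not pos_mask.any(axis=1).all():
        raise ValueError("some batch class has no prototypes")
    den_mask = np.ones_like(pos_mask) if denominator == "all" else ~pos_mask
    if not den_mask.any(axis=1).all():
        raise ValueError("denominator prototype set is empty for some node")
    num = _masked_logsumexp(g, pos_mask)
    den = _masked_logsumexp(g, den_mask)
    return -(num - den).mean()


def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0):
    """Focal loss −α_t (1−p_t)^γ ln(p_t); batched inputs return the mean.

    ``p`` is the model's probability for the positive class; ``p_t`` is p
    for positives and 1−p for negatives, α_t is α for positives and 1−α for
    negatives. Probabilities are clipped to [1e-7, 1−1e-7].
    """
    scalar = np.isscalar(p) and np.isscalar(y)
    if isinstance(p, Tensor):
        y_arr = np.asarray(y, dtype=float)
        pc = p.clip(_PROB_CLIP, 1.0 - _PROB_CLIP)
        p_t = pc * y_arr + (1.0 - pc) * (1.0 - y_arr)
        alpha_t = alpha * y_arr + (1.0 - alpha) * (1.0 - y_arr)
        return -(alpha_t * (1.0 - p_t) ** gamma * p_t.log()).mean()
    p_arr = np.clip(np.asarray(p, dtype=float), _PROB_CLIP, 1.0 - _PROB_CLIP)
    y_arr = np.asarray(y, dtype=float)
    p_t = np.where(y_arr == 1, p_arr, 1.0 - p_arr)
    alpha_t = np.where(y_arr == 1, alpha, 1.0 - alpha)
    val = -alpha_t * (1.0 - p_t) ** gamma * np.log(p_t)
    return float(val) if scalar else float(val.mean())


def total_loss(focal, l_pl):
    """Total objective: unweighted sum of focal and prototype losses."""
    return focal + l_pl


# ---------------------------------------------------------------------- model
class MOGTModule:
    """Parameter container and forward pass of the MOGT network."""

    def __init__(self, n_features: int, model_cfg: ModelConfig, seed: int = 0):
        self.cfg = model_cfg
        self.n_features = int(n_features)
        rng = np.random.default_rng(seed)
        h = model_cfg.hidden_dim
        self.params: dict[str, Tensor] = {}

        def param(name, shape, scale=None):
            if scale is None:
                scale = 1.0 / np.sqrt(shape[0])
            t = Tensor(rng.standard_normal(shape) * scale, requires_grad=True)
            self.params[name] = t
            return t

        d_in = self.n_features
        for layer in range(model_cfg.n_layers):
            for w in ("Wq", "Wk", "Wv"):
                param(f"l{layer}.{w}", (d_in, h))
            param(f"l{layer}.Wo", (h, h))
            self.params[f"l{layer}.bo"] = Tensor(np.zeros(h), requires_grad=True)
            self.params[f"l{layer}.ln_g"] = Tensor(np.ones(h), requires_grad=True)
            self.params[f"l{layer}.ln_b"] = Tensor(np.zeros(h), requires_grad=True)
            d_in = h
        param("fc1.W", (h, h))
        self.params["fc1.b"] = Tensor(np.zeros(h), requires_grad=True)
        param("fc2.W", (h, 1))
        self.params["fc2.b"] = Tensor(np.zeros(1), requires_grad=True)
        self.prototypes = PrototypeSet.initialize(
            model_cfg.n_classes, model_cfg.prototypes_per_class, h, rng
        )
        self.params["prototypes"] = self.prototypes.vectors

    # ------------------------------------------------------------------ infra
    def parameters(self) -> list:
        return list(self.params.values())

    def state_dict(self) -> dict:
        return {k: np.array(v.data) for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    def save(self, path) -> None:
        """Serialize config + all weights into a single .npz checkpoint."""
        meta = json.dumps(
            {
                "format": _CHECKPOINT_FORMAT,
                "n_features": self.n_features,
                "model": asdict(self.cfg),
            }
        )
        np.savez(path, __meta__=np.array(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "MOGTModule":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            if meta.get("format") != _CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format: {meta.get('format')}")
            module = cls(meta["n_features"], ModelConfig(**meta["model"]))
            module.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        return module

    # ---------------------------------------------------------------- forward
    def _attention_layer(self, x: Tensor, layer: int, batch: SubgraphBatch) -> Tensor:
        cfg = self.cfg
        n = batch.n_nodes
        dh = cfg.hidden_dim // cfg.n_heads
        sc = batch.scatters()
        q = x @ self.params[f"l{layer}.Wq"]
        k = x @ self.params[f"l{layer}.Wk"]
        v = x @ self.params[f"l{layer}.Wv"]
        qe = gather(q, batch.dst, scatter=sc["dst"])
        ke = gather(k, batch.src, scatter=sc["src"])
        ve = gather(v, batch.src, scatter=sc["src"])
        scores = (
            (qe * ke).reshape(-1, cfg.n_heads, dh).sum(axis=-1) * (1.0 / np.sqrt(dh))
        )
        scores = scores + batch.edge_bias[:, None]
        # per-destination softmax, stabilized with a detached segment max
        shift = np.maximum.reduceat(scores.data, batch.dst_starts(), axis=0)
        ex = (scores - shift[batch.dst]).exp()
        denom = segment_sum(ex, batch.dst, n, scatter=sc["dst"])
        alpha = ex / gather(denom, batch.dst, scatter=sc["dst"])
        msg = alpha.reshape(-1, cfg.n_heads, 1) * ve.reshape(-1, cfg.n_heads, dh)
        out = segment_sum(
            msg.reshape(-1, cfg.hidden_dim), batch.dst, n, scatter=sc["dst"]
        )
        out = out @ self.params[f"l{layer}.Wo"] + self.params[f"l{layer}.bo"]
        return layer_norm(out, self.params[f"l{layer}.ln_g"], self.params[f"l{layer}.ln_b"])

    def forward(
        self,
        batch: SubgraphBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ForwardOutput:
        """Run the encoder on a batch; deterministic when ``training=False``."""
        if batch.n_nodes == 0 or batch.n_centers == 0:
            raise ValueError("empty batch")
        if batch.features.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {batch.features.shape[1]} != model {self.n_features}"
            )
        x = Tensor(batch.features)
        for layer in range(self.cfg.n_layers):
            x = self._attention_layer(x, layer, batch)
        pooled = segment_max(
            gather(x, batch.member_node, scatter=batch.scatters()["member"]),
            batch.member_center,
            batch.n_centers,
            starts=batch.member_starts(),
        )
        if training and self.cfg.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            pooled = pooled.dropout(self.cfg.dropout, rng)
        hidden = (pooled @ self.params["fc1.W"] + self.params["fc1.b"]).relu()
        logits = (hidden @ self.params["fc2.W"] + self.params["fc2.b"]).reshape(-1)
        probs = logits.sigmoid()
        return ForwardOutput(embeddings=pooled, logits=logits, probabilities=probs)

    def loss(
        self,
        out: ForwardOutput,
        labels: np.ndarray,
        supervised: np.ndarray,
        loss_cfg: LossConfig,
    ) -> Tensor:
        """Total training loss over the supervised (train-mask) centers only."""
        sup = np.asarray(supervised)
        if sup.dtype == bool:
            sup = np.flatnonzero(sup)
        if sup.size == 0:
            raise ValueError("no supervised nodes in batch")
        y = np.asarray(labels, dtype=np.int64)[sup]
        p = gather(out.probabilities.reshape(-1, 1), sup).reshape(-1)
        fl = focal_loss(p, y, loss_cfg.focal_alpha, loss_cfg.focal_gamma)
        if not loss_cfg.use_prototype_loss:
            return fl
        emb = gather(out.embeddings, sup)
        lpl = prototype_contrastive_loss(
            emb,
            y,
            self.prototypes,
            temperature=loss_cfg.temperature,
            epsilon=loss_cfg.epsilon,
            denominator=loss_cfg.prototype_denominator,
        )
        return total_loss(fl, lpl)
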
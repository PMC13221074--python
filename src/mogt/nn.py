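"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is a compact autodiff core purpose-built for the graph-transformer in
:mod:`mogt.model`: dense ops (matmul, elementwise arithmetic, reductions)
plus the sparse/segment primitives a graph attention layer needs (row
``gather``, ``segment_sum``, ``segment_max``).  Gradients are accumulated by
a topological backward sweep from a scalar loss; every primitive's backward
is exact (no approximations) and is gradient-checked against central finite
differences in the test suite.

Conventions
-----------
* ``Tensor`` wraps a float64 ``numpy.ndarray``.  Mixed Tensor/ndarray/scalar
  arithmetic is supported; plain arrays are treated as constants.
* Broadcasting follows numpy; backward un-broadcasts by summing over the
  broadcast axes.
* Segment primitives require the segment-id array to be sorted ascending
  (callers in :mod:`mogt.model` pre-sort edge and membership arrays once).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather",
    "scatter_matrix",
    "segment_sum",
    "segment_max",
    "layer_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make `ndarray <op> Tensor` defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self.grad: np.ndarray | None = None
        self._prev = _prev
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -------------------------------------------------------------- unary ops
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _prev=(self,))

        # capture the array, not `out`: a closure referencing its own tensor
        # would create reference cycles and stall the garbage collector
        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (hard clip)."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * mask


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ functions
def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bw
    return out


def scatter_matrix(idx: np.ndarray, n_rows: int):
    """CSR matrix S with S[idx[e], e] = 1: ``S @ x`` scatter-adds edge rows
    into node rows. Shared by :func:`gather` (backward) and
    :func:`segment_sum` (forward) — much faster than ``np.add.at``."""
    from scipy import sparse

    idx = np.asarray(idx, dtype=np.int64)
    e = idx.size
    return sparse.csr_matrix(
        (np.ones(e), (idx, np.arange(e))), shape=(n_rows, e)
    )


def gather(t: Tensor, idx: np.ndarray, scatter=None) -> Tensor:
    """Select rows ``t[idx]`` (first axis), differentiably.

    ``scatter`` may carry the precomputed :func:`scatter_matrix` of ``idx``
    to speed up the backward scatter-add (2-D tensors only).
    """
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(t.data[idx], _prev=(t,))

    def bw(g):
        if not t.requires_grad:
            return
        if scatter is not None and g.ndim == 2:
            t._accumulate(scatter @ g)
        else:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = bw
    return out


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int, scatter=None) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row segment ids."""
    seg = np.asarray(seg, dtype=np.int64)
    if scatter is not None and t.data.ndim == 2:
        data = scatter @ t.data
    else:
        data = np.zeros((n_segments,) + t.data.shape[1:], dtype=np.float64)
        np.add.at(data, seg, t.data)
    out = Tensor(data, _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g[seg])

    out._backward = bw
    return out


def segment_max(t: Tensor, seg: np.ndarray, n_segments: int, starts=None) -> Tensor:
    """Per-segment elementwise max; ``seg`` must be sorted ascending.

    The gradient is routed to the first occurrence of the maximum within
    each segment (deterministic tie-break); the argmax mask is computed
    lazily so evaluation-only forwards skip it. When every segment is
    non-empty, ``starts`` (the first row of each segment) enables the fast
    ``np.maximum.reduceat`` path; empty segments yield 0 with no gradient.
    """
    seg = np.asarray(seg, dtype=np.int64)
    if seg.size and np.any(np.diff(seg) < 0):
        raise ValueError("segment ids must be sorted ascending")
    if starts is not None:
        data = np.maximum.reduceat(t.data, starts, axis=0)
    else:
        data = np.full((n_segments,) + t.data.shape[1:], -np.inf)
        np.maximum.at(data, seg, t.data)
        empty = ~np.isin(np.arange(n_segments), seg)
        if np.any(empty):
            data[empty] = 0.0
    out = Tensor(data, _prev=(t,))

    def _first_mask():
        # first-occurrence argmax mask, per segment, via cumsum offsets
        eq = t.data == data[seg]
        if not seg.size:
            return eq
        seg_starts = np.flatnonzero(np.r_[True, np.diff(seg) != 0])
        counts = np.diff(np.r_[seg_starts, seg.size])
        cum = np.cumsum(eq, axis=0, dtype=np.int64)
        prev_row = np.repeat(seg_starts, counts) - 1
        offset = np.where(
            (prev_row >= 0).reshape((-1,) + (1,) * (eq.ndim - 1)),
            cum[np.maximum(prev_row, 0)],
            0,
        )
        return eq & ((cum - offset) == 1)

    def bw(g):
        if t.requires_grad:
            t._accumulate(np.where(_first_mask(), g[seg], 0.0))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learnable affine parameters."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gamma + beta


class Adam:
    """Adam with decoupled L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
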
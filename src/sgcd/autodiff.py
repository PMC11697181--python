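"""Minimal reverse-mode automatic differentiation over numpy arrays.

The SGCD forward pass is a short, fixed pipeline of dense and sparse linear
maps with a handful of pointwise nonlinearities, so a small define-by-run
tape with exactly the operations that pipeline needs (plus the sparse
edge-value operations the explainer's mask optimization requires) is all the
machinery the package uses.  Everything is float64.

Only the operations used by :mod:`sgcd.model`, :mod:`sgcd.training` and
:mod:`sgcd.explain` are implemented; this is not a general tensor library.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "relu",
    "sigmoid",
    "log",
    "log_softmax",
    "concat",
    "tsum",
    "gather_rows",
    "take",
    "segment_sum",
    "power",
    "scatter_into",
    "spmm",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    if live:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes broadcasting expanded relative to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    return add(a, scale(b, -1.0))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)

    def backward(g):
        a._accumulate(c * g)

    return _make(a.data * c, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def log(a, eps: float = 0.0) -> Tensor:
    a = as_tensor(a)
    x = a.data + eps

    def backward(g):
        a._accumulate(g / x)

    return _make(np.log(x), (a,), backward)


def log_softmax(a) -> Tensor:
    """Row-wise log-softmax with max-subtraction for stability."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    out_data = shifted - logz
    soft = np.exp(out_data)

    def backward(g):
        a._accumulate(g - soft * g.sum(axis=1, keepdims=True))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, ts, backward)


def tsum(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(a.data.sum(), (a,), backward)


def gather_rows(a, idx) -> Tensor:
    """Select rows (2-D) or elements (1-D) by an integer index array."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        a._accumulate(acc)

    return _make(a.data[idx], (a,), backward)


take = gather_rows


def segment_sum(a, seg_ids, n_segments: int) -> Tensor:
    """out[s] = sum of a[k] over k with seg_ids[k] == s (1-D input)."""
    a = as_tensor(a)
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    data = np.zeros(n_segments, dtype=np.float64)
    np.add.at(data, seg_ids, a.data)

    def backward(g):
        a._accumulate(g[seg_ids])

    return _make(data, (a,), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    e = float(exponent)
    data = a.data**e

    def backward(g):
        a._accumulate(g * e * a.data ** (e - 1.0))

    return _make(data, (a,), backward)


def scatter_into(base: np.ndarray, idx, src) -> Tensor:
    """Constant vector `base` with base[idx] replaced by the tensor `src`.

    `idx` must not contain duplicates. Gradient flows only into `src`.
    """
    src = as_tensor(src)
    idx = np.asarray(idx, dtype=np.intp)
    data = np.array(base, dtype=np.float64, copy=True)
    data[idx] = src.data

    def backward(g):
        src._accumulate(g[idx])

    return _make(data, (src,), backward)


def spmm(rows, cols, shape: tuple[int, int], vals, dense) -> Tensor:
    """Sparse (COO structure, value vector) times dense matrix.

    Either `vals` (edge values) or `dense` or both may carry gradients; the
    sparse pattern itself is fixed.
    """
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    vals = as_tensor(vals)
    dense = as_tensor(dense)
    mat = sp.csr_matrix((vals.data, (rows, cols)), shape=shape)
    data = mat @ dense.data

    def backward(g):
        if vals.requires_grad or vals._parents:
            # d out[r,c] / d vals[k] = dense[col_k, c] at row r = row_k
            vals._accumulate(np.einsum("kc,kc->k", g[rows], dense.data[cols]))
        if dense.requires_grad or dense._parents:
            dense._accumulate(mat.T @ g)

    return _make(data, (vals, dense), backward)


class Adam:
    """Adam with additive L2 weight decay (decay folded into the gradient)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
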
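"""Minimal reverse-mode automatic differentiation over numpy arrays.

Exactly the operations a small transformer encoder needs: broadcasting
add/multiply, (batched) matmul, tanh/GELU, softmax, layer normalization,
embedding lookup, dropout, reshape/transpose, fused softmax cross-entropy.
Gradients are validated against central finite differences in the test
suite.  Everything runs in float64 single-threaded, which keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

#: Array dtype for all network state.  float32 is the working default;
#: switch to float64 when validating gradients against finite differences.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Tensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "gelu",
    "softmax",
    "layer_norm",
    "embedding",
    "dropout",
    "reshape",
    "transpose",
    "select_first",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward_fn: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = backward_fn
        self._parents = tuple(parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *g* down to *shape* (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    if isinstance(b, Tensor):
        out_data = a.data * b.data

        def backward(g):
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, (a, b), backward)

    scalar = float(b)

    def backward_s(g):
        a.accumulate(g * scalar)

    return Tensor(a.data * scalar, (a,), backward_s)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a.accumulate(_unbroadcast(ga, a.data.shape))
        b.accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def backward(g):
        a.accumulate(g * (1.0 - y * y))

    return Tensor(y, (a,), backward)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(a: Tensor) -> Tensor:
    """GELU with the tanh approximation."""
    x = a.data
    x2 = x * x
    inner = _GELU_C * (x + 0.044715 * x2 * x)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def backward(g):
        sech2 = 1.0 - t * t
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x2)
        a.accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * sech2 * dinner))

    return Tensor(y, (a,), backward)


def softmax(a: Tensor, bias: Optional[np.ndarray] = None) -> Tensor:
    """Softmax over the last axis, with an optional additive constant bias
    (used for attention masking; the bias carries no gradient)."""
    z = a.data if bias is None else a.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        a.accumulate(y * (g - dot))

    return Tensor(y, (a,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gamma.data * xhat + beta.data

    def backward(g):
        axes = tuple(range(g.ndim - 1))
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        gx = g * gamma.data
        m1 = gx.mean(axis=-1, keepdims=True)
        m2 = (gx * xhat).mean(axis=-1, keepdims=True)
        x.accumulate(inv * (gx - m1 - xhat * m2))

    return Tensor(y, (x, gamma, beta), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    y = table.data[ids]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids, g)
        table.accumulate(gt)

    return Tensor(y, (table,), backward)


def dropout(x: Tensor, p: float, rng: Optional[np.random.Generator]) -> Tensor:
    """Inverted dropout; identity when p == 0 or no rng (inference)."""
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def backward(g):
        x.accumulate(g * keep)

    return Tensor(x.data * keep, (x,), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    old = x.data.shape

    def backward(g):
        x.accumulate(g.reshape(old))

    return Tensor(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes: tuple) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        x.accumulate(g.transpose(inv))

    return Tensor(x.data.transpose(axes), (x,), backward)


def select_first(x: Tensor) -> Tensor:
    """Pooled output: the hidden state at sequence position 0 ([CLS])."""

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, 0, :] = g
        x.accumulate(gx)

    return Tensor(x.data[:, 0, :], (x,), backward)


def softmax_cross_entropy(
    logits: Tensor,
    labels: np.ndarray,
    sample_mask: Optional[np.ndarray] = None,
) -> tuple[Tensor, np.ndarray]:
    """Mean softmax cross-entropy between logits and integer class labels.

    ``logits`` may be (N, C) or (B, T, C); *labels* has the matching leading
    shape.  ``sample_mask`` (same leading shape, 0/1) excludes entries such
    as padding positions from the mean.  Returns the scalar loss tensor and
    the probabilities as a plain array.
    """
    z = logits.data
    labels = np.asarray(labels)
    flat = z.reshape(-1, z.shape[-1])
    lab = labels.reshape(-1)
    if sample_mask is None:
        m = np.ones(lab.shape, dtype=np.float64)
    else:
        m = np.asarray(sample_mask, dtype=np.float64).reshape(-1)
    zmax = flat.max(axis=-1, keepdims=True)
    e = np.exp(flat - zmax)
    probs = e / e.sum(axis=-1, keepdims=True)
    logp = (flat - zmax) - np.log(e.sum(axis=-1, keepdims=True))
    denom = max(m.sum(), 1.0)
    losses = -logp[np.arange(lab.size), lab] * m
    loss_val = losses.sum() / denom

    def backward(g):
        onehot = np.zeros_like(flat)
        onehot[np.arange(lab.size), lab] = 1.0
        gl = (probs - onehot) * (m / denom)[:, None] * g
        logits.accumulate(gl.reshape(z.shape))

    return Tensor(loss_val, (logits,), backward), probs.reshape(z.shape)
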
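"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the encoder/decoder stack
needs: broadcast-aware arithmetic, (batched) matmul, slicing/padding/
concatenation, softmax, layer normalisation, gather along the batch
axis, and a numerically stable binary cross-entropy on logits — plus an
Adam optimiser. Everything runs in float32 and is deterministic for a
fixed seed on a single device.

The design is a define-by-run tape: each operation returns a new
:class:`Tensor` holding references to its parents and a closure that
propagates the upstream gradient. ``Tensor.backward()`` topologically
sorts the tape and accumulates gradients into every tensor created with
``requires_grad=True``.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward: Callable | None = None, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would overflow recursion
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
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._backward is not None:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._backward is not None:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * s
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(g * s)

    return Tensor(out_data, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad or a._backward is not None:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._backward is not None:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape: Sequence[int]) -> Tensor:
    out_data = a.data.reshape(shape)
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return Tensor(out_data, parents=(a,), backward=backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accumulate(full)

    return Tensor(out_data, parents=(a,), backward=backward)


def pad_axis(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    pads = [(0, 0)] * a.ndim
    pads[axis] = (before, after)
    out_data = np.pad(a.data, pads)
    if not _needs(a):
        return Tensor(out_data)

    idx = [slice(None)] * a.ndim
    idx[axis] = slice(before, before + a.data.shape[axis])
    idx = tuple(idx)

    def backward(g):
        a._accumulate(g[idx])

    return Tensor(out_data, parents=(a,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(_needs(t) for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._backward is not None:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(s, e)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def gather(a: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows along axis 0; duplicated indices sum their gradients."""
    indices = np.asarray(indices)
    out_data = a.data[indices]
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, indices, g)
        a._accumulate(full)

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return Tensor(out_data, parents=(a,), backward=backward)


def softmax(a: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, with an optional additive logit bias.

    ``bias`` (e.g. a large negative mask for padded keys) is a plain
    array and receives no gradient.
    """
    z = a.data if bias is None else a.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learned affine."""
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    if not _needs(a, gamma, beta):
        return Tensor(out_data)

    n = a.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, n).sum(axis=0))
        if a.requires_grad or a._backward is not None:
            gx = g * gamma.data
            da = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            a._accumulate(da)

    return Tensor(out_data, parents=(a, gamma, beta), backward=backward)


def mean_all(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.mean())
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(np.full_like(a.data, g / a.data.size))

    return Tensor(out_data, parents=(a,), backward=backward)


def sum_axis(a: Tensor, axis: int) -> Tensor:
    out_data = a.data.sum(axis=axis)
    if not _needs(a):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=DTYPE)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(loss.mean())
    if not _needs(logits):
        return Tensor(out_data)

    p = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        logits._accumulate(g * (p - y) / z.size)

    return Tensor(out_data, parents=(logits,), backward=backward)


# ---------------------------------------------------------------------------
# layers


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None,
           gain: float = 1.0) -> np.ndarray:
    limit = gain * math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, name: str,
                 gain: float = 1.0):
        self.w = parameter(xavier(rng, d_in, d_out, gain=gain), name=f"{name}.w")
        self.b = parameter(np.zeros(d_out, dtype=DTYPE), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)

    def parameters(self):
        return [self.w, self.b]


def conv1d_same(x: Tensor, w: Tensor, b: Tensor, kernel_size: int) -> Tensor:
    """Length-preserving 1D convolution.

    ``x`` is (..., L, C_in); ``w`` is (K*C_in, C_out) laid out as the K
    kernel taps stacked along the input-channel axis. Implemented as
    pad → K shifted slices → concat → matmul, so the backward pass falls
    out of the primitive ops.
    """
    k = kernel_size
    half = k // 2
    xp = pad_axis(x, x.ndim - 2, half, k - 1 - half)
    L = x.shape[-2]
    taps = [narrow(xp, x.ndim - 2, i, L) for i in range(k)]
    cols = concat(taps, axis=-1)
    return add(matmul(cols, w), b)


class Conv1dSame:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel_size: int, name: str):
        self.kernel_size = kernel_size
        fan_in = c_in * kernel_size
        self.w = parameter(xavier(rng, fan_in, c_out), name=f"{name}.w")
        self.b = parameter(np.zeros(c_out, dtype=DTYPE), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b, self.kernel_size)

    def parameters(self):
        return [self.w, self.b]


class LayerNorm:
    def __init__(self, d: int, name: str):
        self.gamma = parameter(np.ones(d, dtype=DTYPE), name=f"{name}.gamma")
        self.beta = parameter(np.zeros(d, dtype=DTYPE), name=f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most max_norm."""
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = math.sqrt(total)
        if norm > max_norm > 0:
            factor = max_norm / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad *= factor
        return norm

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
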
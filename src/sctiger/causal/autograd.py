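"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the per-target attention/convolution networks:
broadcasting add/mul, causal shifts along the time axis, PReLU, channel
sums, and mean-squared error — plus an Adam optimizer. Gradients are checked
against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar (used sparingly; explicit functions preferred)
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def shift_right(x, s: int) -> Tensor:
    """Shift along the last (time) axis by ``s`` steps, zero-padding the left.

    ``shift_right(x, s)[..., t] == x[..., t - s]`` (zero for t < s); the
    building block of causal convolutions.
    """
    x = _wrap(x)
    if s == 0:
        out_data = x.data.copy()
    else:
        out_data = np.zeros_like(x.data)
        out_data[..., s:] = x.data[..., :-s]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        if s == 0:
            x._accum(g)
        else:
            gg = np.zeros_like(g)
            gg[..., :-s] = g[..., s:]
            x._accum(gg)

    out._backward = backward
    return out


def prelu(x, alpha) -> Tensor:
    """Parametric ReLU with a scalar (or broadcastable) slope tensor."""
    x, alpha = _wrap(x), _wrap(alpha)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, alpha.data * x.data), parents=(x, alpha))

    def backward(g):
        if x.requires_grad:
            x._accum(np.where(pos, g, alpha.data * g))
        if alpha.requires_grad:
            alpha._accum(_unbroadcast(np.where(pos, 0.0, x.data) * g, alpha.data.shape))

    out._backward = backward
    return out


def sum_channels(x) -> Tensor:
    """Sum over the first (channel) axis, keeping the time axis."""
    x = _wrap(x)
    out = Tensor(x.data.sum(axis=0, keepdims=True), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g, x.data.shape).copy())

    out._backward = backward
    return out


def mse(pred, target) -> Tensor:
    """Mean squared error against a constant target array."""
    pred = _wrap(pred)
    t = np.asarray(target, dtype=np.float64)
    diff = pred.data - t
    out = Tensor(np.mean(diff**2), parents=(pred,))

    def backward(g):
        if pred.requires_grad:
            pred._accum(g * 2.0 * diff / diff.size)

    out._backward = backward
    return out


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
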
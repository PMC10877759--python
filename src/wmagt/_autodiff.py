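"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the model needs are implemented: broadcasting
arithmetic, matmul, ReLU/sigmoid/log/exp/sqrt/power, reductions,
row gather, concatenation and clamping, plus an Adam optimizer.
Everything runs in float64 for deterministic, reproducible training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "sqrt",
    "tsum",
    "tmean",
    "concat",
    "reshape",
    "take_rows",
    "clamp",
    "masked_softmax",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (self._accumulate(g), other._accumulate(g)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                self._accumulate(g * other.data),
                other._accumulate(g * self.data),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accumulate(g / other.data),
                other._accumulate(-g * self.data / other.data**2),
            ),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor._make(
            self.data**e,
            (self,),
            lambda g: self._accumulate(g * e * self.data ** (e - 1.0)),
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (
                self._accumulate(g @ other.data.T),
                other._accumulate(self.data.T @ g),
            ),
        )
        return out

    @property
    def T(self):
        out = Tensor._make(
            self.data.T, (self,), lambda g: self._accumulate(g.T)
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions --------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor._make(
        np.where(mask, x.data, 0.0), (x,), lambda g: x._accumulate(g * mask)
    )


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    s = np.where(
        x.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(x.data))),
        np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))),
    )
    return Tensor._make(s, (x,), lambda g: x._accumulate(g * s * (1.0 - s)))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._make(np.log(x.data), (x,), lambda g: x._accumulate(g / x.data))


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    return Tensor._make(e, (x,), lambda g: x._accumulate(g * e))


def sqrt(x: Tensor) -> Tensor:
    return x**0.5


def clamp(x: Tensor, lo: float | None = None, hi: float | None = None) -> Tensor:
    """Clip values; gradient is passed only where the input was inside."""
    x = as_tensor(x)
    out = np.clip(x.data, lo, hi)
    inside = np.ones_like(x.data, dtype=bool)
    if lo is not None:
        inside &= x.data >= lo
    if hi is not None:
        inside &= x.data <= hi
    return Tensor._make(out, (x,), lambda g: x._accumulate(g * inside))


# -- reductions and reshaping ----------------------------------------------

def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape))

    return Tensor._make(out, (x,), back)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(out, tuple(tensors), back)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    old = x.data.shape
    return Tensor._make(
        x.data.reshape(shape), (x,), lambda g: x._accumulate(g.reshape(old))
    )


def take_rows(x: Tensor, idx) -> Tensor:
    """Gather rows by integer index (with repetition allowed)."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_idx) != 0])
    uniq = sorted_idx[starts]

    def back(g):
        # segment-sum scatter-add (reduceat beats np.add.at by a wide margin)
        full = np.zeros_like(x.data)
        g = np.asarray(g)
        if g.ndim == 1:
            full[uniq] = np.add.reduceat(g[order], starts)
        else:
            full[uniq] = np.add.reduceat(g[order], starts, axis=0)
        x._accumulate(full)

    return Tensor._make(x.data[idx], (x,), back)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to `mask` (boolean); off-mask entries are 0.

    The row max over the mask is treated as a constant shift, which keeps the
    computation numerically stable without changing the derivative.
    """
    scores = as_tensor(scores)
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, 0.0, -1e30)
    shifted = scores + Tensor(neg)
    row_max = np.max(shifted.data, axis=1, keepdims=True)
    num = exp(shifted - Tensor(row_max))
    den = tsum(num, axis=1, keepdims=True)
    return num / den


# -- parameters and optimization -------------------------------------------

def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    """Glorot/Xavier uniform initialization as a trainable tensor."""
    if len(shape) >= 2:
        fan_in, fan_out = shape[-2], shape[-1]
    else:
        fan_in = fan_out = max(shape[0], 1)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with a mutable learning rate (for cyclic schedules)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
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
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
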
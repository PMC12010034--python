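"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the cascade networks and their DiceCE loss need are
implemented: broadcasting arithmetic, reductions, exp/log, slicing,
concatenation and log-softmax. Convolutions live in ``layers`` and build
their own backward closures on top of this tape.

Gradients are float32 throughout; every op is finite-difference checked in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward_fn: Optional[Callable[[Array], None]] = None,
        requires_grad: bool = False,
    ):
        self.data = _as_array(data)
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.grad: Optional[Array] = None

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- backward ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big volumes
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
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)
            if node is not self and node.parents:
                node.grad = None  # free intermediate gradients

    # ---- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def accumulate(t: Tensor, g: Array) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---- elementwise ops ----------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g: Array) -> None:
        accumulate(a, _unbroadcast(g, a.data.shape))
        accumulate(b, _unbroadcast(g, b.data.shape))

    out.backward_fn = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(g: Array) -> None:
        accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    out.backward_fn = backward
    return out


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, (a, b))

    def backward(g: Array) -> None:
        accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out.backward_fn = backward
    return out


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    val = np.exp(a.data)
    out = Tensor(val, (a,))

    def backward(g: Array) -> None:
        accumulate(a, g * val)

    out.backward_fn = backward
    return out


def log(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), (a,))

    def backward(g: Array) -> None:
        accumulate(a, g / a.data)

    out.backward_fn = backward
    return out


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def backward(g: Array) -> None:
        accumulate(a, g * (a.data > 0))

    out.backward_fn = backward
    return out


# ---- reductions / shape ops ---------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(g: Array) -> None:
        if axis is None:
            accumulate(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            gg = np.expand_dims(g, axes)
        accumulate(a, np.broadcast_to(gg, a.data.shape).copy())

    out.backward_fn = backward
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax % a.data.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def getitem(a: Tensor, idx) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data[idx], (a,))

    def backward(g: Array) -> None:
        full = np.zeros_like(a.data)
        full[idx] = g
        accumulate(a, full)

    out.backward_fn = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g: Array) -> None:
        accumulate(a, g.reshape(a.data.shape))

    out.backward_fn = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g: Array) -> None:
        start = 0
        for t, n in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            accumulate(t, g[tuple(sl)])
            start += n

    out.backward_fn = backward
    return out


def log_softmax(a: Tensor, axis: int = 1) -> Tensor:
    a = _wrap(a)
    m = a.data.max(axis=axis, keepdims=True)
    s = a.data - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    val = s - lse
    out = Tensor(val, (a,))
    soft = np.exp(val)

    def backward(g: Array) -> None:
        accumulate(a, g - soft * g.sum(axis=axis, keepdims=True))

    out.backward_fn = backward
    return out


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    return exp(log_softmax(a, axis=axis))
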
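"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float64 ndarray and
remembers, for each produced value, the parent tensors and a vector-Jacobian
product per parent.  Calling :meth:`Tensor.backward` on a scalar loss walks
the graph in reverse topological order and accumulates gradients into every
tensor created with ``requires_grad=True``.

Only the operations the sequence model needs are provided (broadcasting
add/mul, batched matmul, relu/tanh, fused softmax / log-softmax / layer
norm, reductions, reshape/transpose, concatenation, embedding gather,
inverted dropout).  Everything is float64 so that structural unit tests can
compare against oracles at 1e-9.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "softmax",
    "log_softmax",
    "tsum",
    "tmean",
    "reshape",
    "swapaxes",
    "concat",
    "take",
    "layer_norm",
    "dropout",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:  # float32 opted into explicitly, else f64
            arr = arr.astype(np.float64, copy=False)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                elif not p._parents:
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    grads[id(p)] = pg

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor division supported only by scalars")
        return mul(self, 1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple, vjps: tuple) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._vjps = vjps
    return out


# -- arithmetic --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.data.shape),
         lambda g: _unbroadcast(g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        (lambda g: _unbroadcast(g * b.data, a.data.shape),
         lambda g: _unbroadcast(g * a.data, b.data.shape)),
    )


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D; reshape vectors")

    if b.ndim == 2 and a.ndim > 2:
        # stacked rows x one weight matrix: a single large GEMM beats the
        # generic batched path by a wide margin
        m = a.data.shape[-1]
        a2 = a.data.reshape(-1, m)
        out = (a2 @ b.data).reshape(a.data.shape[:-1] + (b.data.shape[-1],))

        def grad_a(g):
            g2 = g.reshape(-1, b.data.shape[-1])
            return (g2 @ b.data.T).reshape(a.data.shape)

        def grad_b(g):
            return a2.T @ g.reshape(-1, b.data.shape[-1])

        return _make(out, (a, b), (grad_a, grad_b))

    def grad_a(g):
        return _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape)

    def grad_b(g):
        return _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape)

    return _make(np.matmul(a.data, b.data), (a, b), (grad_a, grad_b))


# -- nonlinearities ----------------------------------------------------

def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return _make(np.where(mask, x.data, 0.0), (x,), (lambda g: g * mask,))


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    y = np.tanh(x.data)
    return _make(y, (x,), (lambda g: g * (1.0 - y * y),))


def softmax(x, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return _make(y, (x,), (vjp,))


def log_softmax(x, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    p = np.exp(y)

    def vjp(g):
        return g - p * g.sum(axis=axis, keepdims=True)

    return _make(y, (x,), (vjp,))


# -- reductions & shape ------------------------------------------------

def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, x.data.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, x.data.shape).copy()

    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), (vjp,))


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(x, *shape) -> Tensor:
    x = _as_tensor(x)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    old = x.data.shape
    return _make(x.data.reshape(shape), (x,), (lambda g: g.reshape(old),))


def swapaxes(x, a1: int, a2: int) -> Tensor:
    x = _as_tensor(x)
    return _make(np.swapaxes(x.data, a1, a2), (x,),
                 (lambda g: np.swapaxes(g, a1, a2),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return vjp

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


# -- gather / normalisation / regularisation ---------------------------

def take(table, indices) -> Tensor:
    """Embedding lookup: rows of ``table`` selected by an integer array."""
    table = _as_tensor(table)
    idx = np.asarray(indices)

    def vjp(g):
        # grouped scatter-add via sort + reduceat (much faster than np.add.at)
        flat = idx.reshape(-1)
        g2 = g.reshape(-1, table.data.shape[-1])
        order = np.argsort(flat, kind="stable")
        sorted_idx = flat[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_idx) > 0])
        sums = np.add.reduceat(g2[order], starts, axis=0)
        out = np.zeros_like(table.data)
        out[sorted_idx[starts]] = sums
        return out

    return _make(table.data[idx], (table,), (vjp,))


def layer_norm(x, gain, shift, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    x, gain, shift = _as_tensor(x), _as_tensor(gain), _as_tensor(shift)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = xc / std
    y = xhat * gain.data + shift.data

    def vjp_x(g):
        dxhat = g * gain.data
        return (dxhat
                - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) / std

    def vjp_gain(g):
        return _unbroadcast(g * xhat, gain.data.shape)

    def vjp_shift(g):
        return _unbroadcast(g, shift.data.shape)

    return _make(y, (x, gain, shift), (vjp_x, vjp_gain, vjp_shift))


def dropout(x, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    x = _as_tensor(x)
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = ((rng.random(x.data.shape) >= rate) / (1.0 - rate)).astype(x.data.dtype)
    return _make(x.data * mask, (x,), (lambda g: g * mask,))
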
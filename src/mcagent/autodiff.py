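"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The loss functions in this package are smooth compositions of elementwise
maps, reductions, broadcasting arithmetic and matrix products, so a compact
tape-based engine is all that is needed to optimize them jointly with a
small backbone.  Every :class:`Tensor` wraps a float64 ``ndarray``; calling
:meth:`Tensor.backward` on a scalar output accumulates gradients into the
``grad`` attribute of every reachable leaf created with
``requires_grad=True``.

Most helpers here (``exp``, ``tsum``, ``tmax`` ...) accept either a
:class:`Tensor` or a plain ``ndarray`` and dispatch accordingly, which lets
the geometric primitives in :mod:`mcagent.core_geometry` be written once and
used both for plain evaluation and inside a differentiable loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "is_tensor",
    "value_of",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "cos",
    "arccos",
    "maximum",
    "minimum",
    "clip",
    "tsum",
    "tmax",
    "tmean",
    "matmul",
    "concatenate",
    "check_gradients",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # ndarray defers binary ops to Tensor

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # ---- graph traversal ----------------------------------------------
    def backward(self, seed=None):
        if seed is None:
            if self.value.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            seed = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(seed, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self):
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value + o.value,
            parents=(self, o),
            backward=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value * o.value,
            parents=(self, o),
            backward=lambda g: (
                _unbroadcast(g * o.value, self.shape),
                _unbroadcast(g * self.value, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value / o.value,
            parents=(self, o),
            backward=lambda g: (
                _unbroadcast(g / o.value, self.shape),
                _unbroadcast(-g * self.value / o.value**2, o.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.value**k,
            parents=(self,),
            backward=lambda g: (g * k * self.value ** (k - 1),),
        )

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.value.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(old),),
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.value.transpose(axes),
            parents=(self,),
            backward=lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, key):
        out = self.value[key]
        shape = self.shape

        def bw(g):
            acc = np.zeros(shape, dtype=np.float64)
            np.add.at(acc, key, g)
            return (acc,)

        return Tensor(out, parents=(self,), backward=bw)

    # ---- reductions (see module-level tsum/tmax for dispatch) ----------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def max(self, axis=None, keepdims=False):
        out = self.value.max(axis=axis, keepdims=True)
        mask = self.value == out  # ties share gradient equally
        counts = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            elif axis is None:
                g = np.asarray(g).reshape((1,) * self.ndim)
            return (mask * (g / counts),)

        res = out if keepdims or axis is None and self.ndim == 0 else (
            out.reshape(()) if axis is None else np.squeeze(out, axis=axis)
        )
        return Tensor(res, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x) -> np.ndarray:
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---- elementwise functions (Tensor or ndarray) -------------------------

def _elementwise(x, fn, dfn):
    if isinstance(x, Tensor):
        y = fn(x.value)
        return Tensor(y, parents=(x,), backward=lambda g: (g * dfn(x.value, y),))
    return fn(np.asarray(x, dtype=np.float64))


def exp(x):
    return _elementwise(x, np.exp, lambda v, y: y)


def log(x):
    return _elementwise(x, np.log, lambda v, y: 1.0 / v)


def sqrt(x):
    return _elementwise(x, np.sqrt, lambda v, y: 0.5 / y)


def tanh(x):
    return _elementwise(x, np.tanh, lambda v, y: 1.0 - y**2)


def cos(x):
    return _elementwise(x, np.cos, lambda v, y: -np.sin(v))


def arccos(x):
    return _elementwise(x, np.arccos, lambda v, y: -1.0 / np.sqrt(1.0 - v**2))


def maximum(x, y):
    if isinstance(x, Tensor) or isinstance(y, Tensor):
        xt, yt = as_tensor(x), as_tensor(y)
        out = np.maximum(xt.value, yt.value)
        xwins = xt.value >= yt.value  # ties route to the first argument
        return Tensor(
            out,
            parents=(xt, yt),
            backward=lambda g: (
                _unbroadcast(g * xwins, xt.shape),
                _unbroadcast(g * ~xwins, yt.shape),
            ),
        )
    return np.maximum(x, y)


def minimum(x, y):
    if isinstance(x, Tensor) or isinstance(y, Tensor):
        return -maximum(-as_tensor(x), -as_tensor(y))
    return np.minimum(x, y)


def clip(x, lo, hi):
    return minimum(maximum(x, lo), hi)


# ---- reductions / linear algebra (Tensor or ndarray) -------------------

def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tmax(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.max(axis=axis, keepdims=keepdims)
    return np.max(x, axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        at, bt = as_tensor(a), as_tensor(b)
        if at.ndim != 2 or bt.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(
            at.value @ bt.value,
            parents=(at, bt),
            backward=lambda g: (g @ bt.value.T, at.value.T @ g),
        )
    return np.asarray(a) @ np.asarray(b)


def concatenate(parts, axis=0):
    parts = [as_tensor(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([p.value for p in parts], axis=axis),
        parents=tuple(parts),
        backward=bw,
    )


def check_gradients(fn, params, step: float = 1e-5, rtol: float = 1e-3, atol: float = 1e-8):
    """Compare analytic gradients of scalar ``fn(*params)`` with central differences.

    Returns the worst relative discrepancy over all parameter entries.
    ``params`` are leaf Tensors with ``requires_grad=True``.
    """
    out = fn(*params)
    for p in params:
        p.zero_grad()
    out.backward()
    worst = 0.0
    for p in params:
        analytic = np.zeros(p.shape) if p.grad is None else p.grad
        numeric = np.zeros_like(p.value)
        flat = p.value.reshape(-1)
        nflat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            hi = float(value_of(fn(*params)))
            flat[i] = orig - step
            lo = float(value_of(fn(*params)))
            flat[i] = orig
            nflat[i] = (hi - lo) / (2 * step)
        denom = np.maximum(np.abs(analytic) + np.abs(numeric), atol / rtol)
        worst = max(worst, float(np.max(np.abs(analytic - numeric) / denom)))
    return worst
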
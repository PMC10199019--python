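"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package composes neural networks with numerical physics (glottal flow,
contact, projection) into one differentiable program, so every operation the
physics touches must propagate gradients.  This module provides the small
tensor algebra that makes that possible: a :class:`Tensor` wrapping a float64
ndarray, elementwise/broadcasting arithmetic, matmul, reductions (including
max/min with subgradient routing and a temperature-controlled soft minimum),
indexing/gather with scatter-add adjoints, and shape ops.

Design constraints:

* float64 everywhere — the physics operates on SI magnitudes spanning ~15
  orders (areas ~1e-8 m², stiffness ~1e3 Pa), float32 would lose the
  gradient checks;
* gradients accumulate into ``.grad`` via topological-order backward;
* broadcasting adjoints are summed back to the operand shape (``_unbroadcast``).

Functions here accept plain ndarrays transparently (treated as constants),
which lets the forward simulator reuse the same physics code without building
graphs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "is_tensor",
    "concatenate",
    "stack",
    "where",
    "maximum",
    "minimum",
    "relu",
    "absolute",
    "exp",
    "log",
    "sqrt",
    "square",
    "tanh",
    "sigmoid",
    "logsumexp",
    "softmin",
    "take",
    "matmul",
    "asarray",
]


def _to_value(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def asarray(x):
    """Detach: plain ndarray view of a Tensor or array-like."""
    return _to_value(x)


def expand_dims(a, axis: int):
    """Insert a length-1 axis (graph-safe replacement for None-indexing)."""
    if not isinstance(a, Tensor):
        return np.expand_dims(np.asarray(a, float), axis)
    shape = list(a.shape)
    if axis < 0:
        axis = len(shape) + 1 + axis
    shape.insert(axis, 1)
    return a.reshape(tuple(shape))


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that broadcasting introduced for `shape`."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the reverse-mode computation graph."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")
    __array_priority__ = 100  # numpy defers to our dunders

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def size(self):
        return self.value.size

    def item(self):
        return float(self.value)

    def detach(self) -> np.ndarray:
        return self.value

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self, grad=None):
        """Reverse sweep from this node; seeds with ones for scalars."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(node):
            stack_ = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack_:
                cur, it = stack_[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack_.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack_.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _binary(other, self, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / b ** 2)

    def __rtruediv__(self, other):
        return _binary(other, self, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / b ** 2)

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        return _unary(self, lambda a: a ** p, lambda g, a, out: g * p * a ** (p - 1))

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    # -- indexing / shapes ------------------------------------------------
    def __getitem__(self, idx):
        a = self

        def bwd(g, idx=idx):
            out = np.zeros_like(a.value)
            np.add.at(out, idx, g)
            a._accumulate(out)

        return Tensor(a.value[idx], parents=(a,),
                      backward=(lambda g: bwd(g)) if a.requires_grad else None)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor(a.value.reshape(shape), parents=(a,),
                      backward=(lambda g: a._accumulate(g.reshape(a.value.shape)))
                      if a.requires_grad else None)

    def transpose(self, *axes):
        axes = axes or None
        a = self
        inv = None if axes is None else tuple(np.argsort(axes))
        return Tensor(a.value.transpose(axes), parents=(a,),
                      backward=(lambda g: a._accumulate(g.transpose(inv)))
                      if a.requires_grad else None)

    @property
    def T(self):
        return self.transpose()

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = a.value.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.value.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.value.shape).copy())

        return Tensor(out, parents=(a,), backward=bwd if a.requires_grad else None)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def _extremum(self, axis, keepdims, fn, argfn):
        a = self
        out = fn(a.value, axis=axis, keepdims=keepdims)

        def bwd(g):
            # route gradient to the (first) arg-extremum — subgradient choice
            if axis is None:
                out_full = out
            else:
                out_full = out if keepdims else np.expand_dims(out, axis)
            mask = (a.value == out_full)
            if axis is None:
                mask = mask / mask.sum()
                a._accumulate(mask * g)
            else:
                cnt = mask.sum(axis=axis, keepdims=True)
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(mask / cnt * gg)

        return Tensor(out, parents=(a,), backward=bwd if a.requires_grad else None)

    def max(self, axis=None, keepdims=False):
        return self._extremum(axis, keepdims, np.max, np.argmax)

    def min(self, axis=None, keepdims=False):
        return self._extremum(axis, keepdims, np.min, np.argmin)


def as_tensor(x, requires_grad=False) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# op builders
# ---------------------------------------------------------------------------

def _unary(a, fn, grad_fn):
    if not isinstance(a, Tensor):
        return fn(np.asarray(a, dtype=float))
    out_val = fn(a.value)

    def bwd(g):
        a._accumulate(grad_fn(g, a.value, out_val))

    return Tensor(out_val, parents=(a,), backward=bwd if a.requires_grad else None)


def _binary(a, b, fn, grad_a, grad_b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return fn(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    ta, tb = as_tensor(a), as_tensor(b)
    out_val = fn(ta.value, tb.value)

    def bwd(g):
        if ta.requires_grad:
            ta._accumulate(_unbroadcast(grad_a(g, ta.value, tb.value), ta.value.shape))
        if tb.requires_grad:
            tb._accumulate(_unbroadcast(grad_b(g, ta.value, tb.value), tb.value.shape))

    parents = (ta, tb)
    return Tensor(out_val, parents=parents,
                  backward=bwd if (ta.requires_grad or tb.requires_grad) else None)


def matmul(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.matmul(np.asarray(a, float), np.asarray(b, float))
    ta, tb = as_tensor(a), as_tensor(b)
    av, bv = ta.value, tb.value
    out_val = np.matmul(av, bv)

    def bwd(g):
        if ta.requires_grad:
            if bv.ndim == 1:
                ga = np.multiply.outer(g, bv) if av.ndim > 1 else g * bv
            else:
                gg = g[..., None, :] if av.ndim == 1 else g
                ga = np.matmul(gg, np.swapaxes(bv, -1, -2))
                if av.ndim == 1:
                    ga = ga[..., 0, :]
            ta._accumulate(_unbroadcast(ga, av.shape))
        if tb.requires_grad:
            if av.ndim == 1:
                gb = np.multiply.outer(av, g) if bv.ndim > 1 else g * av
            else:
                gg = g[..., :, None] if bv.ndim == 1 else g
                gb = np.matmul(np.swapaxes(av, -1, -2), gg)
                if bv.ndim == 1:
                    gb = gb[..., 0]
            tb._accumulate(_unbroadcast(gb, bv.shape))

    return Tensor(out_val, parents=(ta, tb),
                  backward=bwd if (ta.requires_grad or tb.requires_grad) else None)


# ---------------------------------------------------------------------------
# elementwise functions (ndarray passthrough when no Tensor involved)
# ---------------------------------------------------------------------------

def exp(a):
    return _unary(a, np.exp, lambda g, x, out: g * out)


def log(a):
    return _unary(a, np.log, lambda g, x, out: g / x)


def sqrt(a):
    return _unary(a, np.sqrt, lambda g, x, out: g * 0.5 / out)


def square(a):
    return _unary(a, np.square, lambda g, x, out: g * 2.0 * x)


def tanh(a):
    return _unary(a, np.tanh, lambda g, x, out: g * (1.0 - out ** 2))


def sigmoid(a):
    fn = lambda x: 1.0 / (1.0 + np.exp(-x))
    return _unary(a, fn, lambda g, x, out: g * out * (1.0 - out))


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda g, x, out: g * (x > 0))


def absolute(a):
    return _unary(a, np.abs, lambda g, x, out: g * np.sign(x))


def maximum(a, b):
    return _binary(a, b, np.maximum,
                   lambda g, x, y: g * (x >= y), lambda g, x, y: g * (x < y))


def minimum(a, b):
    return _binary(a, b, np.minimum,
                   lambda g, x, y: g * (x <= y), lambda g, x, y: g * (x > y))


def where(cond, a, b):
    """cond is a constant boolean mask (no gradient through the predicate)."""
    cond = np.asarray(asarray(cond), dtype=bool)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, a, b)
    ta, tb = as_tensor(a), as_tensor(b)
    out = np.where(cond, ta.value, tb.value)

    def bwd(g):
        if ta.requires_grad:
            ta._accumulate(_unbroadcast(np.where(cond, g, 0.0), ta.value.shape))
        if tb.requires_grad:
            tb._accumulate(_unbroadcast(np.where(cond, 0.0, g), tb.value.shape))

    return Tensor(out, parents=(ta, tb),
                  backward=bwd if (ta.requires_grad or tb.requires_grad) else None)


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    tps = [as_tensor(p) for p in parts]
    out = np.concatenate([t.value for t in tps], axis=axis)
    sizes = [t.value.shape[axis] for t in tps]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tps, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, parents=tuple(tps),
                  backward=bwd if any(t.requires_grad for t in tps) else None)


def stack(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.stack(parts, axis=axis)
    tps = [as_tensor(p) for p in parts]
    out = np.stack([t.value for t in tps], axis=axis)

    def bwd(g):
        gs = np.moveaxis(g, axis, 0)
        for t, gi in zip(tps, gs):
            if t.requires_grad:
                t._accumulate(gi)

    return Tensor(out, parents=tuple(tps),
                  backward=bwd if any(t.requires_grad for t in tps) else None)


def take(a, indices, axis=0):
    """Gather along an axis with integer index arrays; adjoint scatter-adds."""
    if not isinstance(a, Tensor):
        return np.take(np.asarray(a, float), indices, axis=axis)
    indices = np.asarray(indices)
    out = np.take(a.value, indices, axis=axis)

    def bwd(g):
        buf = np.zeros_like(a.value)
        gm = np.moveaxis(g, axis, 0) if axis else g
        bm = np.moveaxis(buf, axis, 0) if axis else buf
        np.add.at(bm, indices, gm.reshape(indices.shape + bm.shape[1:]))
        a._accumulate(buf)

    return Tensor(out, parents=(a,), backward=bwd if a.requires_grad else None)


def logsumexp(a, axis=None, keepdims=False):
    shift = asarray(a).max(axis=axis, keepdims=True)
    shifted = exp(a - shift)
    s = shifted.sum(axis=axis, keepdims=True) if isinstance(shifted, Tensor) \
        else shifted.sum(axis=axis, keepdims=True)
    out = log(s) + shift
    if not keepdims and axis is not None:
        val = asarray(out)
        newshape = tuple(s for i, s in enumerate(val.shape) if i not in np.atleast_1d(
            axis % val.ndim if np.isscalar(axis) else axis))
        out = out.reshape(newshape) if isinstance(out, Tensor) else val.reshape(newshape)
    elif not keepdims and axis is None:
        out = out.reshape(()) if isinstance(out, Tensor) else np.asarray(out).reshape(())
    return out


def softmin(a, tau: float, axis=None, keepdims=False):
    """Smooth minimum: -tau*logsumexp(-a/tau). tau=0 falls back to the hard min."""
    if tau == 0.0:
        return a.min(axis=axis, keepdims=keepdims) if isinstance(a, Tensor) \
            else np.min(a, axis=axis, keepdims=keepdims)
    return -tau * logsumexp(-(a / tau) if isinstance(a, Tensor) else -np.asarray(a, float) / tau,
                            axis=axis, keepdims=keepdims)


def softmax_reduce(a, tau: float, axis=None, keepdims=False):
    """Smooth maximum: tau*logsumexp(a/tau); hard max at tau=0."""
    if tau == 0.0:
        return a.max(axis=axis, keepdims=keepdims) if isinstance(a, Tensor) \
            else np.max(a, axis=axis, keepdims=keepdims)
    x = (a / tau) if isinstance(a, Tensor) else np.asarray(a, float) / tau
    return tau * logsumexp(x, axis=axis, keepdims=keepdims)
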
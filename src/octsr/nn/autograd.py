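"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order accumulating gradients.  Only the operations needed by the networks in
this package are implemented (dense/convolutional algebra, pointwise
nonlinearities, reductions, gather/scatter and a bilinear warp).  Arrays are
kept in whatever float dtype they arrive in, so gradient checks can run in
float64 while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x, ref_dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    a = np.asarray(x)
    if ref_dtype is not None and a.dtype != ref_dtype and a.dtype.kind == "f":
        a = a.astype(ref_dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self._backward = None
        self._parents = ()
        self.name = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(other, ref_dtype):
        if isinstance(other, Tensor):
            return other
        return Tensor(_as_array(other, ref_dtype))

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        track = is_grad_enabled() and any(p.requires_grad for p in parents)
        if track:
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            # Always copy: upstream may hand the same buffer to several parents.
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other, self.dtype)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = self._wrap(other, self.dtype)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(-g, b.shape))

        return Tensor._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor(_as_array(other, self.dtype)) - self

    def __mul__(self, other):
        other = self._wrap(other, self.dtype)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other, self.dtype)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(_as_array(other, self.dtype)) / self

    def __pow__(self, p: float):
        def bwd(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other, self.dtype)

        def bwd(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- pointwise
    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self):
            a._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope).astype(self.dtype)

        def bwd(g, a=self):
            a._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), bwd)

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g, a=self):
            a._accum(g * (1.0 - out * out))

        return Tensor._make(out, (self,), bwd)

    def exp(self):
        out = np.exp(self.data)

        def bwd(g, a=self):
            a._accum(g * out)

        return Tensor._make(out, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bwd(g, a=self):
            a._accum(g * 0.5 / out)

        return Tensor._make(out, (self,), bwd)

    def softplus(self):
        # log(1 + e^x), numerically stable form
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self):
            a._accum(g * sig)

        return Tensor._make(out, (self,), bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self):
            a._accum(g * out * (1.0 - out))

        return Tensor._make(out, (self,), bwd)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g, a=self):
            a._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g, a=self):
            a._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g, a=self):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accum(buf)

        return Tensor._make(self.data[idx], (self,), bwd)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        e = np.exp(shifted)
        s = e.sum(axis=axis, keepdims=True)
        out = (m + np.log(s))
        softmax = e / s

        def bwd(g, a=self):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(gg * softmax)

        return Tensor._make(out if keepdims else np.squeeze(out, axis), (self,), bwd)


class Parameter(Tensor):
    """A Tensor registered as a trainable network weight."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # Parameters stay trainable even if created inside a no_grad block.
        self.requires_grad = True


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)
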
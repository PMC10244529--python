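"""Minimal reverse-mode autodifferentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``.  The op set is
exactly what a small convolutional regression network needs — elementwise
arithmetic with broadcasting, matmul over stacked batch dimensions, reductions,
shape ops, 2-D padding/cropping, softmax, and the usual activations.  The
convolution / pooling / batch-norm primitives live in
:mod:`hmhn.nn.functional`.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "no_grad", "stack", "manual_seed", "default_rng"]

# Global autograd switch (mirrors the usual eval-time "no_grad" idiom).
_GRAD_ENABLED = True

# Global RNG used for parameter init and dropout; reseedable for reproducibility.
_GENERATOR = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reseed the library-wide RNG (parameter init, dropout masks)."""
    global _GENERATOR
    _GENERATOR = np.random.default_rng(seed)


def default_rng() -> np.random.Generator:
    return _GENERATOR


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind in "ui":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev = _prev if _GRAD_ENABLED else ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        """Build a graph node; parents that don't need grad are pruned."""
        parents = tuple(p for p in parents if p.requires_grad or p._prev)
        out = Tensor(data, requires_grad=bool(parents), _prev=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # Iterative topological sort (graphs can be ~1e3 nodes deep).
        topo, visited, stack_ = [], set(), [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack_.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad or a._prev:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._prev:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # -- reductions & shape ops ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def var(self, axis=None, keepdims=False):
        """Population variance (divide by n) along ``axis``."""
        mu = self.mean(axis=axis, keepdims=True)
        out = ((self - mu) ** 2.0).mean(axis=axis, keepdims=keepdims)
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def swapaxes(self, ax1, ax2):
        a = self

        def bw(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        return self ** 0.5


def stack(tensors, axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (differentiable)."""
    tensors = list(tensors)
    datas = [t.data for t in tensors]

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad or t._prev:
                t._accumulate(np.squeeze(p, axis=axis))

    return Tensor._make(np.stack(datas, axis=axis), tuple(tensors), bw)
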
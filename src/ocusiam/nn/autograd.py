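"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.  Only the primitives needed by the
convolutional branches, the attention operators and the contrastive objective
are implemented.  Everything is float64 so finite-difference checks of the
gradients are meaningful at tight tolerances.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # make ndarray + Tensor dispatch here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones, scalars only)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def take_flat(self, indices: np.ndarray) -> "Tensor":
        """Gather from the flattened array; backward scatter-adds.

        The single primitive behind im2col convolution and patch pooling.
        """
        flat = self.data.reshape(-1)

        def bw(g):
            if self.requires_grad:
                acc = np.zeros(flat.shape, dtype=np.float64)
                np.add.at(acc, indices.reshape(-1), g.reshape(-1))
                self._accum(acc.reshape(self.shape))

        return self._make(flat[indices], (self,), bw)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the last two axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def bw(g):
            if self.requires_grad:
                sl = tuple([slice(None)] * (self.ndim - 2) + [slice(pad, -pad)] * 2)
                self._accum(g[sl])

        return self._make(np.pad(self.data, width), (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first arg-max (ties broken
        deterministically by index)."""
        idx = self.data.argmax(axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def bw(g):
            # g always arrives in the keepdims shape (squeezing is a separate
            # reshape node)
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            np.put_along_axis(acc, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(acc)

        res = self._make(out, (self,), bw)
        return res if keepdims else res.reshape(tuple(np.delete(out.shape, axis)))

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))

        return self._make(out, (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out)

        return self._make(out, (self,), bw)

    def clamp_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo (hinge convention)."""
        mask = self.data > lo

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data.reshape(()))


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = bw
    return out
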
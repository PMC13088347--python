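"""Reverse-mode automatic differentiation over dense numpy arrays.

Supports broadcasting for elementwise ops and batched matmul; gradients
are accumulated by topological-order backward passes.  Only the
primitives the package's models need are implemented.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum along axes that were broadcast from size 1
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager: skip graph construction for evaluation passes."""

    def __enter__(self) -> None:
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc) -> None:
        _GRAD_ENABLED.pop()


class Tensor:
    """A dense float64 array with an optional gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the closure cycles so the graph frees promptly
        for node in topo:
            node._backward = None
            node._prev = ()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- ops --------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad or p._prev for p in parents):
            out._prev = parents
            out.requires_grad = True
            if backward is not None:
                out._backward = lambda: backward(out)
        return out

    def __add__(self, other):
        other = self._lift(other)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad)
            other._accumulate(out.grad)

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(out: Tensor) -> None:
            self._accumulate(-out.grad)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad * other.data)
            other._accumulate(out.grad * self.data)

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad / other.data)
            other._accumulate(-out.grad * self.data / (other.data ** 2))

        return self._make(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def back(out: Tensor) -> None:
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(out: Tensor) -> None:
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self._accumulate(g * b)
                other._accumulate(g * a)
                return
            aa = a[None, :] if a.ndim == 1 else a
            bb = b[:, None] if b.ndim == 1 else b
            gg = g
            if a.ndim == 1:
                gg = np.expand_dims(gg, -2)
            if b.ndim == 1:
                gg = np.expand_dims(gg, -1)
            ga = gg @ np.swapaxes(bb, -1, -2)
            gb = np.swapaxes(aa, -1, -2) @ gg
            if a.ndim == 1:
                ga = np.squeeze(ga, -2)
            if b.ndim == 1:
                gb = np.squeeze(gb, -1)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return self._make(self.data @ other.data, (self, other), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad * out.data)

        return self._make(out_data, (self,), back)

    def log(self):
        def back(out: Tensor) -> None:
            self._accumulate(out.grad / self.data)

        return self._make(np.log(self.data), (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad * (1.0 - out.data ** 2))

        return self._make(out_data, (self,), back)

    def sigmoid(self):
        # numerically stable logistic
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, None))),
            np.exp(np.clip(self.data, None, 500))
            / (1.0 + np.exp(np.clip(self.data, None, 500))),
        )

        def back(out: Tensor) -> None:
            self._accumulate(out.grad * out.data * (1.0 - out.data))

        return self._make(out_data, (self,), back)

    def relu(self):
        def back(out: Tensor) -> None:
            self._accumulate(out.grad * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), back)

    def leaky_relu(self, negative_slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, negative_slope)

        def back(out: Tensor) -> None:
            self._accumulate(out.grad * factor)

        return self._make(self.data * factor, (self,), back)

    def sum(self, axis=None, keepdims: bool = False):
        def back(out: Tensor) -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        count = (
            self.data.size
            if axis is None
            else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def swapaxes(self, a: int, b: int):
        def back(out: Tensor) -> None:
            self._accumulate(np.swapaxes(out.grad, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), back)

    def reshape(self, *shape: int):
        old = self.data.shape

        def back(out: Tensor) -> None:
            self._accumulate(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), back)

    # -- composed helpers --------------------------------------------------

    def softmax(self, axis: int = -1):
        """Softmax along ``axis`` (max-shifted for stability; the shift is
        treated as a constant, which leaves gradients unchanged)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data) -> None:
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(out.grad[tuple(sl)])

    if _GRAD_ENABLED[-1] and any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = back
    return out
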
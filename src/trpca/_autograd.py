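"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal engine backing the transformer model: a ``Tensor`` records the
operations applied to it and ``backward()`` accumulates gradients by walking
the tape in reverse topological order. Only the primitives the model needs are
implemented (broadcast add/mul, batched matmul, reshape/transpose/concat,
reductions, exp/log/pow, GELU). float64 throughout: the acceptance contracts
are tight (1e-7..1e-10) and the models are small, so precision beats speed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "gelu", "softmax", "l2_normalize", "logsumexp", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be shared with a sibling's accumulation path
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        # iterative DFS with post-order emission = reverse topological order
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
                if id(p) not in seen:
                    stack.append((p, False))

        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # break closure reference cycles so intermediates free by refcount;
        # leaf tensors (parameters) keep their accumulated gradients
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad or self._prev:
                if b.ndim == 1:
                    ga = np.outer(g, b) if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad or other._prev:
                if a.ndim == 1:
                    gb = np.outer(a, g) if b.ndim > 1 else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


# -- composite / primitive functions --------------------------------------

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x), with Phi the standard normal CDF."""
    phi = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * phi, x.requires_grad, (x,))

    def bw(g):
        pdf = np.exp(-0.5 * x.data ** 2) * _INV_SQRT_2PI
        x._accum(g * (phi + x.data * pdf))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax primitive: dx = y * (g - sum(g * y))."""
    y = np.subtract(x.data, x.data.max(axis=axis, keepdims=True))
    np.exp(y, out=y)
    np.divide(y, y.sum(axis=axis, keepdims=True), out=y)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e.sum(axis=axis, keepdims=True).log() + shift


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Fused unit-norm primitive; zero vectors stay (near) zero.

    y = x / n with n = sqrt(sum(x^2) + eps); dx = g/n - x * sum(g*x) / n^3.
    """
    n = np.sqrt((x.data * x.data).sum(axis=axis, keepdims=True) + eps)
    y = x.data / n
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        x._accum(g / n - x.data * ((g * x.data).sum(axis=axis, keepdims=True) / n ** 3))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._prev:
                t._accum(piece)

    out._backward = bw
    return out
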
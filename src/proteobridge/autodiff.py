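"""Minimal reverse-mode automatic differentiation over numpy arrays.

The joint VAE in this package is small (a few dense layers per head), so a
compact tape-based engine is sufficient: every ``Tensor`` records its parents
and a closure that propagates the upstream gradient. Gradients are plain
``numpy.ndarray``s accumulated by summation, with broadcasting handled by
reducing the upstream gradient back to each parent's shape.

Only the primitives the model needs are provided: arithmetic with
broadcasting, matmul, exp/log/tanh/relu/sqrt, power, sum/mean reductions,
clipping and concatenation. Everything else (losses, kernels, layers) is
composed from these, so a single backward pass differentiates the whole
training objective as well as model outputs with respect to their inputs
(used by the attribution code).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


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
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- graph plumbing --------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # ---- operators -------------------------------------------------------
    def _coerce(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ),
        )
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(
            self.data**e,
            _parents=(self,),
            _backward=lambda g: ((self, g * e * self.data ** (e - 1)),),
        )
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _backward=lambda g: (
                (self, g @ other.data.T),
                (other, self.data.T @ g),
            ),
        )
        return out

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # ---- elementwise functions --------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        return Tensor(val, _parents=(self,), _backward=lambda g: ((self, g * val),))

    def log(self):
        return Tensor(
            np.log(self.data),
            _parents=(self,),
            _backward=lambda g: ((self, g / self.data),),
        )

    def tanh(self):
        val = np.tanh(self.data)
        return Tensor(val, _parents=(self,), _backward=lambda g: ((self, g * (1 - val**2)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask,
            _parents=(self,),
            _backward=lambda g: ((self, g * mask),),
        )

    def sqrt(self):
        return self**0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor(
            np.clip(self.data, lo, hi),
            _parents=(self,),
            _backward=lambda g: ((self, g * mask),),
        )

    # ---- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g2, self.shape).copy()),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        orig = self.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _backward=lambda g: ((self, g.reshape(orig)),),
        )

    @property
    def T(self):
        return Tensor(
            self.data.T,
            _parents=(self,),
            _backward=lambda g: ((self, g.T),),
        )


def as_tensor(x: Union[Tensor, ArrayLike]) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data: ArrayLike) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor(np.concatenate([t.data for t in ts], axis=axis), _parents=ts, _backward=bw)
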
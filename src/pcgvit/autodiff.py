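"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough surface for a small vision transformer: broadcast-aware
arithmetic, (batched) matmul, reshaping/slicing/concatenation, reductions,
softmax / log-softmax, ReLU and GELU.  Gradients are accumulated by a
topological sweep from the output; a ``no_grad`` context skips graph
construction entirely for cheap inference.

Every backward rule here is checked against central finite differences in
the test suite, so the engine can serve as the trusted substrate for the
model's end-to-end gradient tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _coerce(self, other) -> "Tensor":
        """Wrap an operand; python scalars adopt this tensor's dtype so a
        float32 graph is not silently promoted to float64."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float, bool, np.number)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads and closures as soon as they are
                # consumed; leaves (parameters) keep their gradients
                node.grad = None
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises ``grad`` is a freshly allocated buffer that no
        # other node will mutate, so it can be stored without a copy
        if self.grad is None:
            self.grad = grad if own and grad.flags.writeable else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                r = _unbroadcast(g, self.data.shape)
                self._accum(r, own=r is not g)
            if other.requires_grad:
                r = _unbroadcast(g, other.data.shape)
                other._accum(r, own=r is not g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g, own=True)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0), own=True)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(in_shape))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        in_shape = self.data.shape

        basic = not isinstance(idx, np.ndarray) and not (
            isinstance(idx, tuple) and any(isinstance(i, (np.ndarray, list)) for i in idx))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros(in_shape, dtype=g.dtype)
                if basic:  # slices never alias, so direct assignment suffices
                    full[idx] = g
                else:      # fancy indices may repeat: accumulate
                    np.add.at(full, idx, g)
                self._accum(full, own=True)

        return self._make(out_data, (self,), backward)

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out_data = np.broadcast_to(self.data, shape)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                r = _unbroadcast(g, self.data.shape)
                self._accum(r, own=r is not g)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, in_shape).copy(), own=True)
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, in_shape).copy(), own=True)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * mask, own=True)

        return self._make(out_data, (self,), backward)

    def gelu(self) -> "Tensor":
        """Exact GELU: x/2 · (1 + erf(x/√2))."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out_data = x * phi

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                d = phi + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)
                self._accum(g * d, own=True)

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * out_data, own=True)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                gs = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - gs), own=True)

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True), own=True)

        return self._make(out_data, (self,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    ts = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        out._backward = backward
    return out


def linear(x, W, b) -> Tensor:
    """Fused affine map x@W + b (one graph node instead of two)."""
    x, W, b = (Tensor.as_tensor(t) for t in (x, W, b))
    out_data = np.matmul(x.data, W.data) + b.data

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(np.matmul(g, W.data.T), own=True)
        if W.requires_grad:
            gW = np.matmul(np.swapaxes(x.data, -1, -2), g)
            W._accum(_unbroadcast(gW, W.data.shape), own=True)
        if b.requires_grad:
            r = _unbroadcast(g, b.data.shape)
            b._accum(r, own=r is not g)

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in (x, W, b)):
        out.requires_grad = True
        out._parents = (x, W, b)
        out._backward = backward
    return out


def layer_norm(x, gamma, beta, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis (fused primitive).

    Backward follows the standard closed form
    dx = σ⁻¹·(ĝ − mean(ĝ) − x̂·mean(ĝ·x̂)) with ĝ = g·γ, keeping only x̂
    and σ⁻¹ alive instead of the chain of elementwise intermediates.
    """
    x, gamma, beta = (Tensor.as_tensor(t) for t in (x, gamma, beta))
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv_std = (var + eps) ** -0.5
    xhat = xc * inv_std
    out_data = xhat * gamma.data + beta.data

    def backward(g: np.ndarray) -> None:
        gx = g * gamma.data
        if x.requires_grad:
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv_std * (gx - m1 - xhat * m2), own=True)
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape), own=True)
        if beta.requires_grad:
            r = _unbroadcast(g, beta.data.shape)
            beta._accum(r, own=r is not g)

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in (x, gamma, beta)):
        out.requires_grad = True
        out._parents = (x, gamma, beta)
        out._backward = backward
    return out


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar function (test oracle)."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
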
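"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All computation is in float64.  A :class:`Tensor` wraps an ndarray and
records the operations that produced it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients into
every reachable tensor with ``requires_grad=True``.

The operation set is exactly what the model needs: elementwise arithmetic,
matmul, the standard activations, row gather / segment-sum (for batched
graph message passing), concatenation, masked reductions and dropout.
Layers (:class:`Linear`, :class:`GRUCell`, :class:`Embedding`) and the
:class:`Adam` optimizer live here too.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "dropout",
    "xavier_uniform",
    "Linear",
    "GRUCell",
    "Embedding",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / other.data)
            if other.requires_grad:
                other._accum(-out.grad * self.data / other.data**2)

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _bw
        return out

    # -- activations ----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - t * t))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        out = Tensor(s, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _bw
        return out

    def log_sigmoid(self) -> "Tensor":
        """Numerically stable log(sigmoid(x))."""
        x = self.data
        out_data = np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                            x - np.log1p(np.exp(-np.abs(x))))
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * _sigmoid(-x))

        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is zero outside the open interval."""
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                inside = (self.data > lo) & (self.data < hi)
                self._accum(out.grad * inside)

        out._backward = _bw
        return out

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _bw
        return out

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (arbitrary-shape) tensor, seeding with ones."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    out._backward = _bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """out[k] = t[idx[k]] along axis 0 (duplicate indices allowed)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def _bw():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            np.add.at(g, idx, out.grad)
            t._accum(g)

    out._backward = _bw
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = sum of rows of `t` whose segment_ids == s."""
    seg = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg, t.data)
    out = Tensor(data, t.requires_grad, (t,))

    def _bw():
        if t.requires_grad:
            t._accum(out.grad[seg])

    out._backward = _bw
    return out


def dropout(t: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or at rate 0."""
    if not training or rate <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

class Linear:
    """y = x W + b, with Xavier-initialized W (shape in x out)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(xavier_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class GRUCell:
    """Standard gated recurrent unit.

    r = sigmoid(x W_xr + h W_hr + b_r)
    u = sigmoid(x W_xu + h W_hu + b_u)
    c = tanh(x W_xc + r * (h W_hc) + b_c)
    h' = (1 - u) * c + u * h

    With all-zero parameters and zero inputs the output is zero, and every
    output coordinate is a convex combination of h and a tanh value, so
    |h'|_inf <= max(|h|_inf, 1).
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        def mk(a, b):
            return Tensor(xavier_uniform(rng, a, b), requires_grad=True)

        self.W_xr, self.W_xu, self.W_xc = (mk(input_dim, hidden_dim) for _ in range(3))
        self.W_hr, self.W_hu, self.W_hc = (mk(hidden_dim, hidden_dim) for _ in range(3))
        self.b_r = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.b_u = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.b_c = Tensor(np.zeros(hidden_dim), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        r = (x @ self.W_xr + h @ self.W_hr + self.b_r).sigmoid()
        u = (x @ self.W_xu + h @ self.W_hu + self.b_u).sigmoid()
        c = (x @ self.W_xc + r * (h @ self.W_hc) + self.b_c).tanh()
        return (1.0 - u) * c + u * h

    def parameters(self) -> list[Tensor]:
        return [self.W_xr, self.W_xu, self.W_xc,
                self.W_hr, self.W_hu, self.W_hc,
                self.b_r, self.b_u, self.b_c]


class Embedding:
    """Token embedding table whose padding row (id 0) is zero and frozen."""

    PAD_ID = 0

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        table = xavier_uniform(rng, vocab_size, dim)
        table[self.PAD_ID] = 0.0
        self.table = Tensor(table, requires_grad=True)
        # Adam multiplies gradients by this mask; keeps the pad row frozen.
        mask = np.ones((vocab_size, 1))
        mask[self.PAD_ID] = 0.0
        self.grad_mask = mask

    def __call__(self, token_ids: np.ndarray) -> Tensor:
        return gather_rows(self.table, np.asarray(token_ids).reshape(-1))

    def load_vectors(self, rows: dict[int, np.ndarray]) -> None:
        """Overwrite selected rows (user-supplied embedding dictionary hook)."""
        for idx, vec in rows.items():
            if idx == self.PAD_ID:
                continue
            self.table.data[idx] = np.asarray(vec, dtype=np.float64)

    def parameters(self) -> list[Tensor]:
        return [self.table]


class Adam:
    """Adam optimizer with optional per-parameter gradient masks."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_masks: dict[int, np.ndarray] | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.grad_masks = grad_masks or {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            mask = self.grad_masks.get(id(p))
            if mask is not None:
                g = g * mask
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
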
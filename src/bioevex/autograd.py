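"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the extraction networks need: dense linear
algebra on small vectors/matrices, LSTM-friendly nonlinearities, adaptive max
pooling, log-softmax and weighted negative log-likelihood, plus Xavier
initialisation and an Adam optimizer with decoupled L2 weight decay.

Tensors hold float64 data. A tape of parent links is built during the forward
pass; ``Tensor.backward()`` walks it in reverse topological order. Leaf
tensors created with ``requires_grad=True`` (parameters) accumulate ``grad``.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "constant",
    "concat",
    "stack",
    "add_n",
    "conv1d_rows",
    "xavier_uniform",
    "Adam",
]


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = data
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    # -- graph bookkeeping ------------------------------------------------

    def _needs_tape(self) -> bool:
        return self.requires_grad or self._parents != ()

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (deep LSTM graphs overflow Python recursion)
        path: list[tuple[Tensor, int]] = [(self, 0)]
        while path:
            node, idx = path.pop()
            if idx == 0:
                if id(node) in seen:
                    continue
                seen.add(id(node))
            if idx < len(node._parents):
                path.append((node, idx + 1))
                child = node._parents[idx]
                if id(child) not in seen and child._needs_tape():
                    path.append((child, 0))
            else:
                topo.append(node)
        del stack
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.array(g)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        out_data = self.data - other.data

        def bwd(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def __mul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def scale(self, s: float) -> "Tensor":
        out_data = self.data * s

        def bwd(g: np.ndarray) -> None:
            self._accum(g * s)

        return Tensor(out_data, (self,), bwd)

    def matmul(self, vec: "Tensor") -> "Tensor":
        """2-D self @ 1-D vec -> 1-D."""
        out_data = self.data @ vec.data

        def bwd(g: np.ndarray) -> None:
            self._accum(np.outer(g, vec.data))
            vec._accum(self.data.T @ g)

        return Tensor(out_data, (self, vec), bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return self.matmul(other)

    # -- nonlinearities ---------------------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g: np.ndarray) -> None:
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g: np.ndarray) -> None:
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, (self,), bwd)

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        mask = self.data >= 0
        out_data = np.where(mask, self.data, negative_slope * self.data)

        def bwd(g: np.ndarray) -> None:
            self._accum(g * np.where(mask, 1.0, negative_slope))

        return Tensor(out_data, (self,), bwd)

    # -- shape ops --------------------------------------------------------

    def narrow(self, start: int, end: int) -> "Tensor":
        """Contiguous slice along axis 0."""
        out_data = self.data[start:end]

        def bwd(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[start:end] += g

        return Tensor(out_data, (self,), bwd)

    def row(self, i: int) -> "Tensor":
        out_data = self.data[i]

        def bwd(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[i] += g

        return Tensor(out_data, (self,), bwd)

    def max_over_rows(self) -> "Tensor":
        """Adaptive max pooling: column-wise max of a 2-D tensor -> 1-D."""
        argmax = np.argmax(self.data, axis=0)
        out_data = self.data[argmax, np.arange(self.data.shape[1])]

        def bwd(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[argmax, np.arange(self.data.shape[1])] += g

        return Tensor(out_data, (self,), bwd)

    def log_softmax(self) -> "Tensor":
        shifted = self.data - np.max(self.data)
        out_data = shifted - math.log(np.sum(np.exp(shifted)))

        def bwd(g: np.ndarray) -> None:
            self._accum(g - np.exp(out_data) * np.sum(g))

        return Tensor(out_data, (self,), bwd)

    def pick(self, index: int) -> "Tensor":
        out_data = np.asarray(self.data[index])

        def bwd(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[index] += g

        return Tensor(out_data, (self,), bwd)

    def sum(self) -> "Tensor":
        out_data = np.asarray(self.data.sum())

        def bwd(g: np.ndarray) -> None:
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, (self,), bwd)

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        out_data = self.data * keep

        def bwd(g: np.ndarray) -> None:
            self._accum(g * keep)

        return Tensor(out_data, (self,), bwd)

    def take_rows(self, indices) -> "Tensor":
        """Gather rows of a 2-D tensor by an integer index array."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data[idx]

        def bwd(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return Tensor(out_data, (self,), bwd)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64))


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 1-D tensors along axis 0."""
    out_data = np.concatenate([t.data for t in tensors])

    def bwd(g: np.ndarray) -> None:
        off = 0
        for t in tensors:
            n = t.data.shape[0]
            t._accum(g[off : off + n])
            off += n

    return Tensor(out_data, tuple(tensors), bwd)


def stack(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (rows)."""
    out_data = np.stack([t.data for t in tensors])

    def bwd(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            t._accum(g[i])

    return Tensor(out_data, tuple(tensors), bwd)


def add_n(tensors: Sequence[Tensor]) -> Tensor:
    """Sum of same-shape tensors (used for loss aggregation)."""
    out_data = tensors[0].data.copy()
    for t in tensors[1:]:
        out_data = out_data + t.data

    def bwd(g: np.ndarray) -> None:
        for t in tensors:
            t._accum(g)

    return Tensor(out_data, tuple(tensors), bwd)


def conv1d_rows(X: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """1-D convolution over the rows of X.

    X is (n, d), W is (nc, k*d) with kernel size k = W.shape[1] // d, b is
    (nc,). Window i covers rows i..i+k-1 flattened; output is (n-k+1, nc).
    Requires n >= k (callers pad shorter inputs).
    """
    n, d = X.data.shape
    nc, kd = W.data.shape
    k = kd // d
    if n < k:
        raise ValueError(f"input of {n} rows shorter than kernel size {k}")
    win = np.lib.stride_tricks.sliding_window_view(X.data, (k, d)).reshape(n - k + 1, kd)
    out_data = win @ W.data.T + b.data

    def bwd(g: np.ndarray) -> None:
        W._accum(g.T @ win)
        b._accum(g.sum(axis=0))
        gwin = (g @ W.data).reshape(n - k + 1, k, d)
        if X.grad is None:
            X.grad = np.zeros_like(X.data)
        for j in range(k):
            X.grad[j : j + n - k + 1] += gwin[:, j, :]

    return Tensor(out_data, (X, W, b), bwd)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[i]
            v = self._v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient g to the given broadcast-input shape."""
    if g.shape == shape:
        return g
    # sum out prepended axes
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g
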
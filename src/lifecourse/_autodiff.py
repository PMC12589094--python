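"""Minimal reverse-mode tensor autodiff on numpy.

Just enough machinery for a small pre-norm transformer trained with
Adam: broadcast arithmetic, batched matmul, embedding gather, fused
layer-norm / masked-softmax / log-softmax / logsumexp, and GELU.  Arrays
keep whatever float dtype they are created with (float32 for training,
float64 for finite-difference gradient checks).

The graph is dynamic: every op records its inputs and a closure that
accumulates gradients; ``Tensor.backward`` runs a topological sweep.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _ct(a: np.ndarray) -> np.ndarray:
    """Contiguous transpose of the last two axes (fast matmul operand)."""
    return np.ascontiguousarray(np.swapaxes(a, -1, -2))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- helpers ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _acc(self, g: np.ndarray, fresh: bool = False) -> None:
        # the first accumulation adopts the buffer when the op guarantees
        # it is freshly allocated (avoids a zeros_like + add pass); an
        # identity-passed gradient must be copied or two tensors would
        # share one buffer
        if self.grad is None:
            self.grad = g if fresh else g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    # -- graph --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None, free_graph: bool = True) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` leaf.

        ``free_graph=True`` (default) severs each node's backward
        closure afterwards: the closures refer back to their output
        tensor, so an intact graph is one big reference cycle that
        plain refcounting could never reclaim between training steps.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        if free_graph:
            for node in topo:
                node._backward = None
                node._prev = ()
                if not node.requires_grad:
                    node.grad = None

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _node(self.data + other.data, self, other)
        if out._prev:
            def bw():
                if self.requires_grad or self._prev:
                    ga = _unbroadcast(out.grad, self.shape)
                    self._acc(ga, fresh=ga is not out.grad)
                if other.requires_grad or other._prev:
                    gb = _unbroadcast(out.grad, other.shape)
                    other._acc(gb, fresh=gb is not out.grad)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, self)
        if out._prev:
            out._backward = lambda: self._acc(-out.grad, fresh=True)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _node(self.data * other.data, self, other)
        if out._prev:
            def bw():
                if self.requires_grad or self._prev:
                    self._acc(_unbroadcast(out.grad * other.data, self.shape), fresh=True)
                if other.requires_grad or other._prev:
                    other._acc(_unbroadcast(out.grad * self.data, other.shape), fresh=True)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by a scalar constant only")
        return self * (1.0 / other)

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out = _node(np.matmul(self.data, other.data), self, other)
        if out._prev:
            def bw():
                if self.requires_grad or self._prev:
                    g = np.matmul(out.grad, _ct(other.data))
                    self._acc(_unbroadcast(g, self.shape), fresh=True)
                if other.requires_grad or other._prev:
                    g = np.matmul(_ct(self.data), out.grad)
                    other._acc(_unbroadcast(g, other.shape), fresh=True)
            out._backward = bw
        return out

    # -- elementwise --------------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), self)
        if out._prev:
            out._backward = lambda: self._acc(out.grad * out.data, fresh=True)
        return out

    def log(self):
        out = _node(np.log(self.data), self)
        if out._prev:
            out._backward = lambda: self._acc(out.grad / self.data, fresh=True)
        return out

    def gelu(self):
        """GELU, tanh form: 0.5 x (1 + tanh(sqrt(2/pi)(x + 0.044715 x^3)))."""
        x = self.data
        c = x.dtype.type(np.sqrt(2.0 / np.pi))
        x3 = 0.044715 * x * x * x
        u = np.tanh(c * (x + x3))
        out = _node(0.5 * x * (1.0 + u), self)
        if out._prev:
            def bw():
                sech2 = 1.0 - u * u
                inner = c * (1.0 + 3.0 * 0.044715 * x * x)
                self._acc(out.grad * (0.5 * (1.0 + u) + 0.5 * x * sech2 * inner), fresh=True)
            out._backward = bw
        return out

    # -- shape --------------------------------------------------------
    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), self)
        if out._prev:
            out._backward = lambda: self._acc(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(*axes), self)
        if out._prev:
            out._backward = lambda: self._acc(out.grad.transpose(*inv))
        return out

    # -- reductions ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), self)
        if out._prev:
            def bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._acc(np.broadcast_to(g, self.shape).copy(), fresh=True)
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    prev = tuple(p for p in parents if p.requires_grad or p._prev)
    out._prev = prev
    return out


# ---------------------------------------------------------------------
# fused ops
# ---------------------------------------------------------------------

def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]``; scatter-add on the way back."""
    idx = np.asarray(idx, dtype=np.int64)
    out = _node(table.data[idx], table)
    if out._prev:
        def bw():
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, idx, out.grad)
        out._backward = bw
    return out


def gather_rows(x: Tensor, idx0: np.ndarray, idx1: np.ndarray) -> Tensor:
    """Select rows ``x[idx0, idx1, :]`` from a (B, T, D) tensor."""
    out = _node(x.data[idx0, idx1], x)
    if out._prev:
        def bw():
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            np.add.at(x.grad, (idx0, idx1), out.grad)
        out._backward = bw
    return out


def gather_cols(x: Tensor, idx: np.ndarray) -> Tensor:
    """Per-row element pick ``x[arange(n), idx]`` from a (n, m) tensor."""
    rows = np.arange(x.data.shape[0])
    idx = np.asarray(idx, dtype=np.int64)
    out = _node(x.data[rows, idx], x)
    if out._prev:
        def bw():
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            np.add.at(x.grad, (rows, idx), out.grad)
        out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, eps: float = 1e-5) -> Tensor:
    """Last-axis layer normalization with a gain and no bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _node(xhat * gain.data, x, gain)
    if out._prev:
        def bw():
            g = out.grad
            if gain.requires_grad or gain._prev:
                gain._acc(_unbroadcast(g * xhat, gain.shape), fresh=True)
            if x.requires_grad or x._prev:
                gh = g * gain.data
                n = x.data.shape[-1]
                dx = inv * (
                    gh
                    - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
                )
                x._acc(dx.astype(x.dtype) if dx.dtype != x.dtype else dx, fresh=True)
        out._backward = bw
    return out


def masked_softmax(x: Tensor, additive_mask: np.ndarray) -> Tensor:
    """Softmax along the last axis of ``x + additive_mask`` (mask constant)."""
    z = x.data + additive_mask
    z -= z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    s = z
    out = _node(s, x)
    if out._prev:
        def bw():
            g = out.grad
            dot = (g * s).sum(axis=-1, keepdims=True)
            x._acc(s * (g - dot), fresh=True)
        out._backward = bw
    return out


def log_softmax(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable log-softmax along the last axis."""
    z = x.data if additive_mask is None else x.data + additive_mask
    m = z.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))
    out = _node(z - lse, x)
    if out._prev:
        def bw():
            g = out.grad
            sm = np.exp(out.data)
            x._acc(g - sm * g.sum(axis=-1, keepdims=True), fresh=True)
        out._backward = bw
    return out


def logsumexp(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Logsumexp along the last axis; gradient is the softmax."""
    z = x.data if additive_mask is None else x.data + additive_mask
    m = z.max(axis=-1, keepdims=True)
    lse = (m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True)))[..., 0]
    out = _node(lse, x)
    if out._prev:
        def bw():
            sm = np.exp(z - lse[..., None])
            x._acc(sm * out.grad[..., None], fresh=True)
        out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p == 0 or rng is None (eval mode)."""
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adam:
    """Adam with standard moments (beta1=0.9, beta2=0.999), no weight decay."""

    def __init__(self, params: Iterable[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
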
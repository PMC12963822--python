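"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the graph-attention model needs:
dense linear algebra, pointwise nonlinearities, row gather / segment
scatter for sparse message passing, a numerically stable per-segment
softmax, and a masked binary cross-entropy on logits. Gradients are
accumulated by topological traversal of the recorded expression graph.

Everything is float64. There is no graph reuse: build, call
``backward()`` once, discard.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "concat",
    "gather_rows",
    "scatter_sum",
    "segment_softmax",
    "mean",
    "total",
    "asum",
    "reshape",
    "power",
    "sqrt",
    "elu",
    "leaky_relu",
    "sigmoid",
    "masked_bce_with_logits",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # Leading axes that do not exist in the target shape.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the expression graph: value, gradient slot, backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience operators so model code stays readable.
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, g)
        _accum(b, -g)

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data * b.data))

    return _make(a.data / b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def gather_rows(t, index) -> Tensor:
    """``out[i] = t[index[i]]`` — row lookup with scatter-add backward."""
    t = _as_tensor(t)
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        if t.requires_grad:
            grad = np.zeros_like(t.data)
            np.add.at(grad, index, g)
            _accum(t, grad)

    return _make(t.data[index], (t,), backward)


def _canonical_order(values: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Order summands by (segment, value) so each segment's accumulation
    sequence is invariant under any relabeling of the inputs — this is
    what makes graph forward passes bitwise permutation-equivariant."""
    if values.ndim == 1:
        keys = (values,)
    else:
        keys = tuple(values[:, k] for k in reversed(range(values.shape[1])))
    return np.lexsort(keys + (index,))


def scatter_sum(t, index, n_rows: int) -> Tensor:
    """``out[k] = sum of t[i] over i with index[i] == k`` (message aggregation)."""
    t = _as_tensor(t)
    index = np.asarray(index, dtype=np.intp)
    out = np.zeros((n_rows,) + t.data.shape[1:], dtype=np.float64)
    order = _canonical_order(t.data, index)
    np.add.at(out, index[order], t.data[order])

    def backward(g):
        _accum(t, g[index])

    return _make(out, (t,), backward)


def segment_softmax(logits, segments, n_segments: int) -> Tensor:
    """Softmax of a flat logit vector within each segment.

    Used to normalize attention logits over each node's in-neighborhood.
    Stable: the per-segment maximum is subtracted before exponentiation.
    Empty segments contribute nothing.
    """
    logits = _as_tensor(logits)
    segments = np.asarray(segments, dtype=np.intp)
    z = logits.data
    if z.ndim != 1:
        raise ValueError("segment_softmax expects a flat logit vector")
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, z)
    shifted = z - seg_max[segments]
    expz = np.exp(shifted)
    denom = np.zeros(n_segments)
    order = _canonical_order(expz, segments)
    np.add.at(denom, segments[order], expz[order])
    alpha = expz / denom[segments]

    def backward(g):
        if logits.requires_grad:
            # d/dz_i = alpha_i * (g_i - sum_j alpha_j g_j) within the segment
            dot = np.zeros(n_segments)
            np.add.at(dot, segments, alpha * g)
            _accum(logits, alpha * (g - dot[segments]))

    return _make(alpha, (logits,), backward)


def mean(t, axis=None, keepdims: bool = False) -> Tensor:
    t = _as_tensor(t)
    out = t.data.mean(axis=axis, keepdims=keepdims)
    count = t.data.size if axis is None else t.data.shape[axis]

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(t, np.broadcast_to(g, t.data.shape) / count)

    return _make(out, (t,), backward)


def total(t) -> Tensor:
    """Sum of all elements (named to avoid shadowing builtins)."""
    t = _as_tensor(t)

    def backward(g):
        _accum(t, np.broadcast_to(g, t.data.shape))

    return _make(t.data.sum(), (t,), backward)


def asum(t, axis: int, keepdims: bool = False) -> Tensor:
    """Sum along one axis."""
    t = _as_tensor(t)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(t, np.broadcast_to(g, t.data.shape))

    return _make(t.data.sum(axis=axis, keepdims=keepdims), (t,), backward)


def reshape(t, shape) -> Tensor:
    t = _as_tensor(t)
    old = t.data.shape

    def backward(g):
        _accum(t, g.reshape(old))

    return _make(t.data.reshape(shape), (t,), backward)


def power(t, exponent: float) -> Tensor:
    t = _as_tensor(t)

    def backward(g):
        _accum(t, g * exponent * np.power(t.data, exponent - 1))

    return _make(np.power(t.data, exponent), (t,), backward)


def sqrt(t) -> Tensor:
    t = _as_tensor(t)
    out = np.sqrt(t.data)

    def backward(g):
        _accum(t, g * 0.5 / out)

    return _make(out, (t,), backward)


def elu(t, alpha: float = 1.0) -> Tensor:
    t = _as_tensor(t)
    neg = np.minimum(t.data, 0.0)
    out = np.where(t.data > 0, t.data, alpha * np.expm1(neg))

    def backward(g):
        _accum(t, g * np.where(t.data > 0, 1.0, alpha * np.exp(neg)))

    return _make(out, (t,), backward)


def leaky_relu(t, slope: float = 0.2) -> Tensor:
    t = _as_tensor(t)

    def backward(g):
        _accum(t, g * np.where(t.data > 0, 1.0, slope))

    return _make(np.where(t.data > 0, t.data, slope * t.data), (t,), backward)


def sigmoid(t) -> Tensor:
    t = _as_tensor(t)
    out = 1.0 / (1.0 + np.exp(-t.data))

    def backward(g):
        _accum(t, g * out * (1.0 - out))

    return _make(out, (t,), backward)


def masked_bce_with_logits(logits, targets, mask) -> Tensor:
    """Mean binary cross-entropy over masked entries, from raw logits.

    Uses the log-sum-exp form ``softplus(z) - y*z`` so large logits do not
    overflow. ``mask`` is a 0/1 weight vector; the mean is over mask weight.
    """
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    n_eff = m.sum()
    if n_eff <= 0:
        raise ValueError("mask selects no samples")
    z = logits.data
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    value = float((m * (softplus - y * z)).sum() / n_eff)

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            _accum(logits, g * m * (p - y) / n_eff)

    return _make(value, (logits,), backward)


class Adam:
    """Adam with L2 weight decay folded into the gradient (coupled form)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
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
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
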
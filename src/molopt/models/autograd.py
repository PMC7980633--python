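"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an ndarray and
remembers how to push gradients to its parents. Only the operations the
sequence models need are implemented (broadcast arithmetic, matmul, pointwise
nonlinearities, reductions, indexing/concatenation, fused softmax /
log-softmax / layer-norm / cross-entropy). Everything runs in float64.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float64


@contextmanager
def no_grad():
    """Disable graph construction (inference / decoding)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def set_default_dtype(dtype) -> None:
    """Set the float dtype of newly created tensors.

    float64 (the default) keeps closed-form identities exact; float32 roughly
    halves the cost of the matmul-bound training and decoding paths.
    """
    global _DTYPE
    _DTYPE = np.dtype(dtype)


@contextmanager
def default_dtype(dtype):
    global _DTYPE
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, bw):
        if not _GRAD_ENABLED or not any(p.requires_grad for p in parents):
            return Tensor(data)
        return Tensor(data, parents=parents, bw=bw, requires_grad=True)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)
            # free the tape as we go
            node._bw = None
            node._parents = ()

    def _accum(self, g: np.ndarray):
        # copy on first write: g may be a view into (or alias of) another
        # node's gradient buffer
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # ---- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul

    # ---- pointwise ----------------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), bw)

    # ---- shape --------------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: table (V, d), idx int array (...,) -> (..., d)."""
    out_data = table.data[idx]

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
        table._accum(full)

    return Tensor._make(out_data, (table,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum((g - dot) * s)

    return Tensor._make(s, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - logz

    def bw(g):
        x._accum(g - np.exp(out) * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out, (x,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx_hat = g * gamma.data
            term1 = gx_hat
            term2 = gx_hat.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (term1 - term2 - term3))
        _ = n  # closure keep-alive for clarity

    return Tensor._make(out_data, (x, gamma, beta), bw)


def cross_entropy_sum(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Summed token-level negative log likelihood.

    logits (N, V); targets int (N,); mask float (N,) zeroing padded positions.
    Returns a scalar Tensor equal to -sum_i mask_i * log P(target_i).
    """
    mask = np.asarray(mask, dtype=logits.data.dtype)
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    n = logits.data.shape[0]
    picked = logp[np.arange(n), targets]
    loss = -(picked * mask).sum()

    def bw(g):
        probs = np.exp(logp)
        grad = probs * mask[:, None]
        grad[np.arange(n), targets] -= mask
        logits._accum(g * grad)

    return Tensor._make(loss, (logits,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)

    def bw(g):
        x._accum(g * keep)

    return Tensor._make(x.data * keep, (x,), bw)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: registers parameters and submodules by attribute."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            for value in vars(obj).values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
                elif isinstance(value, Module):
                    collect(value)
                elif isinstance(value, (list, tuple)):
                    for item in value:
                        if isinstance(item, Module):
                            collect(item)

        collect(self)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.copy()


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
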
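"""A small reverse-mode automatic-differentiation engine over numpy arrays.

The model needs only a narrow set of operations (dense algebra, pointwise
nonlinearities, embedding gather, 1-D same-padded convolution, masked
attention pooling, segment sums), so each is a single tape node with a
hand-coded backward rule; this keeps the tape short and the per-op numpy
work vectorized across a whole minibatch.

Gradients accumulate into ``Tensor.grad`` during :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order. The engine is
validated elsewhere against closed-form derivatives and central finite
differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "matmul", "tanh", "sigmoid", "exp", "log", "sqrt",
    "absval", "clip", "sum_", "mean_", "concat", "stack", "narrow", "reshape",
    "gather_rows", "conv1d_same", "segment_sum",
    "power", "einsum_bnc_bc", "einsum_bn_bnc",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # --- graph traversal -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # --- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return _add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` along any broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))
    ad, bd = a.data, b.data

    def bw(g):
        if ad.ndim == 1 and bd.ndim == 2:      # (k,) @ (k,m) -> (m,)
            _accum(a, g @ bd.T)
            _accum(b, np.outer(ad, g))
        elif ad.ndim == 2 and bd.ndim == 1:    # (n,k) @ (k,) -> (n,)
            _accum(a, np.outer(g, bd))
            _accum(b, ad.T @ g)
        elif ad.ndim == 1 and bd.ndim == 1:    # dot -> scalar
            _accum(a, g * bd)
            _accum(b, g * ad)
        else:                                   # (n,k) @ (k,m)
            _accum(a, g @ bd.T)
            _accum(b, ad.T @ g)

    out._backward = bw
    return out


def _pointwise(a: Tensor, value: np.ndarray, dvalue: np.ndarray) -> Tensor:
    out = Tensor(value, _parents=(a,))

    def bw(g):
        _accum(a, g * dvalue)

    out._backward = bw
    return out


def tanh(a: Tensor) -> Tensor:
    v = np.tanh(a.data)
    return _pointwise(a, v, 1.0 - v * v)


def sigmoid(a: Tensor) -> Tensor:
    v = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return _pointwise(a, v, v * (1.0 - v))


def exp(a: Tensor) -> Tensor:
    v = np.exp(a.data)
    return _pointwise(a, v, v)


def log(a: Tensor) -> Tensor:
    return _pointwise(a, np.log(a.data), 1.0 / a.data)


def sqrt(a: Tensor) -> Tensor:
    v = np.sqrt(a.data)
    return _pointwise(a, v, 0.5 / np.maximum(v, 1e-30))


def absval(a: Tensor) -> Tensor:
    return _pointwise(a, np.abs(a.data), np.sign(a.data))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient is passed through only inside the range."""
    v = np.clip(a.data, lo, hi)
    inside = ((a.data > lo) & (a.data < hi)).astype(float)
    return _pointwise(a, v, inside)


def sum_(a: Tensor, axis=None) -> Tensor:
    out = Tensor(a.data.sum(axis=axis), _parents=(a,))

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            _accum(a, np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy())

    out._backward = bw
    return out


def mean_(a: Tensor, axis=None) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return sum_(a, axis=axis) * (1.0 / n)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            _accum(t, np.take(g, i, axis=axis))

    out._backward = bw
    return out


def narrow(a: Tensor, start: int, stop: int, axis: int = -1) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis if axis >= 0 else a.data.ndim + axis] = slice(start, stop)
    idx = tuple(idx)
    out = Tensor(a.data[idx], _parents=(a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    out._backward = bw
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    out._backward = bw
    return out


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """``table[idx]`` for integer index arrays; backward scatter-adds."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], _parents=(table,))

    def bw(g):
        if not table.requires_grad:
            return
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx.ravel(),
                  g.reshape(-1, table.data.shape[-1]))

    out._backward = bw
    return out


def _im2col(x: np.ndarray, s: int) -> np.ndarray:
    """(B, n, d) -> (B, n, s*d) windows with centered zero same-padding."""
    B, n, d = x.shape
    left = (s - 1) // 2
    right = s - 1 - left
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    cols = np.empty((B, n, s, d), dtype=x.dtype)
    for o in range(s):
        cols[:, :, o, :] = xp[:, o:o + n, :]
    return cols.reshape(B, n, s * d)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor, s: int) -> Tensor:
    """1-D convolution over the token axis with centered zero same-padding.

    ``x``: (B, n, d); ``weight``: (s*d, ch); ``bias``: (ch,) -> (B, n, ch).
    Every token position keeps a hidden state so attention traces align
    with token positions.
    """
    B, n, d = x.data.shape
    cols = _im2col(x.data, s)
    out_val = cols.reshape(B * n, s * d) @ weight.data + bias.data
    out = Tensor(out_val.reshape(B, n, -1), _parents=(x, weight, bias))

    def bw(g):
        ch = weight.data.shape[1]
        gf = g.reshape(B * n, ch)
        _accum(weight, cols.reshape(B * n, s * d).T @ gf)
        _accum(bias, gf.sum(axis=0))
        if x.requires_grad:
            gcols = (gf @ weight.data.T).reshape(B, n, s, d)
            left = (s - 1) // 2
            gx = np.zeros((B, n + s - 1, d))
            for o in range(s):
                gx[:, o:o + n, :] += gcols[:, :, o, :]
            _accum(x, gx[:, left:left + n, :])

    out._backward = bw
    return out


def power(a: Tensor, p: float) -> Tensor:
    v = a.data ** p
    return _pointwise(a, v, p * a.data ** (p - 1))


def einsum_bnc_bc(h: Tensor, a: Tensor) -> Tensor:
    """Per-item dot products along the channel axis: (B,n,c),(B,c) -> (B,n)."""
    out = Tensor(np.einsum("bnc,bc->bn", h.data, a.data), _parents=(h, a))
    hd, ad = h.data, a.data

    def bw(g):
        _accum(h, g[:, :, None] * ad[:, None, :])
        _accum(a, np.einsum("bn,bnc->bc", g, hd))

    out._backward = bw
    return out


def einsum_bn_bnc(w: Tensor, h: Tensor) -> Tensor:
    """Weighted sum over the token axis: (B,n),(B,n,c) -> (B,c)."""
    out = Tensor(np.einsum("bn,bnc->bc", w.data, h.data), _parents=(w, h))
    wd, hd = w.data, h.data

    def bw(g):
        _accum(w, np.einsum("bc,bnc->bn", g, hd))
        _accum(h, wd[:, :, None] * g[:, None, :])

    out._backward = bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` (B, d) into ``n_segments`` groups."""
    seg = np.asarray(segment_ids)
    val = np.zeros((n_segments, x.data.shape[1]))
    np.add.at(val, seg, x.data)
    out = Tensor(val, _parents=(x,))

    def bw(g):
        _accum(x, g[seg])

    out._backward = bw
    return out
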
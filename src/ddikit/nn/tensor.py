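"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the extractors and heads in this package:
broadcast-aware elementwise ops, (batched) matmul, gather/indexing,
axis reductions and concatenation. Single precision by default (the
engine is memory-bandwidth bound); :func:`default_dtype` switches to
float64 where verification demands it (e.g. numerical gradient checks).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

DTYPE = np.float32


@contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype used by newly created tensors."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be shared with another parent's gradient
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
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
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bw)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        ).squeeze(axis)

        def bw(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.data, a, b), parents=(self,), backward=bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


def stack_last_valid(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Gather x[i, lengths[i]-1, :] for each row i of a (B, L, F) tensor."""
    b = np.arange(x.shape[0])
    key = (b, np.asarray(lengths) - 1)
    return x[key]


# ---------------------------------------------------------------------------
# fused ops for the sequence extractors (fewer, larger kernels)


def conv1d_same(x: Tensor, W: Tensor, b: Tensor, kernel: int) -> Tensor:
    """'Same' 1D convolution over (B, L, E) with a (k*E, F) weight matrix.

    Implemented as zero-padded im2col + matmul; the backward pass scatters
    through k shifted slice additions instead of fancy indexing.
    """
    B, L, E = x.shape
    p = kernel // 2
    xp = np.zeros((B, L + 2 * p, E), dtype=x.data.dtype)
    xp[:, p : p + L, :] = x.data
    cols = np.empty((B, L, kernel * E), dtype=x.data.dtype)
    for i in range(kernel):
        cols[:, :, i * E : (i + 1) * E] = xp[:, i : i + L, :]
    out_data = cols @ W.data + b.data

    def bw(g):
        gW = np.tensordot(cols, g, axes=([0, 1], [0, 1]))
        W._accumulate(gW)
        b._accumulate(g.sum(axis=(0, 1)))
        gcols = g @ W.data.T
        gxp = np.zeros_like(xp)
        for i in range(kernel):
            gxp[:, i : i + L, :] += gcols[:, :, i * E : (i + 1) * E]
        x._accumulate(gxp[:, p : p + L, :])

    return Tensor(out_data, parents=(x, W, b), backward=bw)


def masked_max_pool2(x: Tensor, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Width-2 max pooling over axis 1 of (B, L, F); PAD positions ignored.

    Returns the pooled tensor and the downsampled mask. Fully masked
    output positions are zeroed so they stay inert in later convolutions.
    """
    B, L, F = x.shape
    xm = np.where(mask[:, :, None] > 0, x.data, -1e30)
    if L % 2 == 1:
        xm = np.concatenate([xm, np.full((B, 1, F), -1e30, dtype=xm.dtype)], axis=1)
        mask = np.concatenate([mask, np.zeros((B, 1))], axis=1)
    L2 = xm.shape[1] // 2
    xm = xm.reshape(B, L2, 2, F)
    idx = np.argmax(xm, axis=2)
    out_data = np.take_along_axis(xm, idx[:, :, None, :], axis=2).squeeze(2)
    new_mask = mask.reshape(B, L2, 2).max(axis=2)
    out_data = np.where(new_mask[:, :, None] > 0, out_data, 0.0)

    def bw(g):
        g = g * (new_mask[:, :, None] > 0)
        gx = np.zeros((B, L2, 2, F), dtype=g.dtype)
        np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = gx.reshape(B, 2 * L2, F)[:, :L, :]
        x._accumulate(gx * (mask[:, :L, None] > 0))

    return Tensor(out_data, parents=(x,), backward=bw), new_mask


def global_masked_max(x: Tensor, mask: np.ndarray) -> Tensor:
    """Max over the sequence axis of (B, L, F), ignoring PAD positions."""
    xm = np.where(mask[:, :, None] > 0, x.data, -1e30)
    idx = np.argmax(xm, axis=1)
    out_data = np.take_along_axis(xm, idx[:, None, :], axis=1).squeeze(1)

    def bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx[:, None, :], g[:, None, :], axis=1)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm over the rows of a 2D tensor.

    Returns (normalized tensor, batch mean, batch variance).
    """
    mu = x.data.mean(axis=0)
    xc = x.data - mu
    var = (xc * xc).mean(axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn * gamma.data + beta.data
    n = x.data.shape[0]

    def bw(g):
        gamma._accumulate((g * xn).sum(axis=0))
        beta._accumulate(g.sum(axis=0))
        gxn = g * gamma.data
        gx = inv * (gxn - gxn.mean(axis=0) - xn * (gxn * xn).sum(axis=0) / n)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bw), mu, var
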
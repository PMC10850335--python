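"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in this package is small enough that a define-by-run tape over
``numpy.ndarray`` is sufficient: every operation builds a :class:`Tensor`
holding the forward value, the parent tensors, and a closure that accumulates
gradients into the parents.  All arithmetic is double precision, which is what
the finite-difference gradient checks in the test suite rely on.

Only the operations the model needs are implemented: broadcast-aware
elementwise arithmetic, (batched) matrix products, the sigmoid/tanh/exp/log
family, slicing, concatenation, reshaping, 1-D cross-correlation,
non-overlapping 1-D max pooling, a leaky rectifier with an arbitrary
(constant) slope array, and a fused softmax cross-entropy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "leaky",
    "conv1d",
    "max_pool1d",
    "concatenate",
    "softmax_cross_entropy",
]


class ShapeError(ValueError):
    """Raised when operand shapes are incompatible."""


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction -----------------------------------------------------
    @classmethod
    def _make(cls, data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion would overflow on long seqs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    @property
    def T(self) -> "Tensor":
        return swapaxes(self, -1, -2)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """A leaf tensor that participates in gradient descent."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return Tensor._make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return Tensor._make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor._make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor._make(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = astensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data * out_data))

    return Tensor._make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    """Numerically stable logistic function exp(x)/(exp(x)+1)."""
    a = astensor(a)
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (a,), backward)


def leaky(a, slope) -> Tensor:
    """y = x for x >= 0 else slope*x; ``slope`` is a constant (no gradient)."""
    a = astensor(a)
    slope = np.asarray(slope, dtype=np.float64)
    factor = np.where(a.data >= 0, 1.0, slope)
    out_data = a.data * factor

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * factor)

    return Tensor._make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / reshaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % a.ndim for ax in axes)
        gg = g
        if not keepdims:
            for ax in sorted(axes):
                gg = np.expand_dims(gg, ax)
        a._accumulate(np.broadcast_to(gg, a.shape).copy())

    return Tensor._make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor._make(out_data, (a,), backward)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = astensor(a)
    out_data = np.swapaxes(a.data, ax1, ax2)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.swapaxes(g, ax1, ax2))

    return Tensor._make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return Tensor._make(out_data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, ts, backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ShapeError("matmul requires tensors with at least 2 dimensions")
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def linear(x, weight, bias=None) -> Tensor:
    """Affine map ``x @ weight.T + bias`` with weight of shape [out, in]."""
    out = matmul(x, swapaxes(astensor(weight), -1, -2))
    if bias is not None:
        out = add(out, bias)
    return out


# ---------------------------------------------------------------------------
# signal operations
# ---------------------------------------------------------------------------

def conv1d(x, weight, bias=None, padding: str = "same") -> Tensor:
    """Batched 1-D cross-correlation.

    ``x`` is [batch, in_ch, length], ``weight`` is [out_ch, in_ch, kernel].
    "same" keeps the length via symmetric zero padding (odd kernels only);
    "valid" returns length - kernel + 1 positions.
    """
    x, weight = astensor(x), astensor(weight)
    if x.ndim != 3 or weight.ndim != 3:
        raise ShapeError("conv1d expects x [B,C,L] and weight [O,C,K]")
    B, Cin, L = x.shape
    Cout, Cin_w, K = weight.shape
    if Cin != Cin_w:
        raise ShapeError(f"channel mismatch: signal has {Cin}, kernel expects {Cin_w}")
    if L < 1:
        raise ValueError("empty signal")
    if padding == "same":
        if K % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")
        pad = (K - 1) // 2
    elif padding == "valid":
        pad = 0
        if L < K:
            raise ValueError(f"signal length {L} shorter than kernel {K}")
    else:
        raise ValueError(f"unknown padding mode {padding!r}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # [B,C,Lo,K]
    out_data = np.einsum("bclk,ock->bol", windows, weight.data, optimize=True)
    Lo = out_data.shape[2]
    if bias is not None:
        bias = astensor(bias)
        out_data = out_data + bias.data[:, None]

    prev = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("bclk,bol->ock", windows, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros((B, Cin, L + 2 * pad))
            for k in range(K):
                gxp[:, :, k:k + Lo] += np.einsum("bol,oc->bcl", g, weight.data[:, :, k], optimize=True)
            x._accumulate(gxp[:, :, pad:pad + L] if pad else gxp)

    return Tensor._make(out_data, prev, backward)


def max_pool1d(x, window: int) -> Tensor:
    """Max over non-overlapping windows along the last axis.

    A trailing remainder shorter than ``window`` is dropped.
    """
    x = astensor(x)
    if window < 1:
        raise ValueError("pool window must be >= 1")
    B, C, L = x.shape
    Lo = L // window
    if Lo < 1:
        raise ValueError(f"length {L} shorter than pool window {window}")
    blocks = x.data[:, :, : Lo * window].reshape(B, C, Lo, window)
    idx = blocks.argmax(axis=3)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=3)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gblocks = np.zeros((B, C, Lo, window))
        np.put_along_axis(gblocks, idx[..., None], g[..., None], axis=3)
        gx = np.zeros((B, C, L))
        gx[:, :, : Lo * window] = gblocks.reshape(B, C, Lo * window)
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of row-wise softmax(logits).

    ``labels`` are integer class indices in [0, C). The fused form keeps the
    log-sum-exp stable and gives the textbook (softmax - onehot)/N gradient.
    """
    logits = astensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    logp = (z - zmax) - np.log(ez.sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    return Tensor._make(np.asarray(loss), (logits,), backward)
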
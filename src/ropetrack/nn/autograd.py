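"""A minimal reverse-mode autodiff engine on numpy arrays.

Deliberately small: exactly the operations the enhancement GAN and the
domain-adversarial regressor need (dense/conv layers, pooling-free
strided convs, nearest upsampling, elementwise nonlinearities,
reductions, concat/slice, gradient reversal). float32 throughout.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # ---- graph machinery ----

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE)
        else:
            self.grad = self.grad + grad

    # ---- operator sugar ----

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __pow__(self, p: float):
        return power(self, p)

    def __getitem__(self, idx):
        return slice_(self, idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    out.requires_grad = (
        any(p.requires_grad or p._parents or p._backward for p in parents)
        if requires_grad is None
        else requires_grad
    )
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---- elementwise / algebra ----


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    def backward(g):
        a._accumulate(g * p * np.power(a.data, p - 1))

    return _make(np.power(a.data, p), (a,), backward)


def reciprocal_sqrt(a: Tensor, eps: float = 1e-5) -> Tensor:
    val = 1.0 / np.sqrt(a.data + eps)

    def backward(g):
        a._accumulate(g * (-0.5) * val / (a.data + eps))

    return _make(val, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, 1.0, slope).astype(DTYPE)

    def backward(g):
        a._accumulate(g * factor)

    return _make(a.data * factor, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * inside)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


# ---- reductions / reshaping ----


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    count = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g / count, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g / count, a.data.shape).copy())

    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def slice_(a: Tensor, idx) -> Tensor:
    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def grad_reverse(a: Tensor, lam: float = 1.0) -> Tensor:
    """Identity forward; gradient multiplied by -lam on the way back."""

    def backward(g):
        a._accumulate(-lam * g)

    return _make(a.data.copy(), (a,), backward)


# ---- convolution ----


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    b, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    b, c, h, w = x_shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    x = np.zeros(x_shape, dtype=DTYPE)
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """NCHW convolution, square kernel, symmetric zero padding."""
    o, cin, kh, kw = w.data.shape
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(o, -1)
    out = np.einsum("ok,bkl->bol", wmat, cols, optimize=True).reshape(-1, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(g.shape[0], o, -1)  # (B, O, L)
        w._accumulate(
            np.einsum("bol,bkl->ok", gmat, cols, optimize=True).reshape(w.data.shape)
        )
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.einsum("ok,bol->bkl", wmat, gmat, optimize=True)
        dxp = _col2im(dcols, xp.shape, kh, kw, stride)
        x._accumulate(dxp[:, :, pad : dxp.shape[2] - pad, pad : dxp.shape[3] - pad] if pad else dxp)

    return _make(out, parents, backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        b, c, h, w = g.shape
        x._accumulate(g.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    return _make(out, (x,), backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over spatial dims (no affine)."""
    mu = mean(x, axis=(2, 3), keepdims=True)
    centered = x - mu
    var = mean(mul(centered, centered), axis=(2, 3), keepdims=True)
    return mul(centered, reciprocal_sqrt(var, eps))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy; labels are integer class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return _make(np.asarray(loss, dtype=DTYPE), (logits,), backward)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
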
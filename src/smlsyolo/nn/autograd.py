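"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains and runs its networks on CPU through this tape-based
engine.  Only the operations the architectures need are implemented:
convolution (grouped/depthwise) via im2col, batched matrix products,
normalisation statistics, element-wise arithmetic with broadcasting, and a
handful of reductions.  Gradients are accumulated in float32.

A global FLOP counter can be armed around a forward pass; multiply-heavy
primitives (conv, matmul) then record analytic floating-point-operation
counts under the 2 x multiply-accumulate convention.  Normalisation,
activations, pooling and resampling are not counted.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# FLOP accounting


class FlopCounter:
    """Context manager accumulating analytic FLOPs of multiply-heavy ops."""

    _active: "FlopCounter | None" = None

    def __init__(self) -> None:
        self.total = 0

    def __enter__(self) -> "FlopCounter":
        FlopCounter._active = self
        return self

    def __exit__(self, *exc) -> None:
        FlopCounter._active = None

    @staticmethod
    def add(flops: int) -> None:
        if FlopCounter._active is not None:
            FlopCounter._active.total += int(flops)


# ---------------------------------------------------------------------------
# Tensor


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph references as we go
                node._backward = None
                node._parents = ()

    # -- convenience ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise ops


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = np.power(a.data, p)

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * np.power(a.data, p - 1.0))

    return Tensor._make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return Tensor._make(out_data, (a,), backward)


def log(a, eps: float = 1e-12) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data + eps)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (a.data + eps))

    return Tensor._make(out_data, (a,), backward)


def sqrt(a, eps: float = 1e-12) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data + eps)

    def backward(g):
        if a.requires_grad:
            a._accum(g * 0.5 / out_data)

    return Tensor._make(out_data, (a,), backward)


def atan(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (1.0 + a.data ** 2))

    return Tensor._make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def clamp(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= (a.data > lo)
    if hi is not None:
        mask *= (a.data < hi)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor._make(out_data, (a,), backward)


# activations ---------------------------------------------------------------


def relu6(a) -> Tensor:
    """Ramp activation capped at 6."""
    return clamp(a, 0.0, 6.0)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = _stable_sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (a,), backward)


def silu(a) -> Tensor:
    a = as_tensor(a)
    s = _stable_sigmoid(a.data)
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return Tensor._make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return Tensor._make(out_data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def backward(g):
        if a.requires_grad:
            a._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (a,), backward)


# shape ops -----------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    in_shape = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(in_shape))

    return Tensor._make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return Tensor._make(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Differentiable slice along one axis."""
    a = as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

    return Tensor._make(out_data, (a,), backward)


def gather_rows(a, index: np.ndarray, few_unique: bool = False) -> Tensor:
    """Select rows of a 2-D tensor; backward scatter-adds.

    ``few_unique=True`` sums duplicates by looping over the unique indices,
    which is much faster when wide rows repeat (e.g. per-image prototypes).
    """
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    out_data = a.data[index]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            if few_unique:
                for u in np.unique(index):
                    full[u] = g[index == u].sum(axis=0)
            else:
                np.add.at(full, index, g)
            a._accum(full)

    return Tensor._make(out_data, (a,), backward)


# reductions ----------------------------------------------------------------


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return Tensor._make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# matmul --------------------------------------------------------------------


def matmul(a, b) -> Tensor:
    """Batched matrix product over the trailing two axes."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    FlopCounter.add(2 * out_data.size // out_data.shape[-1]
                    * a.data.shape[-1] * out_data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


# convolution ---------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh * kw, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = x[:, :, i:i + ho * stride:stride,
                                       j:j + wo * stride:stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, kh * kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                cols[:, :, i * kw + j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def _conv2d_depthwise(x, weight, bias, stride: int, pad: int) -> Tensor:
    """Depthwise conv via per-tap accumulation (no im2col materialisation)."""
    n, c, h, w = x.data.shape
    _, _, kh, kw = weight.data.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad \
        else x.data
    out = np.zeros((n, c, ho, wo), dtype=np.float32)
    wd = weight.data
    for i in range(kh):
        for j in range(kw):
            out += wd[:, 0, i, j].reshape(1, c, 1, 1) * \
                xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
    if bias is not None:
        out += bias.data.reshape(1, c, 1, 1)
    FlopCounter.add(2 * kh * kw * c * ho * wo * n)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gr):
        if bias is not None and bias.requires_grad:
            bias._accum(gr.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    win = xp[:, :, i:i + ho * stride:stride,
                             j:j + wo * stride:stride]
                    gw[:, 0, i, j] = (gr * win).sum(axis=(0, 2, 3))
            weight._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho * stride:stride,
                        j:j + wo * stride:stride] += \
                        wd[:, 0, i, j].reshape(1, c, 1, 1) * gr
            x._accum(gxp[:, :, pad:pad + h, pad:pad + w] if pad else gxp)

    return Tensor._make(out, parents, backward)


def _conv2d_1x1(x, weight, bias) -> Tensor:
    """Point-wise conv as a batched matrix product (no column buffer)."""
    n, cin, h, w = x.data.shape
    cout = weight.data.shape[0]
    xl = x.data.reshape(n, cin, h * w)
    w2 = weight.data.reshape(cout, cin)
    out = np.matmul(w2, xl)
    out_data = out.reshape(n, cout, h, w)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    FlopCounter.add(2 * cin * cout * h * w * n)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gr):
        gr_l = gr.reshape(n, cout, h * w)
        if bias is not None and bias.requires_grad:
            bias._accum(gr.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.matmul(gr_l, xl.swapaxes(1, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gx = np.matmul(w2.T, gr_l)
            x._accum(gx.reshape(x.data.shape))

    return Tensor._make(out_data, parents, backward)


def conv2d(x, weight, bias=None, stride: int = 1, pad: int = 0,
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), grouped/depthwise supported."""
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    n, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight expects "
            f"{cin_g * groups} (groups={groups})")
    if groups == cin and cout == cin and cin_g == 1:
        return _conv2d_depthwise(x, weight, bias, stride, pad)
    if groups == 1 and kh == kw == 1 and stride == 1 and pad == 0:
        return _conv2d_1x1(x, weight, bias)
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    g = groups
    if g == 1:
        w2 = weight.data.reshape(cout, cin * kh * kw)
        out = np.matmul(w2, cols)                      # (n, cout, l) via BLAS
        out_data = out.reshape(n, cout, ho, wo)
    else:
        cols_g = cols.reshape(n, g, cin_g * kh * kw, ho * wo)
        w_g = weight.data.reshape(g, cout // g, cin_g * kh * kw)
        out = np.einsum("gok,ngkl->ngol", w_g, cols_g, optimize=True)
        out_data = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    FlopCounter.add(2 * kh * kw * cin * cout * ho * wo * n // groups)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gr):
        gr_l = gr.reshape(n, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gr.sum(axis=(0, 2, 3)))
        if g == 1:
            if weight.requires_grad:
                gw = np.matmul(gr_l, cols.swapaxes(1, 2)).sum(axis=0)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                w2 = weight.data.reshape(cout, cin * kh * kw)
                gcols = np.matmul(w2.T, gr_l)
                x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad,
                                 ho, wo))
        else:
            gr_g = gr.reshape(n, g, cout // g, ho * wo)
            cols_g = cols.reshape(n, g, cin_g * kh * kw, ho * wo)
            w_g = weight.data.reshape(g, cout // g, cin_g * kh * kw)
            if weight.requires_grad:
                gw = np.einsum("ngol,ngkl->gok", gr_g, cols_g, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.einsum("gok,ngol->ngkl", w_g, gr_g, optimize=True)
                x._accum(_col2im(gcols.reshape(n, cin * kh * kw, ho * wo),
                                 x.data.shape, kh, kw, stride, pad, ho, wo))

    return Tensor._make(out_data, parents, backward)


# pooling / resampling ------------------------------------------------------


def maxpool2d(x, kernel: int, stride: int = 1, pad: int = 0) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho = (h + 2 * pad - kernel) // stride + 1
    wo = (w + 2 * pad - kernel) // stride + 1
    xp = np.full((n, c, h + 2 * pad, w + 2 * pad), -np.inf, dtype=np.float32)
    xp[:, :, pad:pad + h, pad:pad + w] = x.data
    best = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
    arg = np.zeros((n, c, ho, wo), dtype=np.int64)
    for i in range(kernel):
        for j in range(kernel):
            win = xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
            upd = win > best
            best = np.where(upd, win, best)
            arg = np.where(upd, i * kernel + j, arg)
    out_data = best

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    sel = (arg == i * kernel + j)
                    gxp[:, :, i:i + ho * stride:stride,
                        j:j + wo * stride:stride] += g * sel
            gx = gxp[:, :, pad:pad + h, pad:pad + w]
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


# normalisation -------------------------------------------------------------


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    during training.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    mean4 = mean.reshape(1, -1, 1, 1)
    inv = (1.0 / np.sqrt(var + eps)).reshape(1, -1, 1, 1).astype(np.float32)
    xhat = (x.data - mean4) * inv
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + \
        beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_g = gxh.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = inv * (gxh - sum_g / m - xhat * sum_gx / m)
            else:
                gx = gxh * inv
            x._accum(gx.astype(np.float32))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def group_norm(x, gamma, beta, groups: int, eps: float = 1e-5) -> Tensor:
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.data.shape
    g_ = groups
    xg = x.data.reshape(n, g_, c // g_ * h * w)
    mean = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv).reshape(n, c, h, w)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + \
        beta.data.reshape(1, -1, 1, 1)

    def backward(gr):
        if gamma.requires_grad:
            gamma._accum((gr * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(gr.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = (gr * gamma.data.reshape(1, -1, 1, 1)).reshape(
                n, g_, c // g_ * h * w)
            m = c // g_ * h * w
            xhat_g = xhat.reshape(n, g_, m)
            sum_g = gxh.sum(axis=2, keepdims=True)
            sum_gx = (gxh * xhat_g).sum(axis=2, keepdims=True)
            gx = inv * (gxh - sum_g / m - xhat_g * sum_gx / m)
            x._accum(gx.reshape(n, c, h, w).astype(np.float32))

    return Tensor._make(out_data, (x, gamma, beta), backward)


# losses --------------------------------------------------------------------


def bce_with_logits(x, target: np.ndarray) -> Tensor:
    """Element-wise binary cross-entropy on logits (no reduction)."""
    x = as_tensor(x)
    t = np.asarray(target, dtype=np.float32)
    z = x.data
    out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        if x.requires_grad:
            s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                         np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
            x._accum(g * (s - t))

    return Tensor._make(out_data, (x,), backward)
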
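"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains and runs its detector on CPU through this tensor core.
It implements exactly the operations the detector needs — elementwise
arithmetic, reductions, indexing, 2-D convolution via im2col, batch
normalisation, nearest-neighbour resampling, max pooling and the loss
primitives — with float32 storage throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "maximum",
    "minimum",
    "where_const",
    "conv2d",
    "batchnorm2d",
    "maxpool2d",
    "upsample_nearest2x",
    "softmax",
    "bce_with_logits",
    "dfl_loss",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order topological sort (graphs can be deep)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def arctan(self):
        out = Tensor(np.arctan(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / (1.0 + self.data ** 2))
        return out

    def sigmoid(self):
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(self.data * s, _prev=(self,))
        out._backward = lambda g: self._accum(g * (s * (1.0 + self.data * (1.0 - s))))
        return out

    def clamp(self, lo=None, hi=None):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out


# -- n-ary and structural ops ------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def maximum(a: Tensor, b) -> Tensor:
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = Tensor(np.maximum(a.data, b.data), _prev=(a, b))
    amask = a.data >= b.data

    def bwd(g):
        a._accum(_unbroadcast(g * amask, a.data.shape))
        b._accum(_unbroadcast(g * ~amask, b.data.shape))

    out._backward = bwd
    return out


def minimum(a: Tensor, b) -> Tensor:
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = Tensor(np.minimum(a.data, b.data), _prev=(a, b))
    amask = a.data <= b.data

    def bwd(g):
        a._accum(_unbroadcast(g * amask, a.data.shape))
        b._accum(_unbroadcast(g * ~amask, b.data.shape))

    out._backward = bwd
    return out


def where_const(cond: np.ndarray, t: Tensor, other: float) -> Tensor:
    """Select from `t` where cond else the constant `other`."""
    out = Tensor(np.where(cond, t.data, other), _prev=(t,))
    out._backward = lambda g: t._accum(g * cond)
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(t,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        t._accum(s * (g - dot))

    out._backward = bwd
    return out


# -- convolution -------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel.

    Evaluated as k² shifted channel-matmuls, which keeps every copy a
    cheap strided slice (much faster on CPU than a full im2col gather).
    """
    n, c, h, w = x.data.shape
    cout, cin, k, _ = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {cin}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    l = ho * wo
    shifts: list[np.ndarray] = []   # contiguous (N, C, L) slices, row-major in (i,j)
    for i in range(k):
        for j in range(k):
            sl = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            shifts.append(np.ascontiguousarray(sl).reshape(n, c, l))
    y = np.zeros((n, cout, l), dtype=np.float32)
    for idx in range(k * k):
        i, j = divmod(idx, k)
        y += weight.data[:, :, i, j] @ shifts[idx]          # (Cout,C)@(N,C,L)
    if bias is not None:
        y += bias.data[None, :, None]
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y.reshape(n, cout, ho, wo), _prev=prev)

    def bwd(g):
        g3 = np.ascontiguousarray(g).reshape(n, cout, l)
        dw = np.empty_like(weight.data)
        need_dx = x.requires_grad or x._prev
        if need_dx:
            hp, wp = xp.shape[2], xp.shape[3]
            dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dw[:, :, i, j] = np.einsum("nol,ncl->oc", g3, shifts[idx],
                                       optimize=True)
            if need_dx:
                dsl = weight.data[:, :, i, j].T @ g3        # (N,C,L)
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    dsl.reshape(n, c, ho, wo)
        weight._accum(dw)
        if bias is not None:
            bias._accum(g3.sum(axis=(0, 2)))
        if need_dx:
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + w]
            x._accum(dxp)

    out._backward = bwd
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (N,H,W) per channel.

    `running_mean`/`running_var` are plain arrays updated in place during
    training and consumed in eval mode.
    """
    c = x.data.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (x.data.size / c) / max(x.data.size / c - 1, 1)
        inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
        scale = (gamma.data * inv).reshape(gshape)
        shift = (beta.data - gamma.data * mu * inv).reshape(gshape)
        out = Tensor(x.data * scale + shift, _prev=(x, gamma, beta))

        mu32 = mu.astype(np.float32).reshape(gshape)
        inv4 = inv.reshape(gshape)

        def bwd(g):
            xhat = (x.data - mu32) * inv4   # recomputed; cheaper than caching
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._prev:
                m = x.data.size / c
                gx = g * gamma.data.reshape(gshape)
                s1 = gx.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accum(inv.reshape(gshape) * (gx - s1 / m - xhat * s2 / m))

        out._backward = bwd
        return out
    inv = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv).reshape(gshape)
    shift = (beta.data - gamma.data * running_mean * inv).reshape(gshape)
    out = Tensor(x.data * scale + shift, _prev=(x, gamma, beta))

    def bwd_eval(g):
        xhat = (x.data - running_mean.reshape(gshape)) * inv.reshape(gshape)
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            x._accum(g * scale)

    out._backward = bwd_eval
    return out


def maxpool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    from numpy.lib.stride_tricks import sliding_window_view

    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def bwd(g):
        hp, wp = xp.shape[2], xp.shape[3]
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ii, jj = np.unravel_index(idx, (k, k))
        ni, ci, hi, wi = np.meshgrid(np.arange(n), np.arange(c), np.arange(ho),
                                     np.arange(wo), indexing="ij")
        np.add.at(dxp, (ni, ci, hi * stride + ii, wi * stride + jj), g)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accum(dxp)

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))
    n, c, h, w = x.data.shape
    out._backward = lambda g: x._accum(
        g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
    )
    return out


# -- loss primitives ---------------------------------------------------

def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    t = _as_f32(target)
    val = np.maximum(z.data, 0) - z.data * t + np.log1p(np.exp(-np.abs(z.data)))
    out = Tensor(val, _prev=(z,))
    out._backward = lambda g: z._accum(g * (0.5 * (1.0 + np.tanh(0.5 * z.data)) - t))
    return out


def dfl_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Distribution-focal cross-entropy for box side-distance bins.

    `logits` has shape (M, B); `target` holds continuous bin positions in
    [0, B-1]. The loss interpolates the cross-entropy between the two
    neighbouring integer bins.
    """
    m, b = logits.data.shape
    t = np.clip(_as_f32(target), 0, b - 1 - 1e-3)
    tl = np.floor(t).astype(np.int64)
    tr = tl + 1
    wl = tr - t
    wr = t - tl
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    logp = z - lse[:, None]
    rows = np.arange(m)
    val = -(wl * logp[rows, tl] + wr * logp[rows, np.minimum(tr, b - 1)])
    out = Tensor(val, _prev=(logits,))

    def bwd(g):
        p = np.exp(logp)
        hot = np.zeros_like(p)
        hot[rows, tl] += wl
        hot[rows, np.minimum(tr, b - 1)] += wr
        logits._accum(g[:, None] * (p - hot))

    out._backward = bwd
    return out
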
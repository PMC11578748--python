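"""Detector building blocks.

The baseline stage block of the YOLOv8 family (``C2f``: a 1×1 expansion,
a channel split, a chain of residual bottlenecks whose intermediate
outputs are all concatenated, then a 1×1 contraction) plus the
multi-scale adaptive variants this package is built around:

* ``MultiScaleConv`` splits its input into four equal channel groups
  A–D, passes A/B/C through 1×1/3×3/5×5 convolutions, reweights each
  processed group by a softmax channel attention over its pooled channel
  means, concatenates the three reweighted groups with the untouched
  group D, and mixes channels with a final 1×1 convolution. Groups at
  three receptive fields give cheap multi-scale fusion; the attention
  lets the block emphasise whichever scale carries signal for the
  current input.
* ``MultiScaleBottleneck`` wraps ``MultiScaleConv`` behind an ordinary
  3×3 convolution with a residual connection.
* ``MultiScaleC2f`` is the ``C2f`` topology with every inner bottleneck
  replaced by ``MultiScaleBottleneck``. At equal width and depth it has
  fewer parameters than ``C2f`` because the grouped branches replace one
  dense 3×3 convolution.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import ConvBlock, MaxPool2d, Module, Tensor

__all__ = [
    "softmax_vec",
    "channel_group_split",
    "channel_attention_weights",
    "MultiScaleConv",
    "MultiScaleBottleneck",
    "Bottleneck",
    "C2f",
    "MultiScaleC2f",
    "SPPF",
]


def softmax_vec(v) -> np.ndarray:
    """Numerically stable softmax of a 1-D vector (max-shifted)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ValueError(f"softmax expects a non-empty 1-D vector, got shape {v.shape}")
    e = np.exp(v - v.max())
    return e / e.sum()


def channel_group_split(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Split a (C,H,W) feature map into four contiguous channel groups."""
    x = np.asarray(x)
    c = x.shape[0]
    if c % 4 != 0:
        raise ValueError(f"channel count {c} is not divisible by 4")
    g = c // 4
    return tuple(x[i * g:(i + 1) * g] for i in range(4))


def channel_attention_weights(group: np.ndarray) -> np.ndarray:
    """Simplex weights for one channel group: softmax over the per-channel
    spatial means (global average pooling descriptor)."""
    group = np.asarray(group)
    if group.ndim != 3:
        raise ValueError(f"expected (C,H,W) group, got shape {group.shape}")
    return softmax_vec(group.mean(axis=(1, 2)))


def _attend(t: Tensor) -> Tensor:
    """Channel attention on a (N,g,H,W) tensor: softmax over pooled means,
    broadcast multiply. Differentiable."""
    desc = t.mean(axis=(2, 3), keepdims=True)          # (N,g,1,1)
    w = nn.softmax(desc, axis=1)
    return t * w


class MultiScaleConv(Module):
    """Grouped multi-scale convolution with per-group channel attention.

    ``concat_full_input=True`` switches the final concatenation to
    [A', B', C', x] (the full input instead of the untouched D group),
    widening the 1×1 mixing convolution to 7C/4 → C.
    """

    def __init__(self, c: int, concat_full_input: bool = False):
        super().__init__()
        if c % 4 != 0:
            raise ValueError(f"channel count {c} is not divisible by 4")
        g = c // 4
        self.c = c
        self.concat_full_input = concat_full_input
        self.branch1 = ConvBlock(g, g, 1)
        self.branch3 = ConvBlock(g, g, 3)
        self.branch5 = ConvBlock(g, g, 5)
        self.mix = ConvBlock(c + 3 * g if concat_full_input else c, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.c:
            raise ValueError(f"expected {self.c} channels, got {c}")
        g = c // 4
        a = x[:, 0 * g:1 * g]
        b = x[:, 1 * g:2 * g]
        cc = x[:, 2 * g:3 * g]
        d = x[:, 3 * g:4 * g]
        a = _attend(self.branch1(a))
        b = _attend(self.branch3(b))
        cc = _attend(self.branch5(cc))
        tail = x if self.concat_full_input else d
        return self.mix(nn.concat([a, b, cc, tail], axis=1))


class MultiScaleBottleneck(Module):
    """x + MultiScaleConv(Conv3×3(x)); the residual keeps gradients flowing
    through the grouped branches."""

    def __init__(self, c: int, shortcut: bool = True):
        super().__init__()
        self.cv = ConvBlock(c, c, 3)
        self.ms = MultiScaleConv(c)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.ms(self.cv(x))
        return x + y if self.shortcut else y


class Bottleneck(Module):
    """Plain residual bottleneck: two 3×3 convolutions."""

    def __init__(self, c: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = ConvBlock(c, c, 3)
        self.cv2 = ConvBlock(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Split–transform–concat stage block.

    ``multiscale=True`` replaces every inner bottleneck with
    ``MultiScaleBottleneck`` (this is the MS stage block the package
    exists for; hidden width must then be divisible by 4).
    """

    def __init__(self, c_in: int, c_out: int, n: int = 1, shortcut: bool = False,
                 multiscale: bool = False):
        super().__init__()
        self.c = c_out // 2
        self.cv1 = ConvBlock(c_in, c_out, 1)
        self.cv2 = ConvBlock((2 + n) * self.c, c_out, 1)
        mk = (lambda: MultiScaleBottleneck(self.c, shortcut)) if multiscale \
            else (lambda: Bottleneck(self.c, shortcut))
        self.blocks = [mk() for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [y[:, :self.c], y[:, self.c:]]
        for blk in self.blocks:
            parts.append(blk(parts[-1]))
        return self.cv2(nn.concat(parts, axis=1))


def MultiScaleC2f(c_in: int, c_out: int, n: int = 1, shortcut: bool = False) -> C2f:
    return C2f(c_in, c_out, n, shortcut, multiscale=True)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5×5 stride-1 max
    pools concatenated with the input."""

    def __init__(self, c_in: int, c_out: int, k: int = 5):
        super().__init__()
        c_ = c_in // 2
        self.cv1 = ConvBlock(c_in, c_, 1)
        self.cv2 = ConvBlock(c_ * 4, c_out, 1)
        self.pool = MaxPool2d(k, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))
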
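"""Bidirectional weighted feature-pyramid neck with a P2 level.

Four backbone levels P2–P5 (each half the spatial size of the level
below) enter through 1×1 lateral convolutions to a common neck width,
then one top-down sweep and one bottom-up sweep fuse them with
fast-normalised weighted sums::

    F_td(i)  = Node( w1·F_in(i) + w2·up2(F(i+1)) )
    F_out(i) = Node( w1'·F_in(i) + w2'·F_td(i) + w3'·down2(F_out(i-1)) )

where every fusion weight is a learned scalar clamped at zero and the
weighted sum is normalised by the weight total plus a small ``eps``
(so coefficients are nonnegative and sum to slightly under one). Each
fusion node's post-convolution is a shallow C2f stage block; the P4
intermediate node optionally uses the multi-scale variant. P2
participates in fusion only — detection heads read the fused P3/P4/P5.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import C2f
from .nn import ConvBlock, Module, Tensor

__all__ = ["resample", "NormalizedFusion", "Downsample", "BiFPN"]

LEVELS = ("p2", "p3", "p4", "p5")


def resample(x, factor: str, down_conv: "Downsample | None" = None):
    """Resample a feature map by a factor of two.

    ``up2`` is nearest-neighbour upsampling (parameter-free); ``down2``
    applies the given stride-2 convolution and requires even spatial dims.
    """
    if factor == "up2":
        if isinstance(x, Tensor):
            return nn.upsample_nearest2x(x)
        return np.asarray(x).repeat(2, axis=-2).repeat(2, axis=-1)
    if factor == "down2":
        h, w = (x.shape[-2], x.shape[-1])
        if h % 2 or w % 2:
            raise ValueError(f"down2 requires even spatial dims, got {(h, w)}")
        if down_conv is None:
            raise ValueError("down2 requires a stride-2 convolution")
        return down_conv(x)
    raise ValueError(f"unknown resample factor {factor!r}")


class Downsample(Module):
    """Stride-2 3×3 convolution halving spatial dims, channels unchanged."""

    def __init__(self, c: int):
        super().__init__()
        self.conv = ConvBlock(c, c, 3, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class NormalizedFusion(Module):
    """Fast-normalised weighted fusion of ``n_inputs`` same-shape maps.

    out = Conv( Σ clamp(w_i,0)·x_i / (Σ clamp(w_i,0) + eps) ); ``conv``
    may be None for an identity post-stage (used in unit probes).
    """

    def __init__(self, n_inputs: int, conv: Module | None, eps: float = 1e-4):
        super().__init__()
        if n_inputs < 1:
            raise ValueError("fusion needs at least one input")
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.raw_weights = Tensor(np.ones(n_inputs), requires_grad=True)
        self.eps = eps
        self.conv = conv

    def coefficients(self) -> np.ndarray:
        w = np.clip(self.raw_weights.data, 0, None)
        return w / (w.sum() + self.eps)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        if len(inputs) != self.raw_weights.data.size:
            raise ValueError(
                f"expected {self.raw_weights.data.size} inputs, got {len(inputs)}"
            )
        shape0 = inputs[0].shape
        for t in inputs[1:]:
            if t.shape != shape0:
                raise ValueError(f"fusion input shape mismatch: {t.shape} vs {shape0}")
        w = self.raw_weights.clamp(0)
        denom = w.sum() + self.eps
        acc = inputs[0] * (w[(0,)] / denom)
        for i in range(1, len(inputs)):
            acc = acc + inputs[i] * (w[(i,)] / denom)
        return self.conv(acc) if self.conv is not None else acc


class BiFPN(Module):
    """One bidirectional pass over a four-level pyramid.

    Parameters
    ----------
    in_channels : channel count of each backbone level, keyed p2..p5.
    width : common neck width (stage-block hidden width must divide by 8
        when the multi-scale P4 node is enabled).
    ms_p4 : use the multi-scale stage block at the P4 intermediate node.
    """

    def __init__(self, in_channels: dict[str, int], width: int = 64,
                 ms_p4: bool = False, eps: float = 1e-4):
        super().__init__()
        missing = [l for l in LEVELS if l not in in_channels]
        if missing:
            raise ValueError(f"missing pyramid level(s): {missing}")
        self.width = width
        self.lateral = {l: ConvBlock(in_channels[l], width, 1) for l in LEVELS}

        def node(n_in: int, multiscale: bool = False) -> NormalizedFusion:
            return NormalizedFusion(
                n_in, C2f(width, width, n=1, shortcut=False, multiscale=multiscale),
                eps,
            )

        self.td4 = node(2, multiscale=ms_p4)
        self.td3 = node(2)
        self.out2 = node(2)
        self.out3 = node(3)
        self.out4 = node(3)
        self.out5 = node(2)
        self.down23 = Downsample(width)
        self.down34 = Downsample(width)
        self.down45 = Downsample(width)

    def bifpn_pass(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        """Top-down then bottom-up sweep; returns all four fused levels."""
        missing = [l for l in LEVELS if l not in feats]
        if missing:
            raise ValueError(f"missing pyramid level(s): {missing}")
        f = {l: self.lateral[l](feats[l]) for l in LEVELS}
        td4 = self.td4([f["p4"], resample(f["p5"], "up2")])
        td3 = self.td3([f["p3"], resample(td4, "up2")])
        o2 = self.out2([f["p2"], resample(td3, "up2")])
        o3 = self.out3([f["p3"], td3, resample(o2, "down2", self.down23)])
        o4 = self.out4([f["p4"], td4, resample(o3, "down2", self.down34)])
        o5 = self.out5([f["p5"], resample(o4, "down2", self.down45)])
        return {"p2": o2, "p3": o3, "p4": o4, "p5": o5}

    def forward(self, feats: dict[str, Tensor]) -> list[Tensor]:
        """Fused maps routed to the three detection heads (P3, P4, P5)."""
        fused = self.bifpn_pass(feats)
        return [fused["p3"], fused["p4"], fused["p5"]]
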
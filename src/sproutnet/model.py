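"""Detector assembly: backbone, necks, anchor-free decoupled head, the
ablation variant table, parameter counting and inference.

The baseline is a faithful nano-scale YOLOv8 replica: stem + four
stages of (stride-2 conv, C2f) with SPPF on the last, a PAN neck and a
decoupled anchor-free head whose box branch predicts a 16-bin discrete
distribution per box side. The three studied modifications swap in

* the multi-scale stage block (every C2f's inner bottleneck),
* the bidirectional weighted P2 neck,
* the MPDIoU box-regression loss (training-time only; parameter-free),

independently, reproducing the eight ablation variants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .blocks import C2f, SPPF
from .neck import BiFPN
from .nn import ConvBlock, Conv2d, Module, Tensor

__all__ = [
    "VariantConfig",
    "VARIANTS",
    "DetectorModel",
    "assemble",
    "count_parameters",
    "params_table",
    "Detection",
    "GroundTruth",
    "letterbox",
    "nms",
    "forward_detect",
    "save_checkpoint",
    "load_checkpoint",
]

REG_MAX = 16
STRIDES = (8, 16, 32)

#: Table-style ablation variants: (use_msmodule, use_bifpn_p2, box_loss)
VARIANTS: dict[str, tuple[bool, bool, str]] = {
    "model0": (False, False, "ciou"),
    "model1": (True, False, "ciou"),
    "model2": (False, True, "ciou"),
    "model3": (False, False, "mpdiou"),
    "model4": (True, True, "ciou"),
    "model5": (True, False, "mpdiou"),
    "model6": (False, True, "mpdiou"),
    "ms": (True, True, "mpdiou"),
}


@dataclass
class VariantConfig:
    """Architecture + loss switches for one detector variant.

    ``width_mult`` scales the base stage widths (64,128,256,512,1024);
    0.25 is the nano scale used throughout. ``neck_width`` is the common
    BiFPN channel width (64 at nano).
    """

    use_msmodule: bool = False
    use_bifpn_p2: bool = False
    box_loss: str = "ciou"
    num_classes: int = 2
    width_mult: float = 0.25
    depth_mult: float = 0.34
    neck_width: int = 64
    msconv_concat_full_input: bool = False

    def __post_init__(self):
        if self.box_loss not in ("ciou", "mpdiou"):
            raise ValueError(f"unknown box loss {self.box_loss!r}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @classmethod
    def named(cls, name: str, **kw) -> "VariantConfig":
        ms, bifpn, loss = VARIANTS[name]
        return cls(use_msmodule=ms, use_bifpn_p2=bifpn, box_loss=loss, **kw)

    @classmethod
    def tiny(cls, name: str = "ms", **kw) -> "VariantConfig":
        """Reduced-width profile for CPU-scale training experiments."""
        kw.setdefault("width_mult", 0.125)
        kw.setdefault("neck_width", 32)
        return cls.named(name, **kw)

    def widths(self) -> list[int]:
        base = (64, 128, 256, 512, 1024)
        return [max(8, int(round(c * self.width_mult))) for c in base]

    def repeats(self) -> list[int]:
        base = (3, 6, 6, 3)
        return [max(1, round(n * self.depth_mult)) for n in base]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class Backbone(Module):
    """Stem + four (downsample conv, stage block) pairs + SPPF; exposes the
    four pyramid levels p2..p5 (strides 4/8/16/32)."""

    def __init__(self, cfg: VariantConfig):
        super().__init__()
        w1, w2, w3, w4, w5 = cfg.widths()
        n1, n2, n3, n4 = cfg.repeats()
        ms = cfg.use_msmodule
        self.stem = ConvBlock(3, w1, 3, 2)
        self.down1 = ConvBlock(w1, w2, 3, 2)
        self.stage1 = C2f(w2, w2, n1, shortcut=True, multiscale=ms)
        self.down2 = ConvBlock(w2, w3, 3, 2)
        self.stage2 = C2f(w3, w3, n2, shortcut=True, multiscale=ms)
        self.down3 = ConvBlock(w3, w4, 3, 2)
        self.stage3 = C2f(w4, w4, n3, shortcut=True, multiscale=ms)
        self.down4 = ConvBlock(w4, w5, 3, 2)
        self.stage4 = C2f(w5, w5, n4, shortcut=True, multiscale=ms)
        self.sppf = SPPF(w5, w5)
        self.out_channels = {"p2": w2, "p3": w3, "p4": w4, "p5": w5}

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        p2 = self.stage1(self.down1(self.stem(x)))
        p3 = self.stage2(self.down2(p2))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        return {"p2": p2, "p3": p3, "p4": p4, "p5": p5}


class PANNeck(Module):
    """Baseline path-aggregation neck over p3/p4/p5."""

    def __init__(self, cfg: VariantConfig):
        super().__init__()
        _, _, w3, w4, w5 = cfg.widths()
        ms = cfg.use_msmodule
        self.c2f_td4 = C2f(w5 + w4, w4, 1, multiscale=ms)
        self.c2f_td3 = C2f(w4 + w3, w3, 1, multiscale=ms)
        self.down3 = ConvBlock(w3, w3, 3, 2)
        self.c2f_bu4 = C2f(w3 + w4, w4, 1, multiscale=ms)
        self.down4 = ConvBlock(w4, w4, 3, 2)
        self.c2f_bu5 = C2f(w4 + w5, w5, 1, multiscale=ms)
        self.out_channels = [w3, w4, w5]

    def forward(self, feats: dict[str, Tensor]) -> list[Tensor]:
        p3, p4, p5 = feats["p3"], feats["p4"], feats["p5"]
        td4 = self.c2f_td4(nn.concat([nn.upsample_nearest2x(p5), p4], axis=1))
        td3 = self.c2f_td3(nn.concat([nn.upsample_nearest2x(td4), p3], axis=1))
        bu4 = self.c2f_bu4(nn.concat([self.down3(td3), td4], axis=1))
        bu5 = self.c2f_bu5(nn.concat([self.down4(bu4), p5], axis=1))
        return [td3, bu4, bu5]


class DetectHead(Module):
    """Decoupled anchor-free head: per level a box branch emitting
    ``4 * REG_MAX`` side-distance bin logits and a class branch emitting
    ``num_classes`` logits."""

    def __init__(self, in_channels: list[int], num_classes: int):
        super().__init__()
        c2 = max(16, in_channels[0] // 4, REG_MAX * 4)
        c3 = max(in_channels[0], min(num_classes, 100))
        self.num_classes = num_classes
        self.box_branches = []
        self.cls_branches = []
        for c_in, stride in zip(in_channels, STRIDES):
            box = [ConvBlock(c_in, c2, 3), ConvBlock(c2, c2, 3),
                   Conv2d(c2, 4 * REG_MAX, 1, bias=True)]
            cls = [ConvBlock(c_in, c3, 3), ConvBlock(c3, c3, 3),
                   Conv2d(c3, num_classes, 1, bias=True)]
            # bias priors: near-one box distances, rare-object class prior
            box[-1].bias.data[:] = 1.0
            cls[-1].bias.data[:] = float(
                np.log(5.0 / num_classes / (640.0 / stride) ** 2)
            )
            self.box_branches.append(box)
            self.cls_branches.append(cls)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        outs = []
        for f, box, cls in zip(feats, self.box_branches, self.cls_branches):
            b = f
            for m in box:
                b = m(b)
            c = f
            for m in cls:
                c = m(c)
            outs.append(nn.concat([b, c], axis=1))
        return outs


class DetectorModel(Module):
    """Backbone + neck + head. ``forward`` returns raw per-level outputs of
    shape (N, 4*REG_MAX + nc, H_l, W_l) at strides 8/16/32."""

    def __init__(self, cfg: VariantConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        if cfg.use_bifpn_p2:
            self.neck = BiFPN(self.backbone.out_channels, cfg.neck_width,
                              ms_p4=cfg.use_msmodule)
            head_ch = [cfg.neck_width] * 3
        else:
            self.neck = PANNeck(cfg)
            head_ch = self.neck.out_channels
        self.head = DetectHead(head_ch, cfg.num_classes)

    def forward(self, x: Tensor) -> list[Tensor]:
        return self.head(self.neck(self.backbone(x)))


def assemble(cfg: VariantConfig, seed: int | None = None) -> DetectorModel:
    """Build a variant; ``seed`` fixes weight initialisation."""
    if seed is not None:
        nn.seed_all(seed)
    return DetectorModel(cfg)


def count_parameters(model: Module) -> int:
    """Exact count of learnable scalars."""
    return model.num_parameters()


def params_millions(model: Module) -> float:
    return round(count_parameters(model) / 1e6, 1)


def params_table(num_classes: int = 2, **kw) -> dict[str, dict]:
    """Assemble all eight ablation variants and report exact and rounded
    parameter counts."""
    table = {}
    for name in VARIANTS:
        m = assemble(VariantConfig.named(name, num_classes=num_classes, **kw), seed=0)
        n = count_parameters(m)
        table[name] = {"params": n, "params_m": round(n / 1e6, 1)}
    return table


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------

@dataclass
class Detection:
    box: np.ndarray          # xyxy, canvas pixels
    cls: int
    score: float


@dataclass
class GroundTruth:
    box: np.ndarray          # xyxy, canvas pixels
    cls: int


def letterbox(img: np.ndarray, size: int, pad_value: int = 114):
    """Aspect-preserving resize onto a ``size``×``size`` gray canvas.

    Returns (canvas uint8 HWC, scale, (pad_x, pad_y)). ``size`` must be a
    stride-32 multiple.
    """
    if size % 32 != 0:
        raise ValueError(f"input size {size} is not a multiple of 32")
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    if (nh, nw) != (h, w):
        from PIL import Image

        img = np.asarray(Image.fromarray(img.astype(np.uint8)).resize(
            (nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), pad_value, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = img
    return canvas, scale, (px, py)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores)
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ix = np.minimum(boxes[i, 2], boxes[rest, 2]) - np.maximum(boxes[i, 0], boxes[rest, 0])
        iy = np.minimum(boxes[i, 3], boxes[rest, 3]) - np.maximum(boxes[i, 1], boxes[rest, 1])
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        ious = inter / np.maximum(area_i + area_r - inter, 1e-9)
        order = rest[ious <= iou_thr]
    return keep


def anchor_points(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Grid-cell centre coordinates and per-anchor strides for a square
    input, concatenated over the three head levels."""
    pts, strs = [], []
    for s in STRIDES:
        g = size // s
        xs = (np.arange(g) + 0.5) * s
        xx, yy = np.meshgrid(xs, xs)
        pts.append(np.stack([xx.ravel(), yy.ravel()], axis=1))
        strs.append(np.full(g * g, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strs)


def decode_outputs(raw: list[np.ndarray], size: int, num_classes: int):
    """Raw head outputs → (boxes xyxy (A,4), class scores (A,nc)) on the
    canvas, batch size 1."""
    flats = []
    for lvl in raw:
        n, ch, h, w = lvl.shape
        flats.append(lvl.reshape(n, ch, h * w))
    x = np.concatenate(flats, axis=2)[0].T          # (A, 4*REG_MAX+nc)
    box_logits = x[:, :4 * REG_MAX].reshape(-1, 4, REG_MAX)
    z = box_logits - box_logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    dist = (e / e.sum(axis=-1, keepdims=True)) @ np.arange(REG_MAX, dtype=np.float64)
    pts, strs = anchor_points(size)
    lt = pts - dist[:, :2] * strs[:, None]
    rb = pts + dist[:, 2:] * strs[:, None]
    boxes = np.clip(np.concatenate([lt, rb], axis=1), 0, size)
    scores = 0.5 * (1.0 + np.tanh(0.5 * x[:, 4 * REG_MAX:]))
    return boxes, scores


def forward_detect(model: DetectorModel, image: np.ndarray,
                   conf_thr: float = 0.25, iou_thr: float = 0.45,
                   size: int | None = None) -> list[Detection]:
    """Run the detector on one RGB image: letterbox, forward pass in eval
    mode, distribution decode, class-wise greedy NMS.

    Detections are reported on the letterboxed canvas (the network input
    space); callers mapping back to the source frame can invert the
    returned geometry of :func:`letterbox`.
    """
    if size is None:
        size = 32 * max(1, int(np.ceil(max(image.shape[:2]) / 32)))
    canvas, _, _ = letterbox(image, size)
    was_training = model.training
    model.eval()
    x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    raw = [t.data for t in model(x)]
    if was_training:
        model.train()
    boxes, scores = decode_outputs(raw, size, model.cfg.num_classes)
    dets: list[Detection] = []
    for c in range(model.cfg.num_classes):
        sc = scores[:, c]
        mask = sc >= conf_thr
        if not mask.any():
            continue
        b, s = boxes[mask], sc[mask]
        for i in nms(b, s, iou_thr):
            dets.append(Detection(box=b[i].copy(), cls=c, score=float(s[i])))
    dets.sort(key=lambda d: -d.score)
    return dets


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: DetectorModel, path, extra: dict | None = None) -> None:
    """Single-file checkpoint: variant config + all weights/buffers."""
    state = model.state_arrays()
    meta = json.dumps({"config": asdict(model.cfg),
                       "hash": model.cfg.config_hash(),
                       "extra": extra or {}})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def checkpoint_meta(path) -> dict:
    with np.load(path) as z:
        return json.loads(bytes(z["__meta__"]).decode())


def load_checkpoint(path) -> DetectorModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = VariantConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["config"].items()})
        if cfg.config_hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch")
        model = assemble(cfg, seed=0)
        model.load_state_arrays({k: z[k] for k in z.files if k != "__meta__"})
    return model
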
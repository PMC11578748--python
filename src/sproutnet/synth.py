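"""Synthetic field scenes for exercising detection, evaluation and
counting without UAV footage.

The generator emulates the structure of overhead imagery of early-season
peanut fields: noise-textured brown soil, small clustered green seedling
blobs of heterogeneous size (stunted plants, uneven branching),
thin bright-green weed blades that resemble seedling leaves, and
optional translucent pale strips mimicking plastic-film glare that
partially occludes plants. Classes are 0 = Seedling, 1 = Weed with a
4:1 default imbalance. Appearance is procedural — lobed ellipses and
rotated thin rectangles — which is enough to train and verify the
pipeline; photorealism is out of scope.

Everything is driven by one integer seed: identical spec + seed yields
bit-identical pixels and labels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec",
    "YoloLabelRecord",
    "gen_field_image",
    "gen_field_video",
    "read_yolo_labels",
    "write_yolo_labels",
    "split_dataset",
    "write_dataset",
    "CLASS_NAMES",
]

CLASS_NAMES = ["Seedling", "Weed"]
SEEDLING, WEED = 0, 1


@dataclass
class SceneSpec:
    """Parameters of one synthetic field scene.

    Defaults target a 160×160 crop of a fly-over frame: 8 seedlings to 2
    weeds (the 4:1 field imbalance), seedling radii 6–13 px (small
    objects at this scale), weed blades 10–22 px long, and a 30% chance
    of a film-glare strip at 45% opacity.
    """

    size: int = 160
    n_seedlings: int = 8
    n_weeds: int = 2
    seedling_radius: tuple[float, float] = (6.0, 13.0)
    weed_length: tuple[float, float] = (10.0, 22.0)
    film_prob: float = 0.3
    film_opacity: float = 0.45
    soil_noise: float = 14.0
    max_overlap: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.n_seedlings < 0 or self.n_weeds < 0:
            raise ValueError("object counts must be nonnegative")


@dataclass
class YoloLabelRecord:
    """Normalised centre-form label row: ``class cx cy w h``, all in [0,1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")

    def to_xyxy(self, img_w: int, img_h: int) -> np.ndarray:
        return np.array([
            (self.cx - self.w / 2) * img_w, (self.cy - self.h / 2) * img_h,
            (self.cx + self.w / 2) * img_w, (self.cy + self.h / 2) * img_h,
        ])


def _soil(size_h: int, size_w: int, noise: float, rng: np.random.Generator):
    base = np.array([128.0, 96.0, 66.0])
    img = np.empty((size_h, size_w, 3), dtype=np.float64)
    rough = rng.normal(0, noise, (size_h, size_w))
    smooth = gaussian_filter(rng.normal(0, noise, (size_h, size_w)), sigma=6)
    tex = rough * 0.6 + smooth * 1.4
    for ch in range(3):
        img[..., ch] = base[ch] + tex * (0.8 + 0.2 * ch)
    return img


def _draw_seedling(img, cx, cy, radius, rng):
    """Clustered lobed green blob; returns tight xyxy bounds of drawn pixels."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    n_lobes = int(rng.integers(3, 6))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.15, 0.55) * radius
        lx, ly = cx + np.cos(ang) * off, cy + np.sin(ang) * off
        rx = radius * rng.uniform(0.35, 0.6)
        ry = radius * rng.uniform(0.35, 0.6)
        mask |= ((xx - lx) / rx) ** 2 + ((yy - ly) / ry) ** 2 <= 1.0
    mask |= ((xx - cx) / (radius * 0.35)) ** 2 + ((yy - cy) / (radius * 0.35)) ** 2 <= 1.0
    if not mask.any():
        return None
    shade = rng.uniform(0.85, 1.1)
    green = np.array([52.0, 150.0, 58.0]) * shade
    jitter = rng.normal(0, 6, (h, w))
    for ch, val in enumerate(green):
        img[..., ch][mask] = val + jitter[mask]
    ys, xs = np.nonzero(mask)
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=np.float64)


def _draw_weed(img, cx, cy, length, rng):
    """Thin rotated bright-green blade; returns tight xyxy bounds."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    ang = rng.uniform(0, np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    width = rng.uniform(1.2, 2.4)
    mask = (np.abs(u) <= length / 2) & (np.abs(v) <= width)
    # second blade crossing the first, weed tufts are rarely single-bladed
    ang2 = ang + rng.uniform(0.5, 1.2)
    ca2, sa2 = np.cos(ang2), np.sin(ang2)
    u2 = (xx - cx) * ca2 + (yy - cy) * sa2
    v2 = -(xx - cx) * sa2 + (yy - cy) * ca2
    mask |= (np.abs(u2) <= length * 0.35) & (np.abs(v2) <= width)
    if not mask.any():
        return None
    green = np.array([70.0, 170.0, 64.0]) * rng.uniform(0.9, 1.15)
    for ch, val in enumerate(green):
        img[..., ch][mask] = val + rng.normal(0, 5)
    ys, xs = np.nonzero(mask)
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=np.float64)


def _boxes_overlap_frac(a: np.ndarray, b: np.ndarray) -> float:
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    smaller = min((a[2] - a[0]) * (a[3] - a[1]), (b[2] - b[0]) * (b[3] - b[1]))
    return inter / max(smaller, 1e-9)


def _render_scene(spec: SceneSpec, rng: np.random.Generator,
                  canvas_w: int | None = None,
                  x_bounds: tuple[float, float] | None = None):
    """Draw one scene; returns (float image, list of (class, xyxy))."""
    h = spec.size
    w = canvas_w or spec.size
    img = _soil(h, w, spec.soil_noise, rng)
    placed: list[tuple[int, np.ndarray]] = []
    xlo, xhi = x_bounds if x_bounds is not None else (0.0, float(w))

    def try_place(cls: int):
        for _ in range(30):
            if cls == SEEDLING:
                radius = rng.uniform(*spec.seedling_radius)
                margin = radius + 2
            else:
                radius = rng.uniform(*spec.weed_length) / 2
                margin = radius + 2
            cx = rng.uniform(max(margin, xlo), min(w - margin, xhi))
            cy = rng.uniform(margin, h - margin)
            ext = radius * 1.4
            cand = np.array([cx - ext, cy - ext, cx + ext, cy + ext])
            if all(_boxes_overlap_frac(cand, b) <= spec.max_overlap
                   for _, b in placed):
                draw = _draw_seedling if cls == SEEDLING else _draw_weed
                arg = radius if cls == SEEDLING else radius * 2
                box = draw(img, cx, cy, arg, rng)
                if box is not None:
                    placed.append((cls, box))
                return True
        return False

    shortfall = 0
    for cls, n in ((SEEDLING, spec.n_seedlings), (WEED, spec.n_weeds)):
        for _ in range(n):
            if not try_place(cls):
                shortfall += 1

    # translucent film-glare strip partially occluding whatever it covers
    if rng.random() < spec.film_prob:
        y0 = rng.uniform(0, h * 0.8)
        band = rng.uniform(h * 0.08, h * 0.2)
        yy = np.arange(h)
        strip = (yy >= y0) & (yy <= y0 + band)
        pale = np.array([225.0, 228.0, 218.0])
        img[strip] = img[strip] * (1 - spec.film_opacity) + pale * spec.film_opacity

    return np.clip(img, 0, 255), placed, shortfall


def gen_field_image(spec: SceneSpec):
    """Generate one scene.

    Returns ``(image uint8 HxWx3, labels, shortfall)`` where ``labels``
    is one :class:`YoloLabelRecord` per successfully placed object (tight
    boxes) and ``shortfall`` counts objects skipped because no placement
    satisfied the overlap constraint.
    """
    rng = np.random.default_rng(spec.seed)
    img, placed, shortfall = _render_scene(spec, rng)
    s = float(spec.size)
    labels = [
        YoloLabelRecord(cls, ((b[0] + b[2]) / 2) / s, ((b[1] + b[3]) / 2) / s,
                        (b[2] - b[0]) / s, (b[3] - b[1]) / s)
        for cls, b in placed
    ]
    return img.astype(np.uint8), labels, shortfall


def gen_field_video(spec: SceneSpec, n_frames: int = 40,
                    sweep_speed: float = 8.0, ensure_crossing: bool = True):
    """Simulate a linear fly-over of a longer field strip.

    The camera window (``spec.size`` square) moves right across a virtual
    strip at ``sweep_speed`` px/frame. Returns ``(frames, tracks,
    expected_crossings)``:

    * ``frames`` — list of uint8 images;
    * ``tracks`` — per-frame lists of ``(object_id, class_id, xyxy box in
      frame coordinates)`` for every object visible in that frame;
    * ``expected_crossings`` — per-class count of objects whose centre
      crosses the vertical frame-centre line during the sweep.

    Because objects are static and the camera moves, an object's centre
    crosses the frame-centre line exactly once while in view, which gives
    the counter an exact ground truth.
    """
    if sweep_speed <= 0:
        raise ValueError("sweep_speed must be positive")
    rng = np.random.default_rng(spec.seed)
    strip_w = spec.size + int(np.ceil(sweep_speed * (n_frames - 1)))
    mid0 = spec.size / 2.0
    # restrict placement so every object's centre sweeps past the frame
    # centre line while in view (start right of it, end left of it)
    bounds = (mid0 + 3.0, strip_w - mid0 - 3.0) if ensure_crossing else None
    strip, placed, _ = _render_scene(spec, rng, canvas_w=strip_w,
                                     x_bounds=bounds)
    strip = strip.astype(np.uint8)
    mid = spec.size / 2.0

    frames, tracks = [], []
    crossed: dict[int, int] = {}
    prev_side: dict[int, float] = {}
    for f in range(n_frames):
        x0 = f * sweep_speed
        xi = int(round(x0))
        frame = strip[:, xi:xi + spec.size]
        if frame.shape[1] < spec.size:   # pad at strip end (defensive)
            frame = np.pad(frame, ((0, 0), (0, spec.size - frame.shape[1]), (0, 0)))
        frames.append(frame)
        vis = []
        for oid, (cls, b) in enumerate(placed):
            bx = b - np.array([xi, 0, xi, 0], dtype=np.float64)
            if bx[2] <= 0 or bx[0] >= spec.size:
                continue
            vis.append((oid, cls, bx))
            cx = (bx[0] + bx[2]) / 2
            # crossing = the established (nonzero) side of the line flips
            if cx != mid:
                side = 1.0 if cx > mid else -1.0
                if oid in prev_side and prev_side[oid] != side:
                    crossed.setdefault(oid, cls)
                prev_side[oid] = side
        tracks.append(vis)

    expected = {SEEDLING: 0, WEED: 0}
    for cls in crossed.values():
        expected[cls] += 1
    return frames, tracks, expected


# ---------------------------------------------------------------------
# label I/O and dataset layout
# ---------------------------------------------------------------------

def write_yolo_labels(records: list[YoloLabelRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.class_id} {r.cx:.6f} {r.cy:.6f} {r.w:.6f} {r.h:.6f}\n")


def read_yolo_labels(path) -> list[YoloLabelRecord]:
    """Parse one label file; malformed rows raise with their line number."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            try:
                if len(parts) != 5:
                    raise ValueError(f"expected 5 fields, got {len(parts)}")
                records.append(YoloLabelRecord(int(parts[0]), *map(float, parts[1:])))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: bad label row {line!r}: {e}") from None
    return records


def split_dataset(items: list, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Deterministic shuffled train/val/test partition.

    val and test sizes are ``round(ratio * n)``; train takes the
    remainder, so the partition is exact (no overlap, full coverage).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(items)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} items into {len(ratios)} parts")
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    n_train = n - n_val - n_test
    idx = {
        "train": order[:n_train],
        "val": order[n_train:n_train + n_val],
        "test": order[n_train + n_val:],
    }
    return tuple([items[i] for i in idx[k]] for k in ("train", "val", "test"))


def write_dataset(out_dir, n_scenes: int, seed: int = 0,
                  ratios=(0.8, 0.1, 0.1), spec: SceneSpec | None = None) -> dict:
    """Generate a full on-disk dataset in the standard layout::

        out_dir/{train,val,test}/{images,labels}/scene_XXXXX.{png,txt}
        out_dir/dataset.yaml

    Returns a summary dict (per-split sizes, per-class object totals).
    """
    from PIL import Image
    import yaml

    base = spec or SceneSpec()
    ids = list(range(n_scenes))
    splits = dict(zip(("train", "val", "test"), split_dataset(ids, ratios, seed)))
    totals = {name: 0 for name in CLASS_NAMES}
    sizes = {}
    for split, members in splits.items():
        img_dir = os.path.join(out_dir, split, "images")
        lbl_dir = os.path.join(out_dir, split, "labels")
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(lbl_dir, exist_ok=True)
        for i in members:
            sp = SceneSpec(**{**asdict(base), "seed": seed * 1_000_003 + i})
            img, labels, _ = gen_field_image(sp)
            Image.fromarray(img).save(os.path.join(img_dir, f"scene_{i:05d}.png"))
            write_yolo_labels(labels, os.path.join(lbl_dir, f"scene_{i:05d}.txt"))
            for r in labels:
                totals[CLASS_NAMES[r.class_id]] += 1
        sizes[split] = len(members)
    cfg = {"path": str(out_dir), "train": "train/images", "val": "val/images",
           "test": "test/images", "names": CLASS_NAMES}
    with open(os.path.join(out_dir, "dataset.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)
    summary = {"sizes": sizes, "object_totals": totals, "n_scenes": n_scenes}
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
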
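"""Axis-aligned box geometry and bounding-box regression losses.

Boxes are corner-form ``(x1, y1, x2, y2)`` in continuous pixel units with
the origin at the top-left, ``x1 <= x2`` and ``y1 <= y2``. All functions
accept a single box of shape ``(4,)`` or an aligned batch of shape
``(N, 4)`` and return a scalar or an ``(N,)`` vector accordingly.

Two regression losses are provided:

* ``ciou_loss`` — complete IoU: ``1 - IoU`` plus a normalised
  centre-distance term and an aspect-ratio consistency term. This is the
  stock loss of the baseline detector.
* ``mpdiou_loss`` — minimum-point-distance IoU: ``1 - IoU`` plus the
  squared distances between the two matched corner pairs (top-left and
  bottom-right), each normalised by the squared image diagonal
  ``w² + h²``. Because the two corners fully determine a box, penalising
  them directly optimises position, size and aspect ratio at once, and
  keeps the gradient informative when the boxes share an aspect ratio but
  differ in size.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["iou", "mpdiou", "mpdiou_loss", "ciou_loss", "validate_boxes"]

_EPS = 1e-9


def _atleast_2d(b) -> tuple[np.ndarray, bool]:
    arr = np.asarray(b, dtype=np.float64)
    if arr.ndim == 1:
        return arr.reshape(1, 4), True
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"expected box shape (4,) or (N,4), got {arr.shape}")
    return arr, False


def validate_boxes(b: np.ndarray, name: str = "box") -> None:
    if not np.all(np.isfinite(b)):
        raise ValueError(f"{name} has non-finite coordinates")
    bad = (b[:, 0] > b[:, 2]) | (b[:, 1] > b[:, 3])
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"invalid {name} at index {i}: requires x1 <= x2 and y1 <= y2, "
            f"got {tuple(b[i])}"
        )


def _pair(a, b) -> tuple[np.ndarray, np.ndarray, bool]:
    a2, sa = _atleast_2d(a)
    b2, sb = _atleast_2d(b)
    if a2.shape[0] != b2.shape[0]:
        raise ValueError(f"box batch mismatch: {a2.shape[0]} vs {b2.shape[0]}")
    validate_boxes(a2, "first box")
    validate_boxes(b2, "second box")
    return a2, b2, sa and sb


def _iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ix = np.minimum(a[:, 2], b[:, 2]) - np.maximum(a[:, 0], b[:, 0])
    iy = np.minimum(a[:, 3], b[:, 3]) - np.maximum(a[:, 1], b[:, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a + area_b - inter
    # 0/0 (two zero-area boxes) is defined as 0
    return np.where(union > 0, inter / np.maximum(union, _EPS), 0.0)


def iou(a, b):
    """Intersection over union; 0 for disjoint boxes and for two
    zero-area boxes."""
    a2, b2, scalar = _pair(a, b)
    out = _iou(a2, b2)
    return float(out[0]) if scalar else out


def mpdiou(pred, gt, img_size):
    """Minimum-point-distance IoU.

    ``IoU - d1²/(w²+h²) - d2²/(w²+h²)`` where ``d1`` is the distance
    between the two top-left corners and ``d2`` between the two
    bottom-right corners, and ``(w, h)`` is the image size the boxes live
    in (the network input canvas during training). Range ``[-2, 1]`` for
    boxes inside the image; equals plain IoU iff both corner pairs
    coincide.
    """
    w, h = float(img_size[0]), float(img_size[1])
    if w <= 0 or h <= 0:
        raise ValueError(f"image size must be positive, got {(w, h)}")
    p, g, scalar = _pair(pred, gt)
    d1 = (p[:, 0] - g[:, 0]) ** 2 + (p[:, 1] - g[:, 1]) ** 2
    d2 = (p[:, 2] - g[:, 2]) ** 2 + (p[:, 3] - g[:, 3]) ** 2
    out = _iou(p, g) - (d1 + d2) / (w * w + h * h)
    return float(out[0]) if scalar else out


def mpdiou_loss(pred, gt, img_size):
    """``1 - mpdiou``; zero iff the boxes coincide."""
    out = 1.0 - np.asarray(mpdiou(pred, gt, img_size))
    return float(out) if out.ndim == 0 else out


def ciou_loss(pred, gt):
    """Complete-IoU loss: ``1 - IoU + ρ²/c² + α·v``.

    ``ρ`` is the centre distance, ``c`` the diagonal of the smallest
    enclosing box, ``v = (4/π²)(arctan(w_g/h_g) - arctan(w_p/h_p))²`` the
    aspect-ratio term and ``α = v / ((1 - IoU) + v)`` (treated as a
    constant under differentiation).
    """
    p, g, scalar = _pair(pred, gt)
    i = _iou(p, g)
    pcx, pcy = (p[:, 0] + p[:, 2]) / 2, (p[:, 1] + p[:, 3]) / 2
    gcx, gcy = (g[:, 0] + g[:, 2]) / 2, (g[:, 1] + g[:, 3]) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ex = np.maximum(p[:, 2], g[:, 2]) - np.minimum(p[:, 0], g[:, 0])
    ey = np.maximum(p[:, 3], g[:, 3]) - np.minimum(p[:, 1], g[:, 1])
    c2 = ex ** 2 + ey ** 2
    pw, ph = p[:, 2] - p[:, 0], p[:, 3] - p[:, 1]
    gw, gh = g[:, 2] - g[:, 0], g[:, 3] - g[:, 1]
    v = (4.0 / math.pi ** 2) * (
        np.arctan2(gw, np.maximum(gh, _EPS)) - np.arctan2(pw, np.maximum(ph, _EPS))
    ) ** 2
    alpha = v / np.maximum((1.0 - i) + v, _EPS)
    out = 1.0 - i + np.where(c2 > 0, rho2 / np.maximum(c2, _EPS), 0.0) + alpha * v
    return float(out[0]) if scalar else out
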
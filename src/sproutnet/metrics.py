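"""Detection evaluation: precision / recall / F1, average precision,
mAP over IoU sweeps, the class confusion matrix, P-R curves and FPS.

Conventions follow the detector-evaluation mainstream: detections are
greedily matched to ground truth in descending score order at an IoU
threshold (default 0.5), one ground truth matches at most one
detection, AP integrates the monotone precision envelope over recall
(all-points interpolation), and every zero-denominator ratio is
defined as 0 so sparse scenes evaluate cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import Detection, GroundTruth

__all__ = [
    "MatchCounts",
    "TimingBreakdown",
    "precision_recall_f1",
    "match_detections",
    "average_precision",
    "pr_curve",
    "mean_ap",
    "confusion_matrix",
    "fps",
    "evaluate_detections",
    "evaluation_report",
]


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class TimingBreakdown:
    """Per-frame milliseconds for preprocessing, inference, postprocessing."""
    t_pre: float
    t_inf: float
    t_pos: float


def precision_recall_f1(c: MatchCounts) -> tuple[float, float, float]:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2tp/(2tp+fp+fn); 0 on empty
    denominators. F1 equals the harmonic mean 2PR/(P+R)."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if 2 * c.tp + c.fp + c.fn else 0.0
    return p, r, f1


def fps(t: TimingBreakdown) -> float:
    """Frames per second: 1000 / (t_pre + t_inf + t_pos) with times in ms."""
    total = t.t_pre + t.t_inf + t.t_pos
    if total <= 0:
        raise ValueError("total per-frame time must be positive")
    return 1000.0 / total


def _pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(N,4) x (M,4) -> (N,M) IoU matrix."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    union = area_a + area_b - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_thr: float = 0.5):
    """Greedy single-class matching for one image.

    Detections are taken in descending score order; each claims the
    unclaimed ground truth with the highest IoU >= ``iou_thr`` (ties by
    ground-truth index). Returns (MatchCounts, per-detection TP flags in
    score order, score order indices).
    """
    order = np.argsort([-d.score for d in dets], kind="stable")
    gt_boxes = np.array([g.box for g in gts], dtype=np.float64).reshape(-1, 4)
    det_boxes = np.array([dets[i].box for i in order], dtype=np.float64).reshape(-1, 4)
    m = _pairwise_iou(det_boxes, gt_boxes)
    claimed = np.zeros(len(gts), dtype=bool)
    flags = np.zeros(len(dets), dtype=bool)
    for i in range(len(dets)):
        if len(gts) == 0:
            break
        ious = np.where(claimed, -1.0, m[i])
        j = int(np.argmax(ious))
        if ious[j] >= iou_thr:
            claimed[j] = True
            flags[i] = True
    tp = int(flags.sum())
    return MatchCounts(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp), flags, order


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int,
                      interpolation: str = "all") -> float:
    """Area under the precision-envelope vs recall curve.

    ``interpolation='all'`` integrates the exact monotone envelope;
    ``'101'`` samples it at 101 evenly spaced recall points. ``n_gt = 0``
    yields 0 by convention.
    """
    if n_gt <= 0 or len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone non-increasing envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101":
        pts = np.linspace(0, 1, 101)
        vals = np.zeros_like(pts)
        for k, r in enumerate(pts):
            mask = recall >= r
            vals[k] = env[mask][0] if mask.any() else 0.0
        return float(vals.mean())
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * env))


def pr_curve(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int):
    """Precision/recall arrays swept over descending score thresholds."""
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / max(n_gt, 1)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    return precision, recall


def mean_ap(per_class_ap: dict) -> float:
    """Unweighted mean of per-class APs."""
    if not per_class_ap:
        raise ValueError("mean_ap needs at least one class")
    return float(np.mean(list(per_class_ap.values())))


def confusion_matrix(dets_per_image: list[list[Detection]],
                     gts_per_image: list[list[GroundTruth]],
                     num_classes: int, iou_thr: float = 0.5,
                     conf_thr: float = 0.25, normalize: bool = False) -> np.ndarray:
    """(nc+1)×(nc+1) matrix, rows = true class, cols = predicted class,
    last index = background. Matching is class-agnostic by geometry, so
    cross-class confusions land off-diagonal; unmatched ground truths go
    to the background column, unmatched detections to the background row.
    """
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=np.float64)
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = [d for d in dets if d.score >= conf_thr]
        dets = sorted(dets, key=lambda d: -d.score)
        gt_boxes = np.array([g.box for g in gts], dtype=np.float64).reshape(-1, 4)
        claimed = np.zeros(len(gts), dtype=bool)
        for d in dets:
            matched = False
            if len(gts):
                ious = _pairwise_iou(d.box.reshape(1, 4), gt_boxes)[0]
                ious[claimed] = -1.0
                j = int(np.argmax(ious))
                if ious[j] >= iou_thr:
                    claimed[j] = True
                    m[gts[j].cls, d.cls] += 1
                    matched = True
            if not matched:
                m[num_classes, d.cls] += 1
        for j, g in enumerate(gts):
            if not claimed[j]:
                m[g.cls, num_classes] += 1
    if normalize:
        rows = m.sum(axis=1, keepdims=True)
        m = np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)
    return m


def evaluate_detections(dets_per_image: list[list[Detection]],
                        gts_per_image: list[list[GroundTruth]],
                        num_classes: int, iou_thr: float = 0.5) -> dict:
    """Per-class AP at one IoU threshold plus pooled P/R/F1.

    Returns {"per_class": {c: {"ap", "p", "r", "f1", "n_gt"}}, "map": ...}.
    """
    out: dict = {"per_class": {}}
    aps = {}
    for c in range(num_classes):
        flags_all, scores_all = [], []
        tp = fp = fn = 0
        n_gt = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            dc = [d for d in dets if d.cls == c]
            gc = [g for g in gts if g.cls == c]
            n_gt += len(gc)
            counts, flags, order = match_detections(dc, gc, iou_thr)
            tp += counts.tp
            fp += counts.fp
            fn += counts.fn
            flags_all.extend(flags.tolist())
            scores_all.extend([dc[i].score for i in order])
        ap = average_precision(np.array(flags_all, dtype=bool),
                               np.array(scores_all), n_gt)
        p, r, f1 = precision_recall_f1(MatchCounts(tp, fp, fn))
        aps[c] = ap
        out["per_class"][c] = {"ap": ap, "p": p, "r": r, "f1": f1, "n_gt": n_gt}
    out["map"] = mean_ap(aps) if aps else 0.0
    return out


def evaluation_report(dets_per_image, gts_per_image, num_classes: int,
                      class_names: list[str] | None = None) -> dict:
    """Full JSON-serialisable report: per-class P/R/F1/AP50/AP50-95, mAP50,
    mAP50-95 and the confusion matrix."""
    at50 = evaluate_detections(dets_per_image, gts_per_image, num_classes, 0.5)
    sweep = np.arange(0.5, 0.96, 0.05)
    ap_sweep = {c: [] for c in range(num_classes)}
    for thr in sweep:
        res = evaluate_detections(dets_per_image, gts_per_image, num_classes,
                                  float(thr))
        for c in range(num_classes):
            ap_sweep[c].append(res["per_class"][c]["ap"])
    names = class_names or [str(c) for c in range(num_classes)]
    per_class = {}
    for c in range(num_classes):
        row = dict(at50["per_class"][c])
        row["ap50"] = row.pop("ap")
        row["ap50_95"] = float(np.mean(ap_sweep[c]))
        per_class[names[c]] = row
    cm = confusion_matrix(dets_per_image, gts_per_image, num_classes)
    return {
        "per_class": per_class,
        "map50": at50["map"],
        "map50_95": float(np.mean([np.mean(ap_sweep[c]) for c in range(num_classes)])),
        "confusion_matrix": cm.tolist(),
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
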
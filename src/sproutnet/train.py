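"""Training loop for the detector on CPU.

Loss follows the anchor-free detector convention: a task-aligned
assigner picks positive grid cells per ground-truth box, classification
uses binary cross-entropy against IoU-weighted soft targets, box
regression uses the configured IoU-family loss (CIoU for the baseline,
MPDIoU for the modified variants) and the side-distance distributions
get a distribution-focal term. Total = 7.5·box + 0.5·cls + 1.5·dfl,
the stock loss weights of the baseline family.
"""

from __future__ import annotations

import csv
import math
import os

import numpy as np

from . import nn
from .nn import Tensor
from .model import REG_MAX, DetectorModel, anchor_points, letterbox
from .synth import YoloLabelRecord

__all__ = ["task_aligned_assign", "detection_loss", "train_model",
           "recalibrate_batchnorm", "dataset_from_dir", "records_to_xyxy"]

LOSS_W = {"box": 7.5, "cls": 0.5, "dfl": 1.5}


def records_to_xyxy(labels: list[YoloLabelRecord], size: int):
    """YOLO rows → (boxes (M,4) canvas pixels, classes (M,))."""
    if not labels:
        return np.zeros((0, 4)), np.zeros(0, dtype=int)
    boxes = np.stack([r.to_xyxy(size, size) for r in labels])
    cls = np.array([r.class_id for r in labels])
    return boxes, cls


def _pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    ua = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    ub = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    return inter / np.maximum(ua + ub - inter, 1e-9)


def task_aligned_assign(pred_boxes: np.ndarray, pred_scores: np.ndarray,
                        anchors: np.ndarray, gt_boxes: np.ndarray,
                        gt_cls: np.ndarray, topk: int = 10,
                        alpha: float = 0.5, beta: float = 6.0):
    """Assign anchors to ground truths for one image.

    Candidates are anchors whose centre lies inside a gt box; each gt
    keeps its ``topk`` by the alignment metric score^alpha * IoU^beta;
    an anchor claimed by several gts goes to the one with highest IoU.

    Returns (fg_mask (A,), assigned_gt (A,), target_scores (A,)).
    """
    a = anchors.shape[0]
    fg = np.zeros(a, dtype=bool)
    assigned = np.full(a, -1, dtype=int)
    tscore = np.zeros(a)
    m = gt_boxes.shape[0]
    if m == 0:
        return fg, assigned, tscore
    inside = ((anchors[:, 0][:, None] > gt_boxes[None, :, 0]) &
              (anchors[:, 0][:, None] < gt_boxes[None, :, 2]) &
              (anchors[:, 1][:, None] > gt_boxes[None, :, 1]) &
              (anchors[:, 1][:, None] < gt_boxes[None, :, 3]))        # (A,M)
    ious = _pairwise_iou(pred_boxes, gt_boxes)                        # (A,M)
    score = pred_scores[np.arange(a)[:, None], gt_cls[None, :]]       # (A,M)
    metric = np.where(inside, np.clip(score, 1e-9, 1) ** alpha *
                      np.clip(ious, 0, 1) ** beta, -1.0)
    mask = np.zeros_like(inside)
    k = min(topk, a)
    top = np.argpartition(-metric, k - 1, axis=0)[:k]                 # (k,M)
    for j in range(m):
        sel = top[:, j]
        sel = sel[metric[sel, j] > 0]
        mask[sel, j] = True
    claimed = mask.sum(axis=1)
    multi = claimed > 1
    if multi.any():
        best = np.argmax(np.where(mask, ious, -1.0), axis=1)
        mask[multi] = False
        mask[multi, best[multi]] = True
    fg = mask.any(axis=1)
    assigned[fg] = np.argmax(mask[fg], axis=1)
    # per-gt normalised soft targets: metric / max_metric * max_iou
    for j in range(m):
        rows = np.nonzero(mask[:, j])[0]
        if rows.size:
            mmax = metric[rows, j].max()
            imax = ious[rows, j].max()
            tscore[rows] = metric[rows, j] / max(mmax, 1e-9) * imax
    return fg, assigned, tscore


def _iou_terms(p: Tensor, g: np.ndarray):
    gx = Tensor(g)
    ix = nn.minimum(p[:, 2], gx[:, 2]) - nn.maximum(p[:, 0], gx[:, 0])
    iy = nn.minimum(p[:, 3], gx[:, 3]) - nn.maximum(p[:, 1], gx[:, 1])
    inter = ix.clamp(0) * iy.clamp(0)
    area_p = (p[:, 2] - p[:, 0]) * (p[:, 3] - p[:, 1])
    area_g = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    union = area_p + Tensor(area_g) - inter
    return inter / (union + 1e-9), gx


def ciou_loss_t(p: Tensor, g: np.ndarray) -> Tensor:
    """Differentiable CIoU loss on (M,4) boxes (alpha frozen, as usual)."""
    i, gx = _iou_terms(p, g)
    pcx, pcy = (p[:, 0] + p[:, 2]) * 0.5, (p[:, 1] + p[:, 3]) * 0.5
    gcx, gcy = (g[:, 0] + g[:, 2]) * 0.5, (g[:, 1] + g[:, 3]) * 0.5
    rho2 = (pcx - Tensor(gcx)) ** 2 + (pcy - Tensor(gcy)) ** 2
    ex = nn.maximum(p[:, 2], gx[:, 2]) - nn.minimum(p[:, 0], gx[:, 0])
    ey = nn.maximum(p[:, 3], gx[:, 3]) - nn.minimum(p[:, 1], gx[:, 1])
    c2 = ex ** 2 + ey ** 2 + 1e-7
    pw, ph = p[:, 2] - p[:, 0], (p[:, 3] - p[:, 1]) + 1e-7
    gw, gh = g[:, 2] - g[:, 0], g[:, 3] - g[:, 1] + 1e-7
    v = (4.0 / math.pi ** 2) * (Tensor(np.arctan(gw / gh)) - (pw / ph).arctan()) ** 2
    alpha = v.data / np.maximum((1.0 - i.data) + v.data, 1e-9)   # frozen
    return 1.0 - i + rho2 / c2 + Tensor(alpha) * v


def mpdiou_loss_t(p: Tensor, g: np.ndarray, img_wh: tuple[float, float]) -> Tensor:
    """Differentiable MPDIoU loss on (M,4) boxes."""
    i, gx = _iou_terms(p, g)
    d1 = (p[:, 0] - gx[:, 0]) ** 2 + (p[:, 1] - gx[:, 1]) ** 2
    d2 = (p[:, 2] - gx[:, 2]) ** 2 + (p[:, 3] - gx[:, 3]) ** 2
    norm = float(img_wh[0] ** 2 + img_wh[1] ** 2)
    return 1.0 - (i - (d1 + d2) * (1.0 / norm))


def detection_loss(raw: list[Tensor], targets: list[tuple[np.ndarray, np.ndarray]],
                   size: int, num_classes: int, box_loss: str = "ciou"):
    """Assignment + composite loss for one batch.

    ``targets`` holds per-image (gt_boxes xyxy pixels, gt_cls). Returns
    (total loss Tensor, dict of float components).
    """
    n = raw[0].shape[0]
    flats = []
    for lvl in raw:
        _, ch, h, w = lvl.shape
        flats.append(lvl.reshape(n, ch, h * w))
    x = nn.concat(flats, axis=2).transpose(0, 2, 1)            # (N,A,C)
    a = x.shape[1]
    box_logits = x[:, :, :4 * REG_MAX].reshape(n, a, 4, REG_MAX)
    cls_logits = x[:, :, 4 * REG_MAX:]
    dist = (nn.softmax(box_logits, axis=-1) *
            Tensor(np.arange(REG_MAX, dtype=np.float32))).sum(axis=-1)  # (N,A,4)
    pts, strs = anchor_points(size)
    px = Tensor(pts[:, 0][None, :].astype(np.float32))
    py = Tensor(pts[:, 1][None, :].astype(np.float32))
    st = Tensor(strs[None, :].astype(np.float32))
    x1 = px - dist[:, :, 0] * st
    y1 = py - dist[:, :, 1] * st
    x2 = px + dist[:, :, 2] * st
    y2 = py + dist[:, :, 3] * st
    pred_boxes = nn.stack([x1, y1, x2, y2], axis=2)            # (N,A,4)

    pb = pred_boxes.data
    ps = 0.5 * (1.0 + np.tanh(0.5 * cls_logits.data))
    cls_target = np.zeros((n, a, num_classes), dtype=np.float32)
    fg_b, fg_a = [], []
    gt_rows, weights, dfl_targets = [], [], []
    for bi in range(n):
        gtb, gtc = targets[bi]
        fg, assigned, tsc = task_aligned_assign(pb[bi], ps[bi], pts, gtb, gtc)
        idx = np.nonzero(fg)[0]
        if idx.size == 0:
            continue
        cls_target[bi, idx, gtc[assigned[idx]]] = tsc[idx]
        fg_b.extend([bi] * idx.size)
        fg_a.extend(idx.tolist())
        gt_rows.append(gtb[assigned[idx]])
        weights.append(tsc[idx])
        lt = (pts[idx] - gtb[assigned[idx], :2]) / strs[idx, None]
        rb = (gtb[assigned[idx], 2:] - pts[idx]) / strs[idx, None]
        dfl_targets.append(np.concatenate([lt, rb], axis=1))

    score_sum = max(float(cls_target.sum()), 1.0)
    loss_cls = nn.bce_with_logits(cls_logits, cls_target).sum() * (1.0 / score_sum)

    if fg_b:
        fg_b = np.array(fg_b)
        fg_a = np.array(fg_a)
        gt_all = np.concatenate(gt_rows).astype(np.float32)
        w_all = np.concatenate(weights).astype(np.float32)
        p_fg = pred_boxes[(fg_b, fg_a)]                        # (M,4)
        if box_loss == "mpdiou":
            li = mpdiou_loss_t(p_fg, gt_all, (size, size))
        else:
            li = ciou_loss_t(p_fg, gt_all)
        loss_box = (li * Tensor(w_all)).sum() * (1.0 / score_sum)
        d_fg = box_logits[(fg_b, fg_a)].reshape(-1, REG_MAX)   # (M*4,B)
        t_fg = np.concatenate(dfl_targets).reshape(-1)
        w4 = np.repeat(w_all, 4)
        loss_dfl = (nn.dfl_loss(d_fg, t_fg) * Tensor(w4)).sum() * (1.0 / (4 * score_sum))
    else:
        loss_box = Tensor(0.0)
        loss_dfl = Tensor(0.0)

    total = LOSS_W["box"] * loss_box + LOSS_W["cls"] * loss_cls + \
        LOSS_W["dfl"] * loss_dfl
    parts = {"box": float(loss_box.data), "cls": float(loss_cls.data),
             "dfl": float(loss_dfl.data), "total": float(total.data)}
    return total, parts


def dataset_from_dir(split_dir, size: int):
    """Load an images/labels split directory into memory."""
    from PIL import Image
    from .synth import read_yolo_labels

    img_dir = os.path.join(split_dir, "images")
    lbl_dir = os.path.join(split_dir, "labels")
    items = []
    for name in sorted(os.listdir(img_dir)):
        stem = os.path.splitext(name)[0]
        img = np.asarray(Image.open(os.path.join(img_dir, name)).convert("RGB"))
        labels = read_yolo_labels(os.path.join(lbl_dir, stem + ".txt"))
        items.append((img, labels))
    return items


def recalibrate_batchnorm(model, batches: list[np.ndarray]) -> None:
    """Replace BatchNorm running statistics with exact cumulative averages
    over the given batches (train-mode forward passes, no updates).

    Short CPU runs take few optimiser steps, so the exponentially decayed
    running stats can still sit far from the activation distribution;
    evaluation quality then collapses even though train-mode behaviour is
    good. One calibration sweep fixes the mismatch.
    """
    from .nn.modules import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    model.train()
    for i, xb in enumerate(batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)   # cumulative moving average
        model(Tensor(xb))
    for bn, mom in zip(bns, saved):
        bn.momentum = mom


def train_model(model: DetectorModel, dataset, epochs: int = 30,
                batch_size: int = 8, lr0: float = 0.01, seed: int = 0,
                size: int = 160, optimizer: str = "sgd",
                weight_decay: float = 5e-4, warmup_epochs: int = 3,
                log_csv=None, start_epoch: int = 0, on_epoch=None):
    """Train on an in-memory dataset of (uint8 image, label records).

    Deterministic given ``seed``: shuffling, assignment and updates all
    run on a single thread from one generator. Per-epoch box/cls/dfl
    means are returned (and appended to ``log_csv`` when given).
    """
    if not dataset:
        raise ValueError("empty dataset")
    prepped = []
    for img, labels in dataset:
        if img.shape[0] != size or img.shape[1] != size:
            img, _, _ = letterbox(img, size)
        xs = img.astype(np.float32).transpose(2, 0, 1) / 255.0
        prepped.append((xs, records_to_xyxy(labels, size)))

    params = model.parameters()
    if optimizer == "adam":
        opt = nn.Adam(params, lr=lr0, weight_decay=weight_decay)
    else:
        opt = nn.SGD(params, lr=lr0, momentum=0.937, weight_decay=weight_decay)
    n_batches = math.ceil(len(prepped) / batch_size)
    total_steps = epochs * n_batches
    warmup = warmup_epochs * n_batches
    history = []
    model.train()
    step = 0
    for epoch in range(start_epoch, start_epoch + epochs):
        order = np.random.default_rng(seed + epoch).permutation(len(prepped))
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        for b in range(n_batches):
            idx = order[b * batch_size:(b + 1) * batch_size]
            xb = Tensor(np.stack([prepped[i][0] for i in idx]))
            tb = [prepped[i][1] for i in idx]
            opt.lr = nn.warmup_cosine_lr(step, total_steps, lr0, warmup)
            raw = model(xb)
            loss, parts = detection_loss(raw, tb, size, model.cfg.num_classes,
                                         model.cfg.box_loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in sums:
                sums[k] += parts[k]
            step += 1
        row = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        history.append(row)
        if log_csv is not None:
            new = not os.path.exists(log_csv)
            with open(log_csv, "a", newline="") as fh:
                wr = csv.DictWriter(fh, fieldnames=list(row))
                if new:
                    wr.writeheader()
                wr.writerow(row)
        if on_epoch is not None and on_epoch(epoch, row, model):
            break
    calib = [np.stack([prepped[i][0] for i in idx])
             for idx in np.array_split(np.arange(len(prepped)),
                                       max(1, n_batches))]
    recalibrate_batchnorm(model, calib)
    return history
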
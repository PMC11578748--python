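"""Reference-line counting of tracked objects in overhead video.

A pluggable tracker produces per-frame ``TrackState`` records (persistent
id, class, centre history). The counter draws a fixed reference line
across the frame and increments a per-class tally the first time a
track's centre crosses it; an id is never counted twice, so a centre
oscillating around the line (detector jitter) cannot inflate the tally.
A bundled greedy centroid tracker keeps the pipeline self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import Detection

__all__ = [
    "TrackState",
    "CountState",
    "ReferenceLine",
    "CentroidTracker",
    "update_line_counts",
    "annotate_frame",
    "count_video",
]


@dataclass
class TrackState:
    id: int
    class_id: int
    history: list[tuple[float, float]]    # centre positions, oldest first
    counted: bool = False
    missed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        return self.history[-1]


@dataclass
class CountState:
    counts: dict[int, int] = field(default_factory=dict)
    counted_ids: dict[int, int] = field(default_factory=dict)  # id -> class

    def total(self, class_id: int) -> int:
        return self.counts.get(class_id, 0)


@dataclass
class ReferenceLine:
    """Horizontal or vertical counting line at ``position`` pixels."""

    orientation: str = "horizontal"
    position: float = 0.0
    frame_size: tuple[int, int] | None = None   # (w, h) for validation

    def __post_init__(self):
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.frame_size is not None:
            w, h = self.frame_size
            limit = h if self.orientation == "horizontal" else w
            if not 0 <= self.position <= limit:
                raise ValueError(
                    f"line position {self.position} outside frame (limit {limit})"
                )

    @classmethod
    def center_of(cls, frame_w: int, frame_h: int,
                  orientation: str = "horizontal") -> "ReferenceLine":
        pos = frame_h / 2 if orientation == "horizontal" else frame_w / 2
        return cls(orientation, pos, (frame_w, frame_h))

    def signed_offset(self, center: tuple[float, float]) -> float:
        coord = center[1] if self.orientation == "horizontal" else center[0]
        return coord - self.position


class CentroidTracker:
    """Greedy nearest-centroid tracker (same-class, distance-gated).

    A deliberately simple stand-in for heavier appearance/motion trackers:
    detections match the closest live track of the same class within
    ``max_dist``; leftovers spawn new ids; unmatched tracks are dropped
    after ``patience`` missed frames.
    """

    def __init__(self, max_dist: float = 50.0, patience: int = 3):
        self.max_dist = max_dist
        self.patience = patience
        self._next_id = 0
        self.tracks: list[TrackState] = []

    def update(self, dets: list[Detection]) -> list[TrackState]:
        centers = [(float((d.box[0] + d.box[2]) / 2),
                    float((d.box[1] + d.box[3]) / 2)) for d in dets]
        pairs = []
        for ti, t in enumerate(self.tracks):
            for di, (c, d) in enumerate(zip(centers, dets)):
                if d.cls != t.class_id:
                    continue
                dist = float(np.hypot(c[0] - t.center[0], c[1] - t.center[1]))
                if dist <= self.max_dist:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            self.tracks[ti].history.append(centers[di])
            self.tracks[ti].missed = 0
        survivors = []
        for ti, t in enumerate(self.tracks):
            if ti in used_t:
                survivors.append(t)
            else:
                t.missed += 1
                if t.missed <= self.patience:
                    survivors.append(t)
        for di, d in enumerate(dets):
            if di not in used_d:
                survivors.append(TrackState(self._next_id, d.cls, [centers[di]]))
                self._next_id += 1
        self.tracks = survivors
        return [t for t in self.tracks if t.missed == 0]


def update_line_counts(tracks: list[TrackState], line: ReferenceLine,
                       state: CountState) -> CountState:
    """Count each track whose centre changed sides of the line between its
    last two history points; each id counts at most once, ever.

    A track first seen already past the line has no crossing history and
    is not counted. Returns ``state`` (updated in place).
    """
    for t in tracks:
        if t.counted or t.id in state.counted_ids or len(t.history) < 2:
            continue
        cur = line.signed_offset(t.history[-1])
        if cur == 0:
            continue   # sitting exactly on the line; decide on the next move
        # last side established before this point (zero offsets carry no side)
        prev = 0.0
        for p in reversed(t.history[:-1]):
            prev = line.signed_offset(p)
            if prev != 0:
                break
        if prev != 0 and (prev < 0) != (cur < 0):
            t.counted = True
            state.counted_ids[t.id] = t.class_id
            state.counts[t.class_id] = state.counts.get(t.class_id, 0) + 1
    return state


_CLASS_COLORS = [(60, 200, 60), (220, 80, 80), (80, 80, 220), (220, 200, 60)]


def annotate_frame(frame: np.ndarray, tracks: list[TrackState],
                   state: CountState, line: ReferenceLine,
                   boxes: dict[int, np.ndarray] | None = None) -> np.ndarray:
    """Render the reference line, track boxes/ids and running counts onto a
    copy of the frame. Pure visualisation; no state change."""
    out = np.array(frame, dtype=np.uint8, copy=True)
    h, w = out.shape[:2]
    p = int(round(line.position))
    if line.orientation == "horizontal":
        out[max(0, min(p, h - 1)), :, :] = (255, 255, 0)
    else:
        out[:, max(0, min(p, w - 1)), :] = (255, 255, 0)
    for t in tracks:
        color = _CLASS_COLORS[t.class_id % len(_CLASS_COLORS)]
        if boxes is not None and t.id in boxes:
            x1, y1, x2, y2 = [int(round(v)) for v in boxes[t.id]]
            x1, x2 = max(0, x1), min(w - 1, x2)
            y1, y2 = max(0, y1), min(h - 1, y2)
            out[y1, x1:x2 + 1] = color
            out[y2, x1:x2 + 1] = color
            out[y1:y2 + 1, x1] = color
            out[y1:y2 + 1, x2] = color
        cx, cy = int(round(t.center[0])), int(round(t.center[1]))
        if 0 <= cy < h and 0 <= cx < w:
            out[cy, cx] = (255, 255, 255)
    # running tallies as filled marker bars (top-left corner, one row/class)
    for c, n in sorted(state.counts.items()):
        row = 2 + 3 * c
        if row < h:
            out[row:row + 2, 2:2 + min(2 * n, w - 4)] = \
                _CLASS_COLORS[c % len(_CLASS_COLORS)]
    return out


def count_video(frames, detections_per_frame, line: ReferenceLine,
                tracker: CentroidTracker | None = None,
                annotate_dir=None) -> dict:
    """Drive tracker + line counter over a frame/detections stream.

    ``frames`` may be None when no annotation output is wanted. Returns a
    JSON-ready report with per-class totals and per-id crossing frames.
    """
    tracker = tracker or CentroidTracker()
    state = CountState()
    crossing_frame: dict[int, int] = {}
    frames = frames if frames is not None else [None] * len(detections_per_frame)
    for fi, (frame, dets) in enumerate(zip(frames, detections_per_frame)):
        tracks = tracker.update(dets)
        before = set(state.counted_ids)
        update_line_counts(tracks, line, state)
        for tid in set(state.counted_ids) - before:
            crossing_frame[tid] = fi
        if annotate_dir is not None and frame is not None:
            from PIL import Image
            import os

            det_boxes = {t.id: d.box for t, d in _pair_tracks_dets(tracks, dets)}
            img = annotate_frame(frame, tracks, state, line, det_boxes)
            Image.fromarray(img).save(
                os.path.join(annotate_dir, f"frame_{fi:05d}.png"))
    return {
        "counts": {int(k): int(v) for k, v in sorted(state.counts.items())},
        "crossing_frame": {int(k): int(v) for k, v in sorted(crossing_frame.items())},
        "n_frames": len(detections_per_frame),
    }


def _pair_tracks_dets(tracks: list[TrackState], dets: list[Detection]):
    """Associate live tracks with the detection at their current centre."""
    out = []
    for t in tracks:
        cx, cy = t.center
        for d in dets:
            dx, dy = (d.box[0] + d.box[2]) / 2, (d.box[1] + d.box[3]) / 2
            if abs(dx - cx) < 1e-6 and abs(dy - cy) < 1e-6 and d.cls == t.class_id:
                out.append((t, d))
                break
    return out


def save_count_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
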
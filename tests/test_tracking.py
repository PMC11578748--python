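"""Centroid tracking and reference-line counting."""

import itertools

import numpy as np
import pytest

from sproutnet.model import Detection
from sproutnet.synth import SceneSpec, gen_field_video
from sproutnet.tracking import (
    CentroidTracker,
    CountState,
    ReferenceLine,
    TrackState,
    annotate_frame,
    count_video,
    update_line_counts,
)


def det(cx, cy, cls=0, r=5.0):
    return Detection(np.array([cx - r, cy - r, cx + r, cy + r]), cls, 0.9)


class TestCentroidTracker:
    def test_static_detections_keep_ids(self):
        tr = CentroidTracker(max_dist=20)
        a = tr.update([det(10, 10), det(50, 50)])
        b = tr.update([det(11, 10), det(50, 51)])
        assert {t.id for t in a} == {t.id for t in b}

    def test_long_jump_spawns_new_id(self):
        tr = CentroidTracker(max_dist=15)
        a = tr.update([det(10, 10)])
        b = tr.update([det(90, 90)])
        assert a[0].id != b[0].id

    def test_class_gated_matching(self):
        tr = CentroidTracker(max_dist=20)
        a = tr.update([det(10, 10, cls=0)])
        b = tr.update([det(12, 10, cls=1)])
        assert a[0].id != b[0].id

    def test_greedy_equals_min_cost_assignment(self, rng):
        """On 3-track/3-detection steps with well-separated objects the
        greedy nearest-centroid update matches exhaustive minimum-cost
        assignment."""
        for trial in range(30):
            centers = rng.uniform(10, 150, (3, 2))
            steps = centers + rng.uniform(-4, 4, (3, 2))
            tr = CentroidTracker(max_dist=25)
            first = tr.update([det(*c) for c in centers])
            ids0 = [t.id for t in first]
            second = tr.update([det(*s) for s in steps])
            got = {t.id: t.center for t in second}

            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(3)):
                cost = sum(np.hypot(*(centers[i] - steps[perm[i]]))
                           for i in range(3))
                if cost < best_cost:
                    best, best_cost = perm, cost
            for i, t_id in enumerate(ids0):
                expect = steps[best[i]]
                assert got[t_id] == pytest.approx(tuple(expect), abs=1e-6)

    def test_patience_drops_stale_tracks(self):
        tr = CentroidTracker(max_dist=20, patience=1)
        tr.update([det(10, 10)])
        tr.update([])
        tr.update([])
        assert tr.tracks == []


class TestReferenceLine:
    def test_center_constructor(self):
        line = ReferenceLine.center_of(200, 100)
        assert line.orientation == "horizontal"
        assert line.position == 50

    def test_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ReferenceLine("horizontal", 120, frame_size=(100, 100))

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            ReferenceLine("diagonal", 10)


class TestLineCounting:
    def _track(self, tid, cls, ys):
        return TrackState(tid, cls, [(50.0, float(y)) for y in ys])

    def test_single_crossing_counted_once(self):
        line = ReferenceLine("horizontal", 80)
        state = CountState()
        t = self._track(0, 0, [70])
        update_line_counts([t], line, state)
        t.history.append((50.0, 90.0))
        update_line_counts([t], line, state)
        assert state.counts == {0: 1}

    def test_oscillation_debounce(self):
        line = ReferenceLine("horizontal", 80)
        state = CountState()
        t = self._track(0, 0, [70])
        for y in [90, 70, 90, 70, 90, 70, 90]:
            t.history.append((50.0, float(y)))
            update_line_counts([t], line, state)
        assert state.counts == {0: 1}

    def test_first_seen_past_line_not_counted(self):
        line = ReferenceLine("horizontal", 80)
        state = CountState()
        t = self._track(0, 0, [90, 95, 100])
        update_line_counts([t], line, state)
        assert state.counts == {}

    def test_exact_line_touch_then_cross(self):
        line = ReferenceLine("horizontal", 80)
        state = CountState()
        t = self._track(0, 0, [70, 80])
        update_line_counts([t], line, state)
        assert state.counts == {}          # sitting on the line: undecided
        t.history.append((50.0, 90.0))
        update_line_counts([t], line, state)
        assert state.counts == {0: 1}

    def test_counts_monotone_nondecreasing(self, rng):
        line = ReferenceLine("vertical", 50)
        state = CountState()
        tracks = {}
        prev_total = 0
        for frame in range(30):
            live = []
            for tid in range(6):
                x = float(rng.uniform(0, 100))
                tracks.setdefault(tid, TrackState(tid, tid % 2, []))
                tracks[tid].history.append((x, 10.0))
                live.append(tracks[tid])
            update_line_counts(live, line, state)
            total = sum(state.counts.values())
            assert total >= prev_total
            prev_total = total
        assert prev_total == len(state.counted_ids)


@pytest.fixture(scope="module")
def video():
    spec = SceneSpec(size=160, n_seedlings=20, n_weeds=5, seed=3)
    return gen_field_video(spec, n_frames=50, sweep_speed=8.0)


class TestVideoCounting:

    def test_exact_counts_from_gt_tracks(self, video):
        frames, tracks, expected = video
        dets = [[Detection(np.array(b), c, 1.0) for _, c, b in fr]
                for fr in tracks]
        line = ReferenceLine.center_of(160, 160, "vertical")
        rep = count_video(None, dets, line, CentroidTracker(max_dist=30))
        assert rep["counts"] == expected
        assert expected == {0: 20, 1: 5}

    def test_rerun_identical(self, video):
        frames, tracks, _ = video
        dets = [[Detection(np.array(b), c, 1.0) for _, c, b in fr]
                for fr in tracks]
        line = ReferenceLine.center_of(160, 160, "vertical")
        r1 = count_video(None, dets, line, CentroidTracker(max_dist=30))
        r2 = count_video(None, dets, line, CentroidTracker(max_dist=30))
        assert r1 == r2

    def test_zero_object_video(self):
        line = ReferenceLine.center_of(160, 160, "vertical")
        rep = count_video(None, [[] for _ in range(10)], line)
        assert rep["counts"] == {}


class TestAnnotate:
    def test_dimensions_and_purity(self):
        frame = np.zeros((60, 80, 3), np.uint8)
        line = ReferenceLine.center_of(80, 60)
        state = CountState()
        t = TrackState(0, 0, [(40.0, 30.0)])
        out = annotate_frame(frame, [t], state, line,
                             boxes={0: np.array([30, 20, 50, 40.0])})
        assert out.shape == frame.shape
        assert np.all(frame == 0)          # input untouched
        assert np.any(out != 0)            # something drawn
        out2 = annotate_frame(frame, [t], state, line,
                              boxes={0: np.array([30, 20, 50, 40.0])})
        np.testing.assert_array_equal(out, out2)   # idempotent on state

    def test_empty_tracks_only_line(self):
        frame = np.zeros((20, 20, 3), np.uint8)
        line = ReferenceLine.center_of(20, 20)
        out = annotate_frame(frame, [], CountState(), line)
        assert np.all(out[10] == (255, 255, 0))
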
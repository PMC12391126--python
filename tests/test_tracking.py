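"""Grid ID initialization and IoU identity inheritance."""

from datetime import datetime, timedelta

import numpy as np
import pytest

import leafcal as lc
from leafcal.io_formats import FrameObservation
from leafcal.tracking import start_tracks

from conftest import id_consistency, make_mask


def square_mask(shape, x, y, side):
    return make_mask(shape, np.s_[y : y + side, x : x + side])


def lattice_frame(time, jitter=0, pitch=100, side=20, shape=(400, 400), seed=0):
    """16 square leaves on a 4x4 lattice, optional centroid jitter in px."""
    rng = np.random.default_rng(seed)
    masks = []
    for r in range(4):
        for c in range(4):
            dx, dy = (rng.integers(-jitter, jitter + 1, 2) if jitter else (0, 0))
            x = int(pitch * c + pitch // 2 - side // 2 + dx)
            y = int(pitch * r + pitch // 2 - side // 2 + dy)
            masks.append(square_mask(shape, x, y, side))
    return FrameObservation(time=time, width=shape[1], height=shape[0], masks=masks)


class TestIoU:
    def test_identical_masks(self):
        m = square_mask((20, 20), 3, 3, 5)
        assert lc.iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = square_mask((20, 20), 0, 0, 4)
        b = square_mask((20, 20), 10, 10, 4)
        assert lc.iou(a, b) == 0.0

    def test_offset_squares_third(self):
        a = make_mask((10, 10), np.s_[0:2, 0:2])
        b = make_mask((10, 10), np.s_[0:2, 1:3])
        assert lc.iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_identity_iff_equal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = (rng.random((15, 15)) > 0.6).astype(np.uint8) * 255
            b = (rng.random((15, 15)) > 0.6).astype(np.uint8) * 255
            if not (a.any() or b.any()):
                continue
            assert lc.iou(a, b) == lc.iou(b, a)
            assert (lc.iou(a, b) == 1.0) == np.array_equal(a > 0, b > 0)

    def test_both_empty_raises(self):
        z = np.zeros((5, 5), np.uint8)
        with pytest.raises(ValueError, match="empty"):
            lc.iou(z, z)


class TestInitialIds:
    def test_exact_lattice_gets_row_major_ids(self):
        frame = lattice_frame(datetime(2025, 3, 1))
        instances = [lc.extract_instance_stats(m) for m in frame.masks]
        mapping = lc.assign_initial_ids(instances)
        assert mapping == {i: i for i in range(16)}

    def test_small_jitter_does_not_change_assignment(self):
        frame = lattice_frame(datetime(2025, 3, 1), jitter=5, seed=7)
        instances = [lc.extract_instance_stats(m) for m in frame.masks]
        assert lc.assign_initial_ids(instances) == {i: i for i in range(16)}

    def test_wrong_count_prompts_manual_review(self):
        frame = lattice_frame(datetime(2025, 3, 1))
        instances = [lc.extract_instance_stats(m) for m in frame.masks[:15]]
        with pytest.raises(ValueError, match="review"):
            lc.assign_initial_ids(instances)


class TestMatchFrame:
    def setup_method(self):
        self.t0 = datetime(2025, 3, 1, 12, 0, 0)
        self.frame0 = lattice_frame(self.t0)
        self.shape = (400, 400)

    def test_identical_frame_inherits_all_ids(self):
        tracks = start_tracks(self.frame0)
        frame1 = lattice_frame(self.t0 + timedelta(minutes=15))
        lc.match_frame(tracks, frame1)
        assert len(tracks) == 16
        assert all(len(t.observations) == 2 for t in tracks)

    def test_grown_leaf_above_threshold_keeps_id(self):
        tracks = start_tracks(self.frame0)
        masks = list(lattice_frame(self.t0 + timedelta(minutes=15)).masks)
        # grow leaf 0 from 20x20 to 25x25 anchored at the same corner:
        # IoU = 400/625 = 0.64 > 0.5
        masks[0] = square_mask(self.shape, 40, 40, 25)
        frame1 = FrameObservation(
            time=self.t0 + timedelta(minutes=15), width=400, height=400, masks=masks
        )
        lc.match_frame(tracks, frame1)
        assert len(tracks) == 16
        assert tracks[0].observations[-1][1].pixel_count == 625

    def test_low_iou_instance_opens_new_id_16(self):
        tracks = start_tracks(self.frame0)
        masks = list(lattice_frame(self.t0 + timedelta(minutes=15)).masks)
        masks.append(square_mask(self.shape, 2, 2, 10))  # overlaps nothing
        frame1 = FrameObservation(
            time=self.t0 + timedelta(minutes=15), width=400, height=400, masks=masks
        )
        lc.match_frame(tracks, frame1)
        assert sorted(t.leaf_id for t in tracks) == list(range(17))

    def test_conflict_resolved_by_descending_iou(self):
        # two candidates over one track: the higher-IoU one wins the ID,
        # the loser opens a new track
        t0 = self.t0
        base = square_mask((100, 100), 40, 40, 20)
        frame0 = FrameObservation(time=t0, width=100, height=100, masks=[base])
        config = lc.MatchConfig(rows=1, cols=1)
        tracks = start_tracks(frame0, config)
        close = square_mask((100, 100), 42, 40, 20)   # IoU 18/22 side overlap
        further = square_mask((100, 100), 45, 40, 20)  # lower IoU, still > 0.5
        v_close = lc.iou(base, close)
        v_far = lc.iou(base, further)
        assert v_close > v_far > 0.5
        frame1 = FrameObservation(
            time=t0 + timedelta(minutes=15), width=100, height=100,
            masks=[further, close],
        )
        lc.match_frame(tracks, frame1, config)
        assert len(tracks) == 2
        winner = tracks[0].observations[-1][1]
        assert np.array_equal(winner.raster, close)

    def test_observation_count_conserved_and_ids_never_shrink(self):
        tracks = start_tracks(self.frame0)
        n_instances = 16
        for k in range(1, 4):
            frame = lattice_frame(self.t0 + timedelta(minutes=15 * k))
            ids_before = {t.leaf_id for t in tracks}
            lc.match_frame(tracks, frame)
            n_instances += len(frame.masks)
            assert {t.leaf_id for t in tracks} >= ids_before
        assert sum(len(t.observations) for t in tracks) == n_instances


class TestSyntheticSequence:
    def test_full_identity_recovery_on_growing_scene(self, tracked_scene):
        """Monotone concentric growth without occlusion: every leaf keeps
        its identity for the whole series."""
        _, frames, gt, tracks = tracked_scene
        assert len(tracks) == 16
        assert id_consistency(tracks, frames, gt) == 1.0

    def test_observation_total_matches_instances(self, tracked_scene):
        _, frames, _, tracks = tracked_scene
        assert sum(len(t.observations) for t in tracks) == sum(
            len(f) for f in frames
        )
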
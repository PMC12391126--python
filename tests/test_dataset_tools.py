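"""Retention filtering, dataset splitting, and seeded augmentation."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

import leafcal as lc
from leafcal.dataset_tools import rotate_points


def frame_names(n, interval_min, start=datetime(2025, 3, 1)):
    return [
        "f_" + (start + timedelta(minutes=i * interval_min)).strftime(
            "%Y-%m-%d-%H-%M-%S"
        ) + ".jpg"
        for i in range(n)
    ]


class TestFilterFrames:
    def test_no_exclusions_returns_input(self):
        frames = frame_names(10, 30)
        assert lc.filter_frames(frames, 0.0, 0.0) == frames

    def test_source_experiment_retention_count(self):
        """3456 frames; 480 in the first 24 h, 960 in the last 48 h, and 293
        flagged frames in between leave 1723 survivors."""
        frames = frame_names(3456, 3)  # 3-min cadence: 480 frames per 24 h
        flagged = set(frames[600:893])  # 293 frames, disjoint from windows
        kept = lc.filter_frames(frames, 24.0, 48.0, flagged)
        assert len(kept) == 1723

    def test_multiply_excluded_frame_counted_once(self):
        # 10 frames: 3 in the leading window (1 of them also flagged),
        # 1 more flagged elsewhere -> 6 retained
        frames = frame_names(10, 60)
        flagged = {frames[1], frames[5]}
        kept = lc.filter_frames(frames, 2.5, 0.0, flagged)
        assert len(kept) == 6
        assert frames[5] not in kept

    def test_windows_covering_everything_warn_not_raise(self, caplog):
        frames = frame_names(5, 60)
        with caplog.at_level("WARNING"):
            assert lc.filter_frames(frames, 100.0, 0.0) == []
        assert "every frame" in caplog.text

    def test_survivors_in_time_order(self):
        frames = frame_names(20, 15)
        shuffled = list(reversed(frames))
        kept = lc.filter_frames(shuffled, 0.0, 0.0)
        assert kept == frames


class TestSplitDataset:
    def test_source_dataset_sizes(self):
        train, val, test = lc.split_dataset(list(range(2707)), seed=0)
        assert (len(train), len(val), len(test)) == (1895, 541, 271)

    def test_small_n_rounding(self):
        train, val, test = lc.split_dataset(list(range(10)), seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_same_seed_reproduces_partition(self):
        items = [f"img{i}" for i in range(57)]
        assert lc.split_dataset(items, seed=42) == lc.split_dataset(items, seed=42)

    def test_partition_is_disjoint_and_exhaustive(self):
        for n in (3, 17, 100, 333):
            items = list(range(n))
            train, val, test = lc.split_dataset(items, seed=5)
            combined = train + val + test
            assert len(combined) == n
            assert set(combined) == set(items)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            lc.SplitRatios(0.7, 0.2, 0.2)


class TestAugment:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        self.square = [(24.0, 24.0), (40.0, 24.0), (40.0, 40.0), (24.0, 40.0)]

    def test_identity_spec_is_noop(self):
        out, polys = lc.augment(
            self.img, [self.square], lc.AugmentSpec.identity(), seed=3
        )
        assert np.array_equal(out, self.img)
        assert np.allclose(polys[0], self.square)

    def test_rotation_matches_rotation_matrix_oracle(self):
        spec = lc.AugmentSpec(
            rotation_deg=(30.0, 30.0), hue_deg=(0, 0), brightness=(0, 0),
            blur_px=0.0, noise_frac=0.0,
        )
        _, polys = lc.augment(self.img, [self.square], spec, seed=0)
        a = np.deg2rad(30.0)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        c = np.array([32.0, 32.0])
        expect = (np.asarray(self.square) - c) @ rot.T + c
        assert np.abs(polys[0] - expect).max() < 0.5

    def test_90_degree_rotation_of_centered_square_is_symmetry(self):
        spec = lc.AugmentSpec(
            rotation_deg=(90.0, 90.0), hue_deg=(0, 0), brightness=(0, 0),
            blur_px=0.0, noise_frac=0.0,
        )
        _, polys = lc.augment(self.img, [self.square], spec, seed=0)
        got = {tuple(np.round(p, 6)) for p in polys[0]}
        expect = {tuple(map(float, v)) for v in self.square}
        assert got == expect

    def test_rotation_preserves_vertex_count_and_area(self):
        spec = lc.AugmentSpec(
            rotation_deg=(-45.0, 45.0), hue_deg=(0, 0), brightness=(0, 0),
            blur_px=0.0, noise_frac=0.0,
        )
        for seed in range(5):
            _, polys = lc.augment(self.img, [self.square], spec, seed=seed)
            assert len(polys[0]) == 4
            a0 = ShapelyPolygon(self.square).area
            a1 = ShapelyPolygon(polys[0]).area
            assert abs(a1 - a0) / a0 < 0.01

    def test_polygon_rotated_out_of_frame_dropped_with_warning(self, caplog):
        corner = [(60.0, 0.0), (64.0, 0.0), (64.0, 4.0), (60.0, 4.0)]
        spec = lc.AugmentSpec(
            rotation_deg=(89.0, 89.0), hue_deg=(0, 0), brightness=(0, 0),
            blur_px=0.0, noise_frac=0.0,
        )
        big = np.zeros((40, 200, 3), np.uint8)  # wide frame: corner swings out
        with caplog.at_level("WARNING"):
            _, polys = lc.augment(big, [[(190.0, 2.0), (198.0, 2.0), (198.0, 8.0), (190.0, 8.0)]], spec, seed=0)
        assert polys == []
        assert "dropped" in caplog.text
        del corner

    def test_photometric_transforms_leave_polygons_alone(self):
        spec = lc.AugmentSpec(
            rotation_deg=(0.0, 0.0), hue_deg=(40.0, 40.0),
            brightness=(0.3, 0.3), blur_px=2.0, noise_frac=0.02,
        )
        out, polys = lc.augment(self.img, [self.square], spec, seed=1)
        assert np.allclose(polys[0], self.square)
        assert not np.array_equal(out, self.img)

    def test_same_seed_same_output(self):
        a = lc.augment(self.img, [self.square], lc.AugmentSpec(), seed=9)
        b = lc.augment(self.img, [self.square], lc.AugmentSpec(), seed=9)
        assert np.array_equal(a[0], b[0])
        assert np.allclose(a[1][0], b[1][0])


def test_rotate_points_round_trip():
    pts = np.array([[1.0, 2.0], [5.0, 7.0]])
    back = rotate_points(rotate_points(pts, 33.0, (3, 3)), -33.0, (3, 3))
    assert np.allclose(back, pts)
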
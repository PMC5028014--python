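"""Detection and tracking: distance images, suppressed maxima, Gaussian-
weighted following, duplicate pruning and the full tracking loop."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cellmot import (
    DetectionParams,
    Track,
    TrackingParams,
    detect_cells,
    preprocess_frame,
    prune_duplicates,
    run_tracking,
    track_step,
)
from cellmot.tracking import LOST

from conftest import render_disk


def brute_force_distance_transform(mask: np.ndarray) -> np.ndarray:
    """O(N^2) oracle: each foreground pixel's distance to nearest background."""
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    fg = np.column_stack([yy[mask], xx[mask]])
    bg = np.column_stack([yy[~mask], xx[~mask]])
    out = np.zeros(mask.shape)
    if len(fg) and len(bg):
        out[mask] = cdist(fg, bg).min(axis=1)
    return out


class TestPreprocess:
    def test_all_background_gives_zeros(self):
        img = np.full((32, 32), 10.0)
        params = DetectionParams(blur_sigma=0, threshold=50)
        assert not preprocess_frame(img, params).any()

    def test_disk_peaks_at_centre_with_value_near_radius(self):
        img = render_disk((100, 100), 50, 50, 10)
        d = preprocess_frame(img, DetectionParams(blur_sigma=0, threshold=100))
        iy, ix = np.unravel_index(np.argmax(d), d.shape)
        assert abs(d.max() - 10) <= 1
        assert abs(ix - 50) <= 1 and abs(iy - 50) <= 1

    def test_two_disks_match_brute_force_oracle(self):
        img = render_disk((64, 64), 15, 20, 7) + render_disk((64, 64), 45, 40, 6)
        params = DetectionParams(blur_sigma=0, threshold=100)
        d = preprocess_frame(img, params)
        oracle = brute_force_distance_transform(img > 100)
        np.testing.assert_allclose(d, oracle, atol=1e-9)
        # maxima of each positive region sit at the disk centres
        for cx, cy, r in ((15, 20, 7), (45, 40, 6)):
            win = d[cy - r:cy + r + 1, cx - r:cx + r + 1]
            iy, ix = np.unravel_index(np.argmax(win), win.shape)
            assert abs((cx - r + ix) - cx) <= 1 and abs((cy - r + iy) - cy) <= 1

    def test_random_binary_images_exact(self):
        rng = np.random.default_rng(0)
        params = DetectionParams(blur_sigma=0, threshold=0.5)
        for _ in range(10):
            mask = rng.random((40, 40)) < 0.4
            mask[0, 0] = False  # keep some background
            img = mask.astype(float)
            np.testing.assert_array_equal(
                preprocess_frame(img, params),
                brute_force_distance_transform(mask))

    def test_rejects_empty_and_non_2d(self):
        params = DetectionParams()
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((0, 5)), params)
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((4, 4, 3)), params)


class TestDetect:
    params = DetectionParams(blur_sigma=0, threshold=100,
                             suppression_radius=8, min_peak_value=3)

    def test_zero_image_empty(self):
        assert detect_cells(np.zeros((50, 50)), self.params) == []

    def test_single_disk_single_detection(self):
        img = render_disk((80, 80), 40, 30, 9)
        d = preprocess_frame(img, self.params)
        det = detect_cells(d, self.params)
        assert len(det) == 1
        (x, y), = det
        assert abs(x - 40) <= 1 and abs(y - 30) <= 1

    def test_two_equal_maxima_within_suppression_keep_first_in_scan_order(self):
        d = np.zeros((20, 20))
        d[5, 5] = 5.0
        d[5, 10] = 5.0  # 5 px apart < suppression_radius 8
        det = detect_cells(d, self.params)
        assert det == [(5.0, 5.0)]  # row-major tie-break: smaller x wins

    def test_well_separated_maxima_all_kept(self):
        d = np.zeros((40, 40))
        d[5, 5] = 5.0
        d[30, 30] = 4.0
        assert detect_cells(d, self.params) == [(5.0, 5.0), (30.0, 30.0)]

    def test_min_peak_value_filters_shallow_maxima(self):
        d = np.zeros((20, 20))
        d[10, 10] = 2.0  # below min_peak_value 3
        assert detect_cells(d, self.params) == []


class TestTrackStep:
    det = DetectionParams(blur_sigma=0, threshold=100)
    trk = TrackingParams(search_halfwidth=12, gaussian_sigma=6, lost_threshold=0.5)

    def test_stationary_disk_stays_put(self):
        d = preprocess_frame(render_disk((80, 80), 40, 40, 8), self.det)
        assert track_step(d, (40.0, 40.0), self.trk) == (40.0, 40.0)

    def test_follows_two_pixel_displacement(self):
        d = preprocess_frame(render_disk((80, 80), 42, 40, 8), self.det)
        new = track_step(d, (40.0, 40.0), self.trk)
        assert new is not LOST
        assert abs(new[0] - 42) <= 1 and abs(new[1] - 40) <= 1

    def test_background_is_lost(self):
        d = np.zeros((80, 80))
        assert track_step(d, (40.0, 40.0), self.trk) is LOST

    def test_window_clipped_at_boundary(self):
        d = preprocess_frame(render_disk((60, 60), 3, 3, 5), self.det)
        new = track_step(d, (1.0, 1.0), self.trk)
        assert new is not LOST  # no out-of-bounds access near the corner


class TestPruneDuplicates:
    def test_identical_positions_keep_one(self):
        t1 = Track(0, [(0, 10.0, 10.0)])
        t2 = Track(1, [(0, 10.0, 10.0)])
        kept = prune_duplicates([t1, t2], 0, duplicate_radius=5)
        assert [t.id for t in kept] == [0]
        assert t2.status == "pruned"

    def test_distant_tracks_all_kept(self):
        tracks = [Track(i, [(0, 20.0 * i, 0.0)]) for i in range(4)]
        kept = prune_duplicates(tracks, 0, duplicate_radius=5)
        assert len(kept) == 4

    def test_longest_lived_wins_among_three(self):
        # ages 5, 3, 3 (ids 1, 2, 3), all at nearly the same spot
        t1 = Track(1, [(f, 10.0, 10.0) for f in range(6)])
        t2 = Track(2, [(f, 11.0, 10.0) for f in range(2, 6)])
        t3 = Track(3, [(f, 10.0, 11.0) for f in range(2, 6)])
        kept = prune_duplicates([t1, t2, t3], 5, duplicate_radius=5)
        assert [t.id for t in kept] == [1]
        assert t2.status == t3.status == "pruned"


class TestRunTracking:
    det = DetectionParams(blur_sigma=0, threshold=100, suppression_radius=8,
                          min_peak_value=3)
    trk = TrackingParams()

    def test_empty_video_no_tracks(self):
        frames = [np.zeros((64, 64))] * 5
        assert run_tracking(frames, self.det, self.trk) == []

    def test_single_stationary_cell_one_full_track(self):
        frame = render_disk((80, 80), 40, 40, 8)
        tracks = run_tracking([frame] * 50, self.det, self.trk)
        assert len(tracks) == 1
        assert len(tracks[0].points) == 50
        frames_seq = [p[0] for p in tracks[0].points]
        assert frames_seq == list(range(50))

    def test_requires_two_frames_and_equal_shapes(self):
        with pytest.raises(ValueError):
            run_tracking([np.zeros((32, 32))], self.det, self.trk)
        with pytest.raises(ValueError):
            run_tracking([np.zeros((32, 32)), np.zeros((16, 16))], self.det, self.trk)

    def test_no_two_active_tracks_within_duplicate_radius(self, small_scene):
        tracks = run_tracking(small_scene.frames)
        trk = TrackingParams()
        by_frame = {}
        for t in tracks:
            for f, x, y in t.points:
                by_frame.setdefault(f, []).append((t.id, x, y, t))
        for f, entries in by_frame.items():
            # only tracks still active *after* this frame were both retained
            live = [(x, y) for _id, x, y, t in entries
                    if t.last_frame > f or t.status == "active"]
            for i in range(len(live)):
                for j in range(i + 1, len(live)):
                    d = np.hypot(live[i][0] - live[j][0], live[i][1] - live[j][1])
                    assert d > trk.duplicate_radius

    def test_tracks_are_gapless_and_in_bounds(self, small_scene):
        h, w = small_scene.frames.shape[1:]
        for t in run_tracking(small_scene.frames):
            frames_seq = [p[0] for p in t.points]
            assert frames_seq == list(range(frames_seq[0], frames_seq[-1] + 1))
            for _f, x, y in t.points:
                assert 0 <= x <= w - 1 and 0 <= y <= h - 1

    def test_recovers_most_ground_truth_positions(self, small_scene):
        tracks = run_tracking(small_scene.frames)
        by_frame = {}
        for t in tracks:
            for f, x, y in t.points:
                by_frame.setdefault(f, []).append((x, y))
        total = matched = 0
        for pts in small_scene.true_tracks.values():
            for f, x, y in pts:
                total += 1
                cand = by_frame.get(f, [])
                if cand and min(np.hypot(x - a, y - b) for a, b in cand) <= 3:
                    matched += 1
        assert matched / total >= 0.95
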
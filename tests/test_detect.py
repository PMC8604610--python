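import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousegait.config import DetectionThresholds
from mousegait.detect import (
    PawCluster,
    compute_centroid,
    detect_paws,
    filter_cluster_size,
    proximity_cluster,
    threshold_green,
)
from mousegait.frames import FrameImage
from mousegait.simulate import SyntheticGaitConfig, paw_template


def frame_with_green(g_grid):
    g = np.asarray(g_grid, dtype=np.uint8)
    px = np.zeros(g.shape + (3,), np.uint8)
    px[:, :, 1] = g
    return FrameImage(px)


class TestThresholdGreen:
    def test_dark_frame_yields_nothing(self):
        img = frame_with_green(np.zeros((5, 5)))
        coords, _ = threshold_green(img, 205, (0, 5))
        assert coords.shape == (0, 2)

    def test_exact_pixels_recovered(self):
        g = np.zeros((5, 5))
        g[2, 2] = 255  # (x=2, y=2)
        g[1, 4] = 255  # (x=4, y=1)
        coords, gv = threshold_green(frame_with_green(g), 205, (0, 5))
        assert {tuple(c) for c in coords} == {(2, 2), (4, 1)}
        assert set(gv) == {255}

    def test_zero_threshold_returns_whole_band(self):
        img = frame_with_green(np.zeros((6, 4)))
        coords, _ = threshold_green(img, 0, (1, 4))
        assert coords.shape[0] == 3 * 4
        assert set(coords[:, 1]) == {1, 2, 3}

    def test_empty_band_rejected(self):
        img = frame_with_green(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            threshold_green(img, 205, (3, 3))

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_adds_pixels(self, t1, t2, seed):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(seed)
        img = frame_with_green(rng.integers(0, 256, (8, 8)))
        n_lo = threshold_green(img, lo, (0, 8))[0].shape[0]
        n_hi = threshold_green(img, hi, (0, 8))[0].shape[0]
        assert n_hi <= n_lo


class TestProximityCluster:
    def test_single_pixel(self):
        parts = proximity_cluster(np.array([[0, 0]]), 2.0)
        assert [p.tolist() for p in parts] == [[0]]

    def test_separated_groups(self):
        pts = np.array([[0, 0], [0, 1], [10, 10]])
        parts = proximity_cluster(pts, 2.0)
        assert [sorted(p) for p in parts] == [[0, 1], [2]]

    def test_chain_transitivity(self):
        # endpoints 4 apart (> threshold) still join through the middle
        pts = np.array([[0, 0], [0, 2], [0, 4]])
        parts = proximity_cluster(pts, 2.0)
        assert len(parts) == 1

    def test_empty_input(self):
        assert proximity_cluster(np.empty((0, 2)), 2.0) == []

    @pytest.mark.parametrize("threshold", [1.0, 2.0, 5.0])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_sets(self, threshold, seed, oracle_cluster):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(1, 50))
        pts = rng.integers(0, 25, (n, 2))
        pts = np.unique(pts, axis=0)
        parts = proximity_cluster(pts, threshold)
        got = {frozenset(p.tolist()) for p in parts}
        assert got == oracle_cluster(pts.tolist(), threshold)

    def test_stencil_and_kdtree_paths_agree(self, oracle_cluster):
        rng = np.random.default_rng(7)
        pts = np.unique(rng.integers(0, 20, (40, 2)), axis=0)
        fast = {frozenset(p.tolist()) for p in proximity_cluster(pts, 2.0)}
        general = {
            frozenset(p.tolist())
            for p in proximity_cluster(pts.astype(float) + 0.0, 2.0)
        }
        # float coords that are whole numbers still take the stencil; force
        # the KD-tree path via a threshold above the stencil cutoff
        wide_fast = {frozenset(p.tolist()) for p in proximity_cluster(pts, 5.0)}
        assert fast == general == oracle_cluster(pts.tolist(), 2.0)
        assert wide_fast == oracle_cluster(pts.tolist(), 5.0)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        pts = np.unique(rng.integers(0, 30, (60, 2)), axis=0)
        parts = proximity_cluster(pts, 2.0)
        flat = sorted(i for p in parts for i in p)
        assert flat == list(range(len(pts)))


class TestSizeFilterAndCentroid:
    def make_cluster(self, n):
        coords = np.column_stack([np.arange(n), np.zeros(n, int)])
        return PawCluster(0, coords, np.full(n, 255))

    def test_inclusive_boundaries(self):
        clusters = [self.make_cluster(n) for n in (64, 65, 510, 511)]
        kept = filter_cluster_size(clusters, 65, 510)
        assert [c.size for c in kept] == [65, 510]

    def test_empty_list(self):
        assert filter_cluster_size([], 65, 510) == []

    def test_degenerate_bounds_keep_everything(self):
        clusters = [self.make_cluster(n) for n in (1, 7, 300, 10000)]
        assert len(filter_cluster_size(clusters, 1, 10**9)) == 4

    @pytest.mark.parametrize(
        "coords,expected",
        [
            ([(3, 4)], (3.0, 4.0)),
            ([(0, 0), (2, 0), (0, 2), (2, 2)], (1.0, 1.0)),
            ([(0, 0), (0, 1), (0, 5)], (0.0, 2.0)),
        ],
    )
    def test_centroid_examples(self, coords, expected):
        assert compute_centroid(np.array(coords)) == expected

    def test_centroid_of_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            compute_centroid(np.empty((0, 2)))

    @given(st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_centroid_inside_bounding_box(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        cluster = PawCluster(0, rng.integers(0, 50, (n, 2)), rng.integers(205, 256, n))
        x, y = cluster.centroid
        x0, y0, x1, y1 = cluster.bounding_box
        assert x0 <= x <= x1 and y0 <= y <= y1


class TestDetectPaws:
    def paw_frame(self, positions, extra=None):
        cfg = SyntheticGaitConfig()
        tpl = paw_template(cfg)
        px = np.zeros((cfg.height, cfg.width, 3), np.uint8)
        for x, y in positions:
            px[tpl[:, 1] + y, tpl[:, 0] + x, 1] = 240
        if extra is not None:
            for x, y in extra:
                px[y, x, 1] = 240
        return FrameImage(px), cfg.band

    def test_blank_frame(self):
        img, band = self.paw_frame([])
        assert detect_paws(img, DetectionThresholds(), band) == []

    def test_four_blobs_recovered_with_accurate_centroids(self):
        positions = [(200, 40), (210, 80), (280, 40), (290, 80)]
        img, band = self.paw_frame(positions)
        clusters = detect_paws(img, DetectionThresholds(), band)
        assert len(clusters) == 4
        cfg = SyntheticGaitConfig()
        tpl_off = paw_template(cfg).mean(axis=0)
        centers = sorted((c.centroid[0] - tpl_off[0], c.centroid[1] - tpl_off[1]) for c in clusters)
        for (gx, gy), (px_, py_) in zip(sorted(positions), centers):
            assert abs(gx - px_) <= 1 and abs(gy - py_) <= 1

    def test_speck_and_streak_filtered_out(self):
        positions = [(200, 40), (210, 80), (280, 40), (290, 80)]
        img, band = self.paw_frame(positions)
        px = img.pixels.copy()
        px[30:32, 100:105, 1] = 240  # 10-pixel speck, below min size
        px[60:64, 10:510 // 4 * 2, 1] = 240  # ~1000-pixel streak, above max
        clusters = detect_paws(FrameImage(px), DetectionThresholds(), band)
        assert len(clusters) == 4

    def test_sorted_by_centroid_x_descending(self):
        positions = [(150, 40), (350, 80), (250, 60)]
        img, band = self.paw_frame(positions)
        xs = [c.centroid[0] for c in detect_paws(img, DetectionThresholds(), band)]
        assert xs == sorted(xs, reverse=True)
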
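"""Otsu thresholding, blob extraction, GMM and convexity refinement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.draw import disk, ellipse

from hemorph.segmentation import (
    DegenerateHistogramError,
    SegmentationConfig,
    otsu_threshold,
    refine_convexity,
    refine_gmm,
    segment_blobs,
    segment_tile,
)
from hemorph.synthetic_data import TileSimParams, generate_he_tile


def brute_force_otsu(hist) -> int:
    """Exhaustive within-class scatter minimization in exact rational
    arithmetic (independent oracle; ties break to the smallest cut)."""
    from fractions import Fraction

    h = [int(c) for c in hist]
    best_t, best_wcv = None, None
    for t in range(255):
        w0 = sum(h[: t + 1])
        w1 = sum(h[t + 1 :])
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(i * h[i] for i in range(t + 1))
        m1 = sum(i * h[i] for i in range(t + 1, 256))
        a0 = sum(i * i * h[i] for i in range(t + 1))
        a1 = sum(i * i * h[i] for i in range(t + 1, 256))
        # class scatter: sum h_i (i - mu)^2 = A - M^2 / W, exactly
        wcv = Fraction(a0) - Fraction(m0 * m0, w0) + Fraction(a1) - Fraction(m1 * m1, w1)
        if best_wcv is None or wcv < best_wcv:
            best_wcv = wcv
            best_t = t
    return best_t


class TestOtsu:
    def test_two_spikes_separated(self):
        h = np.zeros(256)
        h[50] = 120
        h[200] = 80
        t = otsu_threshold(h)
        assert 50 <= t < 200

    def test_single_bin_is_degenerate(self):
        h = np.zeros(256)
        h[77] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(h)

    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(100):
            h = rng.integers(0, 50, size=256).astype(float)
            if np.count_nonzero(h) < 2:
                continue
            assert otsu_threshold(h) == brute_force_otsu(h)

    @given(
        hist=hnp.arrays(
            np.int64, 256, elements=st.integers(min_value=0, max_value=30)
        )
    )
    def test_oracle_equivalence_property(self, hist):
        if np.count_nonzero(hist) < 2:
            return
        assert otsu_threshold(hist) == brute_force_otsu(np.asarray(hist))


class TestSegmentBlobs:
    def test_blank_channel_gives_empty_mask(self):
        mask = segment_blobs(np.full((64, 64), 0.3), SegmentationConfig())
        assert mask.n_labels == 0

    def test_two_discs_found(self):
        chan = np.zeros((128, 128))
        for c in [(30, 30), (90, 90)]:
            rr, cc = disk(c, 10)
            chan[rr, cc] = 1.0
        mask = segment_blobs(chan, SegmentationConfig())
        assert mask.n_labels == 2

    def test_small_disc_removed_by_area_filter(self):
        chan = np.zeros((64, 64))
        rr, cc = disk((32, 32), 3)  # ~28 px < min_area 40
        chan[rr, cc] = 1.0
        mask = segment_blobs(chan, SegmentationConfig())
        assert mask.n_labels == 0

    def test_labels_contiguous_and_within_area_bounds(self, rng):
        chan = (rng.random((128, 128)) > 0.93).astype(float)
        cfg = SegmentationConfig(min_area=2, max_area=50)
        mask = segment_blobs(chan, cfg)
        labels = mask.labels
        present = np.unique(labels[labels > 0])
        assert list(present) == list(range(1, mask.n_labels + 1))
        counts = np.bincount(labels.ravel())[1:]
        assert ((counts >= 2) & (counts <= 50)).all()


class TestRefineGMM:
    def test_small_blob_guard(self, rng):
        cfg = SegmentationConfig(gmm_min_pixels=50)
        assert refine_gmm(rng.normal(100, 5, size=40), cfg) is None

    def test_unimodal_blob_not_split(self, rng):
        cfg = SegmentationConfig()
        assert refine_gmm(rng.normal(120, 10, size=1000), cfg) is None

    def test_bimodal_blob_split_with_high_accuracy(self, rng):
        """Two chromatin populations 12 sigma apart: the EM assignment must
        agree with midpoint thresholding (the independent oracle) >= 99%."""
        x = np.concatenate([rng.normal(60, 10, 500), rng.normal(180, 10, 500)])
        cfg = SegmentationConfig()
        assignment = refine_gmm(x, cfg)
        assert assignment is not None
        oracle = (x > 120).astype(int)
        agree = max((assignment == oracle).mean(), (assignment != oracle).mean())
        assert agree >= 0.99

    def test_close_means_not_split(self, rng):
        # separation below gmm_separation * pooled sigma stays merged
        x = np.concatenate([rng.normal(100, 10, 500), rng.normal(112, 10, 500)])
        assert refine_gmm(x, SegmentationConfig(gmm_separation=2.0)) is None


class TestRefineConvexity:
    def test_solid_circle_unchanged(self):
        m = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 15)
        m[rr, cc] = True
        parts = refine_convexity(m, SegmentationConfig())
        assert len(parts) == 1
        np.testing.assert_array_equal(parts[0], m)

    def test_convex_ellipse_unchanged(self):
        m = np.zeros((80, 80), bool)
        rr, cc = ellipse(40, 40, 10, 20)
        m[rr, cc] = True
        parts = refine_convexity(m, SegmentationConfig())
        assert len(parts) == 1

    def test_overlapping_circles_split_against_nearest_center_oracle(self):
        """Two r=20 circles, centers 30 px apart: the cut must yield two
        parts whose areas match nearest-center pixel assignment within 15%."""
        yy, xx = np.mgrid[0:80, 0:110]
        d1 = (yy - 40) ** 2 + (xx - 40) ** 2
        d2 = (yy - 40) ** 2 + (xx - 70) ** 2
        m = (d1 <= 400) | (d2 <= 400)
        parts = refine_convexity(m, SegmentationConfig())
        assert len(parts) == 2
        areas = sorted(p.sum() for p in parts)
        oracle = sorted([(m & (d1 <= d2)).sum(), (m & (d2 < d1)).sum()])
        for got, want in zip(areas, oracle):
            assert abs(got - want) / want <= 0.15

    def test_never_increases_foreground(self):
        yy, xx = np.mgrid[0:80, 0:110]
        m = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 400) | (
            (yy - 40) ** 2 + (xx - 70) ** 2 <= 400
        )
        parts = refine_convexity(m, SegmentationConfig())
        assert sum(p.sum() for p in parts) <= m.sum()
        # parts are disjoint
        stack = np.sum([p.astype(int) for p in parts], axis=0)
        assert stack.max() <= 1


class TestSegmentTile:
    def test_background_only_tile_has_no_nuclei(self, reference):
        params = TileSimParams(size=128, n_nuclei=0, seed=1)
        tile, _ = generate_he_tile(params)
        mask = segment_tile(tile, reference)
        assert mask.n_labels == 0

    def test_planted_nuclei_recovered(self, reference):
        """Moderate-noise tile, 30 planted nuclei: >= 90% found within 5 px."""
        params = TileSimParams(size=256, n_nuclei=30, seed=5)
        tile, truth = generate_he_tile(params)
        mask = segment_tile(tile, reference)
        labels = mask.labels
        centroids = []
        for lab in range(1, mask.n_labels + 1):
            ys, xs = np.nonzero(labels == lab)
            centroids.append((xs.mean(), ys.mean()))
        centroids = np.array(centroids)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centroids).query(truth.centroids)
        assert (d <= 5).mean() >= 0.9
        d2, _ = cKDTree(truth.centroids).query(centroids)
        assert (d2 <= 5).mean() >= 0.9

    def test_deterministic_given_seed(self, reference):
        params = TileSimParams(size=128, n_nuclei=10, seed=2)
        tile, _ = generate_he_tile(params)
        cfg = SegmentationConfig(seed=7)
        m1 = segment_tile(tile, reference, config=cfg)
        m2 = segment_tile(tile, reference, config=cfg)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_emitted_areas_respect_config_bounds(self, reference):
        params = TileSimParams(size=256, n_nuclei=25, seed=3, touching_fraction=0.4)
        tile, _ = generate_he_tile(params)
        cfg = SegmentationConfig()
        mask = segment_tile(tile, reference, config=cfg)
        counts = np.bincount(mask.labels.ravel())[1:]
        assert ((counts >= cfg.min_area) & (counts <= cfg.max_area)).all()
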
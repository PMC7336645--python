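"""Displacement-area-ratio statistic: thresholding, masks, IoU."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ivmotion as m
from ivmotion.displacement import MIPSequence

from conftest import brute_force_iou, brute_force_median, brute_force_otsu_8bit


class TestPooledOtsu:
    def test_bimodal_split(self):
        """Half pixels at 10, half at 200: threshold lies strictly between."""
        frames = np.empty((2, 10, 10), dtype=np.uint8)
        frames[:, :, :5] = 10
        frames[:, :, 5:] = 200
        thr = m.pooled_otsu_threshold(frames)
        assert 10 <= thr < 200
        assert np.array_equal(frames > thr, frames == 200)

    def test_matches_exhaustive_scan(self, rng):
        """Pooled threshold equals the brute-force intra-class-variance scan."""
        for _ in range(5):
            frames = rng.integers(0, 256, size=(4, 24, 24)).astype(np.uint8)
            assert m.pooled_otsu_threshold(frames) == brute_force_otsu_8bit(frames)

    def test_foreground_agrees_with_skimage(self, rng):
        """Independent reference: same foreground as skimage's Otsu on 8-bit."""
        from skimage.filters import threshold_otsu

        for _ in range(5):
            frames = rng.integers(0, 256, size=(3, 24, 24)).astype(np.uint8)
            mine = frames > m.pooled_otsu_threshold(frames)
            ref = frames > threshold_otsu(frames)
            assert np.array_equal(mine, ref)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            m.pooled_otsu_threshold(np.full((3, 8, 8), 7, dtype=np.uint8))

    def test_pooling_is_global_not_per_frame(self):
        """A dim frame and a bright frame share one threshold."""
        dim = np.full((16, 16), 20, dtype=np.uint8)
        dim[4:8, 4:8] = 60
        bright = np.full((16, 16), 20, dtype=np.uint8)
        bright[4:8, 4:8] = 220
        thr = m.pooled_otsu_threshold(np.stack([dim, bright]))
        masks = m.binarize_and_denoise(np.stack([dim, bright]), thr, kernel=1).masks
        # one global threshold: the bright frame's cells survive it
        assert masks[1].sum() == 16


class TestBinarizeDenoise:
    def test_isolated_pixel_removed(self):
        img = np.zeros((2, 9, 9), dtype=np.uint8)
        img[:, 4, 4] = 255
        masks = m.binarize_and_denoise(img, threshold=100, kernel=3).masks
        assert not masks.any()

    def test_square_matches_direct_median(self):
        img = np.zeros((1, 16, 16), dtype=np.uint8)
        img[0, 3:13, 3:13] = 255
        masks = m.binarize_and_denoise(img, threshold=100, kernel=3).masks
        expected = brute_force_median(img[0] > 100, 3)
        assert np.array_equal(masks[0], expected)
        assert masks[0][4:12, 4:12].all()  # interior preserved
        assert not masks[0][3, 3]  # corners eroded

    def test_random_masks_match_direct_median(self, rng):
        for _ in range(3):
            img = (rng.random((2, 20, 20)) * 255).astype(np.uint8)
            masks = m.binarize_and_denoise(img, threshold=127, kernel=3).masks
            for t in range(2):
                assert np.array_equal(masks[t], brute_force_median(img[t] > 127, 3))

    def test_kernel_one_is_identity(self, rng):
        img = (rng.random((3, 12, 12)) * 255).astype(np.uint8)
        masks = m.binarize_and_denoise(img, threshold=127, kernel=1).masks
        assert np.array_equal(masks, img > 127)

    @pytest.mark.parametrize("kernel", [0, 2, 4, -1])
    def test_even_or_nonpositive_kernel_rejected(self, kernel):
        with pytest.raises(ValueError, match="odd"):
            m.binarize_and_denoise(np.zeros((2, 4, 4), np.uint8), 0, kernel)


class TestIoUPair:
    def test_identity_is_one(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        assert m.iou_pair(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert m.iou_pair(a, b) == 0.0

    def test_shifted_square_hand_count(self):
        """2x2 square vs itself shifted one pixel: 2 / 6 = 1/3."""
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[2:4, 2:4] = True
        b[2:4, 3:5] = True
        assert m.iou_pair(a, b) == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(10):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            assert m.iou_pair(a, b) == pytest.approx(brute_force_iou(a, b), abs=0)

    def test_empty_mask_conventions(self):
        empty = np.zeros((5, 5), bool)
        full = np.ones((5, 5), bool)
        with pytest.warns(UserWarning):
            assert m.iou_pair(empty, empty) == 1.0
        with pytest.warns(UserWarning):
            assert m.iou_pair(empty, full) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            m.iou_pair(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((12, 12)) > 0.5
        b = r.random((12, 12)) > 0.5
        v = m.iou_pair(a, b)
        assert 0.0 <= v <= 1.0
        assert v == m.iou_pair(b, a)

    def test_translation_never_increases_iou(self):
        """Shifting a disc further away can only shrink the overlap."""
        yy, xx = np.mgrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 15) ** 2 <= 25
        prev = 1.0
        for shift in range(0, 11):
            v = m.iou_pair(disc, np.roll(disc, shift, axis=1))
            assert v <= prev + 1e-12
            prev = v


class TestDisplacementSeries:
    def test_static_movie_all_zero(self):
        mask = np.zeros((5, 8, 8), bool)
        mask[:, 2:5, 2:5] = True
        res = m.displacement_series(mask)
        assert np.allclose(res.displacement_ratio, 0.0)
        assert res.mean_ratio == 0.0

    def test_alternating_disjoint_all_one(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2, :2] = True
        b[5:, 5:] = True
        masks = np.stack([a, b, a, b])
        res = m.displacement_series(masks)
        assert np.allclose(res.displacement_ratio, 1.0)

    def test_lengths_and_complement(self, rng):
        masks = rng.random((7, 10, 10)) > 0.5
        res = m.displacement_series(masks)
        assert len(res.iou) == 6
        assert np.allclose(res.displacement_ratio, 1.0 - res.iou)
        assert ((res.iou >= 0) & (res.iou <= 1)).all()

    def test_pipeline_direction_arrested_below_motile(self, small_cohort_config):
        """Arrested cells produce a lower displacement-area ratio."""
        ratios = {}
        for regime in ("motile", "arrested"):
            cfg = small_cohort_config(regime, seed=42, n_frames=15)
            truth = m.simulate_tracks(cfg)
            movie = m.render_movie(truth, cfg)
            seq = MIPSequence(movie.mip("green"), cfg.voxel_size[0], cfg.frame_interval)
            res, _ = m.displacement_pipeline(seq)
            ratios[regime] = res.mean_ratio
        assert ratios["arrested"] < ratios["motile"]
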
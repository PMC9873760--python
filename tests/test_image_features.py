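import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from artvalue.features import (
    compute_blur,
    compute_global_features,
    compute_segment_features,
    intensity_bin_fractions,
    intensity_entropy,
)
from artvalue.raster import RasterImage
from artvalue.segmentation import Segmentation, segment_srm


def whole_image_segmentation(h, w):
    return Segmentation(np.zeros((h, w), dtype=int), "srm")


class TestBlur:
    def test_uniform_image_scores_zero(self):
        img = RasterImage(np.full((32, 32, 3), 0.5))
        assert compute_blur(img) == 0.0

    def test_nyquist_stripes_score_near_one(self):
        px = np.zeros((32, 32, 3))
        px[:, ::2] = 1.0  # alternating columns: energy at the x Nyquist
        assert compute_blur(RasterImage(px)) >= 0.99

    def test_nonincreasing_under_gaussian_smoothing(self):
        # periodic smoothing: the discrete spectrum is attenuated exactly
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, (48, 48, 3))
        scores = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            sm = (
                gaussian_filter(base, sigma=(sigma, sigma, 0), mode="wrap")
                if sigma else base
            )
            scores.append(compute_blur(RasterImage(np.clip(sm, 0, 1))))
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[0] > scores[-1]

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(4)
        px = rng.uniform(0.1, 0.5, (32, 32, 3))
        a = compute_blur(RasterImage(px))
        b = compute_blur(RasterImage(px + 0.3))
        assert a == pytest.approx(b, abs=1e-12)


class TestSegmentFeatures:
    def test_whole_image_segment_size_is_one(self, noise_image):
        seg = whole_image_segmentation(48, 48)
        f = compute_segment_features(noise_image, seg, 0)
        assert f["segment_size"] == 1.0

    def test_solid_centered_square_moments(self):
        px = np.full((32, 32, 3), 0.2)
        px[8:24, 8:24] = 0.9
        img = RasterImage(px)
        seg = segment_srm(img, min_segments=2)
        # the centered square is the smaller segment
        sq = 1 if seg.areas()[1] == 256 else 0
        f = compute_segment_features(img, seg, sq, normalize_coords=False)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["skew"] == pytest.approx(0.0, abs=1e-9)
        assert f["com_x"] == pytest.approx(15.5)
        assert f["com_y"] == pytest.approx(15.5)

    def test_mirror_symmetric_crop_has_zero_horizontal_mse(self):
        px = np.full((32, 32, 3), 0.1)
        px[10:20, 8:24] = 0.8  # left-right symmetric, top-bottom asymmetric
        img = RasterImage(px)
        seg = segment_srm(img, min_segments=2)
        f = compute_segment_features(img, seg, 0)
        assert f["h_symmetry"] == pytest.approx(0.0)
        assert f["v_symmetry"] > 0.0

    def test_absent_segment_yields_nan_sentinel(self):
        img = RasterImage(np.full((16, 16, 3), 0.5))
        seg = whole_image_segmentation(16, 16)
        f = compute_segment_features(img, seg, 1)
        assert all(np.isnan(v) for v in f.values())

    def test_segment_sizes_sum_to_one(self, banded_image):
        seg = segment_srm(banded_image)
        sizes = [
            compute_segment_features(banded_image, seg, i)["segment_size"]
            for i in range(2)
        ]
        remaining = seg.areas()[2:].sum() / (64 * 64)
        assert sum(sizes) + remaining == pytest.approx(1.0, abs=1e-9)

    def test_com_within_bounding_box_and_variance_nonneg(self, banded_image):
        seg = segment_srm(banded_image)
        f = compute_segment_features(banded_image, seg, 1, normalize_coords=False)
        ys, xs = np.nonzero(seg.segment_mask(1))
        assert xs.min() <= f["com_x"] <= xs.max()
        assert ys.min() <= f["com_y"] <= ys.max()
        assert f["variance"] >= 0


class TestGlobalFeatures:
    def test_all_black_image_fills_first_intensity_bin(self):
        img = RasterImage(np.zeros((16, 16, 3)))
        g = compute_global_features(img)
        assert g["intensity_bin_1"] == 1.0
        assert all(g[f"intensity_bin_{i}"] == 0.0 for i in range(2, 6))

    def test_aspect_ratio_is_width_over_height(self):
        img = RasterImage(np.full((200, 300, 3), 0.5))
        assert compute_global_features(img)["aspect_ratio"] == pytest.approx(1.5)

    def test_mode_hue_tracks_dominant_value(self):
        rng = np.random.default_rng(0)
        hsv_dominant = np.full((40, 40, 3), 0.5)
        px = np.zeros((40, 40, 3))
        # 90% of pixels cyan (hue 0.5), rest random
        import skimage.color as skc

        px[:] = skc.hsv2rgb(np.broadcast_to([0.5, 1.0, 1.0], (40, 40, 3)))
        mask = rng.random((40, 40)) < 0.1
        px[mask] = rng.uniform(0, 1, (int(mask.sum()), 3))
        g = compute_global_features(RasterImage(np.clip(px, 0, 1)))
        assert abs(g["global_mode_hue"] - 0.5) < 1.0 / 64

    def test_flip_invariance_of_histogram_features(self, noise_image):
        g1 = compute_global_features(noise_image)
        g2 = compute_global_features(RasterImage(noise_image.pixels[:, ::-1]))
        for key in ["global_entropy", "aspect_ratio", "global_mode_hue"] + [
            f"intensity_bin_{i}" for i in range(1, 6)
        ]:
            assert g1[key] == pytest.approx(g2[key], abs=1e-12)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_entropy_bounds_and_bin_fractions(seed):
    rng = np.random.default_rng(seed)
    px = rng.uniform(0, 1, (16, 16, 3))
    img = RasterImage(px)
    ent = intensity_entropy(img.grayscale_255(), n_bins=256)
    assert 0.0 <= ent <= np.log2(256)
    fr = intensity_bin_fractions(img)
    assert (fr >= 0).all()
    assert fr.sum() == pytest.approx(1.0, abs=1e-9)


def test_entropy_zero_iff_single_bin():
    assert intensity_entropy(np.full(100, 42.0)) == 0.0
    assert intensity_entropy(np.array([10.0, 200.0])) > 0.0
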
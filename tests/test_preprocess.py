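"""Denoising, Otsu thresholding, hole filling and labelling."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from grainmorph.calibration import CalibratedImage
from grainmorph.preprocess import (
    LabelMap,
    ParticleMask,
    area_filter,
    binarize,
    fill_holes,
    gaussian_denoise,
    label_components,
    otsu_threshold,
)


def _img(arr, scale=1.0):
    return CalibratedImage(np.asarray(arr), scale)


def exhaustive_otsu(pixels: np.ndarray) -> int:
    """Independent oracle: scan all 256 split points for max between-class
    variance, smallest threshold on ties."""
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            v = 0.0
        else:
            mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / hist[: t + 1].sum()
            mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / hist[t + 1 :].sum()
            v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent oracle: count 8-connected components by stack flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    H, W = mask.shape
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


class TestGaussianDenoise:
    def test_constant_image_unchanged(self):
        img = _img(np.full((12, 12), 77, dtype=np.uint8))
        assert (gaussian_denoise(img, 2.5).pixels == 77).all()

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = _img(rng.integers(0, 256, (9, 9), dtype=np.uint8))
        out = gaussian_denoise(img, 0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_matches_dense_convolution_oracle(self):
        # single bright pixel, float image: compare against direct spatial
        # convolution with the sampled, normalized kernel
        sigma = 1.0
        px = np.zeros((21, 21))
        px[10, 10] = 1.0
        out = gaussian_denoise(_img(px), sigma)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = convolve2d(px, kernel, mode="same", boundary="symm")
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_denoise(_img(np.zeros((4, 4), dtype=np.uint8)), -1.0)


class TestOtsu:
    def test_bimodal_separates_classes(self):
        rng = np.random.default_rng(1)
        px = rng.choice([0, 255], size=(20, 20), p=[0.7, 0.3]).astype(np.uint8)
        t = otsu_threshold(_img(px))
        assert 0 <= t < 255
        mask = binarize(_img(px), t)
        assert mask.mask.sum() == (px == 255).sum()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(_img(np.full((5, 5), 9, dtype=np.uint8)))

    def test_matches_exhaustive_scan_on_random_images(self):
        rng = np.random.default_rng(7)
        for i in range(50):
            if i % 2:
                px = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            else:  # bimodal mixture, closer to real micrographs
                a = rng.normal(70, 12, size=(16, 16))
                b = rng.normal(190, 15, size=(16, 16))
                pick = rng.random((16, 16)) < 0.4
                px = np.clip(np.where(pick, a, b), 0, 255).astype(np.uint8)
            assert otsu_threshold(_img(px)) == exhaustive_otsu(px)

    def test_agrees_with_skimage_on_8bit(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        px = np.clip(
            np.concatenate(
                [rng.normal(60, 10, 200), rng.normal(200, 12, 120)]
            ).reshape(16, 20),
            0,
            255,
        ).astype(np.uint8)
        t = otsu_threshold(_img(px))
        t_ref = threshold_otsu(px)
        # same foreground under both conventions
        assert ((px > t) == (px > t_ref)).all() or abs(t - t_ref) <= 1


class TestBinarize:
    def test_everything_below_threshold_gives_empty_mask(self):
        px = np.arange(25, dtype=np.uint8).reshape(5, 5)
        assert binarize(_img(px), 30).mask.sum() == 0

    def test_foreground_count_equals_histogram_tail(self):
        rng = np.random.default_rng(11)
        px = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        t = 140
        hist = np.bincount(px.ravel(), minlength=256)
        assert binarize(_img(px), t).mask.sum() == hist[t + 1 :].sum()


def _annulus(outer=20, inner=5, pad=4):
    n = 2 * (outer + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    r = np.hypot(yy - n // 2, xx - n // 2)
    return ParticleMask((r <= outer) & (r > inner), 1.0)


class TestFillHoles:
    def test_no_holes_is_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:8] = True
        out = fill_holes(ParticleMask(mask, 1.0), 3.0)
        np.testing.assert_array_equal(out.mask, mask)

    def test_tau_zero_fills_everything(self):
        pm = _annulus()
        out = fill_holes(pm, 0.0)
        # classical hole fill: the interior disc is foreground now
        n = pm.mask.shape[0]
        assert out.mask[n // 2, n // 2]
        assert out.mask.sum() > pm.mask.sum()

    def test_annulus_depth_rule(self):
        # hole-to-outer-boundary distance ~ outer - inner = 15
        pm = _annulus(outer=20, inner=5)
        n = pm.mask.shape[0]
        filled = fill_holes(pm, 10.0)
        assert filled.mask[n // 2, n // 2], "deep hole should be filled at tau=10"
        kept = fill_holes(pm, 20.0)
        assert not kept.mask[n // 2, n // 2], "hole preserved at tau=20"

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(5)
        blob = rng.random((40, 40)) > 0.35
        pm = ParticleMask(blob, 1.0)
        once = fill_holes(pm, 2.0)
        twice = fill_holes(once, 2.0)
        assert (once.mask | pm.mask).sum() == once.mask.sum()  # superset
        np.testing.assert_array_equal(once.mask, twice.mask)


class TestLabelComponents:
    def test_empty_mask(self):
        lm = label_components(ParticleMask(np.zeros((5, 5), dtype=bool), 1.0))
        assert lm.count == 0

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(ParticleMask(mask, 1.0)).count == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(9)
        mask = rng.random((30, 30)) < 0.25
        lm = label_components(ParticleMask(mask, 1.0))
        assert lm.count == flood_fill_count(mask)


def _areas_fixture(areas):
    """One horizontal run of each requested area, on separate rows."""
    mask = np.zeros((2 * len(areas) + 2, max(areas) + 4), dtype=bool)
    for i, a in enumerate(areas):
        mask[2 * i + 1, 2 : 2 + a] = True
    return label_components(ParticleMask(mask, 1.0))


class TestAreaFilter:
    def test_default_drops_up_to_three_pixels(self):
        lm = area_filter(_areas_fixture([1, 2, 3]))
        assert lm.count == 0

    def test_min_area_one_is_identity(self):
        lm0 = _areas_fixture([1, 2, 3, 4])
        lm = area_filter(lm0, 1)
        assert lm.count == lm0.count
        np.testing.assert_array_equal(lm.labels, lm0.labels)

    def test_survivors_of_one_to_ten(self):
        lm = area_filter(_areas_fixture(list(range(1, 11))), 4)
        assert lm.count == 7
        areas = np.bincount(lm.labels.ravel())[1:]
        assert areas.min() == 4
        # consecutive labels in raster order of first occurrence
        assert sorted(areas) == list(range(4, 11))
        assert list(areas) == list(range(4, 11))  # rows ordered by area here

    def test_never_increases_count(self):
        rng = np.random.default_rng(2)
        mask = rng.random((40, 40)) < 0.3
        lm = label_components(ParticleMask(mask, 1.0))
        for ma in (1, 2, 5, 10):
            assert area_filter(lm, ma).count <= lm.count


def test_otsu_binarize_nonempty_both_classes():
    rng = np.random.default_rng(21)
    for _ in range(10):
        px = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        if np.all(px == px.flat[0]):
            continue
        img = _img(px)
        mask = binarize(img, otsu_threshold(img)).mask
        assert 0 < mask.sum() < mask.size
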
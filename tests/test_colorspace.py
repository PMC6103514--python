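"""Color conversions, quantization, Otsu thresholding and binarization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyn.colorspace import (
    ChannelImage,
    Threshold,
    binarize,
    extract_channel,
    otsu_threshold,
    quantize_channel,
    rgb_to_hsi,
    rgb_to_lab,
)
from conftest import otsu_brute


def _srgb_lab_by_hand(r, g, b):
    """Reference sRGB (D65) -> CIELAB conversion, written out step by step."""
    def lin(c):
        c = c / 255.0
        return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4

    rl, gl, bl = lin(r), lin(g), lin(b)
    x = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > 0.008856 else 7.787 * t + 16 / 116

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


class TestRgbToLab:
    @pytest.mark.parametrize(
        "rgb, l_expect",
        [((255, 255, 255), 100.0), ((0, 0, 0), 0.0)],
    )
    def test_extremes(self, rgb, l_expect):
        lab = rgb_to_lab(np.array([[rgb]], dtype=np.uint8))
        assert lab[0, 0, 0] == pytest.approx(l_expect, abs=1e-3)
        assert abs(lab[0, 0, 1]) < 0.5 and abs(lab[0, 0, 2]) < 0.5

    def test_mid_gray_matches_hand_conversion(self):
        lab = rgb_to_lab(np.array([[[119, 119, 119]]], dtype=np.uint8))
        l_ref, a_ref, b_ref = _srgb_lab_by_hand(119, 119, 119)
        assert lab[0, 0, 0] == pytest.approx(l_ref, abs=0.05)
        assert abs(lab[0, 0, 1]) < 0.01 and abs(lab[0, 0, 2]) < 0.01

    def test_random_pixels_match_hand_conversion(self, rng):
        px = rng.integers(0, 256, size=(12, 3))
        lab = rgb_to_lab(px.reshape(1, 12, 3).astype(np.uint8))[0]
        for i, (r, g, b) in enumerate(px):
            ref = _srgb_lab_by_hand(int(r), int(g), int(b))
            assert np.allclose(lab[i], ref, atol=0.15)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((0, 4, 3), dtype=np.uint8))

    def test_pixelwise(self, rng):
        img = rng.integers(0, 256, size=(6, 7, 3)).astype(np.uint8)
        perm = rng.permutation(42)
        flat = img.reshape(-1, 3)[perm].reshape(6, 7, 3)
        assert np.allclose(
            rgb_to_lab(img).reshape(-1, 3)[perm], rgb_to_lab(flat).reshape(-1, 3)
        )


class TestRgbToHsi:
    @pytest.mark.parametrize(
        "rgb, expect",
        [
            ((100, 100, 100), (0.0, 0.0, 100 / 255)),   # achromatic: H=0 by convention
            ((255, 0, 0), (0.0, 1.0, 1 / 3)),
            ((0, 255, 0), (1 / 3, 1.0, 1 / 3)),          # arccos formula by hand
        ],
    )
    def test_known_pixels(self, rgb, expect):
        hsi = rgb_to_hsi(np.array([[rgb]], dtype=np.uint8))[0, 0]
        assert hsi == pytest.approx(expect, abs=1e-9)

    def test_ranges(self, rng):
        img = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
        hsi = rgb_to_hsi(img)
        assert hsi[..., 0].min() >= 0 and hsi[..., 0].max() < 1
        assert hsi[..., 1].min() >= -1e-12 and hsi[..., 1].max() <= 1 + 1e-12
        assert hsi[..., 2].min() >= 0 and hsi[..., 2].max() <= 1


class TestQuantize:
    @pytest.mark.parametrize(
        "channel, value, expect",
        [
            ("L", 100.0, 255), ("L", 0.0, 0), ("L", 50.0, 128),
            ("b", 127.0, 255), ("b", -128.0, 0),
        ],
    )
    def test_affine_map(self, channel, value, expect):
        q = quantize_channel(ChannelImage(np.full((1, 1), value), channel))
        assert q.values[0, 0] == expect
        assert q.quantized

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            ChannelImage(np.zeros((2, 2)), "Q")

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.floats(0, 100, allow_nan=False),
        x2=st.floats(0, 100, allow_nan=False),
    )
    def test_monotone(self, x1, x2):
        lo, hi = sorted((x1, x2))
        q = quantize_channel(ChannelImage(np.array([[lo, hi]]), "L"))
        assert q.values[0, 0] <= q.values[0, 1]


class TestOtsu:
    def test_bimodal_split(self):
        v = np.array([[10] * 8 + [200] * 8], dtype=np.uint8)
        t = otsu_threshold(ChannelImage(v, "I", quantized=True))
        assert 10 <= t.value < 200

    def test_four_pixel_case(self):
        v = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        t = otsu_threshold(ChannelImage(v, "L", quantized=True))
        mask = binarize(ChannelImage(v, "L", quantized=True), t, "high")
        assert mask.sum() == 2 and mask[1].all() and not mask[0].any()

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            v = rng.integers(0, 256, size=(24, 18)).astype(np.uint8)
            t = otsu_threshold(ChannelImage(v, "R", quantized=True))
            assert t.value == otsu_brute(v)

    def test_matches_skimage(self, rng):
        from skimage.filters import threshold_otsu

        v = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        t = otsu_threshold(ChannelImage(v, "R", quantized=True))
        # skimage returns the low-class maximum on integer data
        assert abs(int(threshold_otsu(v, nbins=256)) - t.value) <= 1

    def test_constant_image_rejected(self):
        v = np.full((5, 5), 77, dtype=np.uint8)
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(ChannelImage(v, "L", quantized=True))


class TestBinarize:
    def test_all_above_gives_full_mask(self):
        ch = ChannelImage(np.full((3, 3), 200, dtype=np.uint8), "L", quantized=True)
        assert binarize(ch, Threshold(100, "L"), "high").all()

    def test_t255_high_is_empty(self):
        ch = ChannelImage(np.full((3, 3), 255, dtype=np.uint8), "L", quantized=True)
        assert not binarize(ch, Threshold(255, "L"), "high").any()

    def test_checkerboard(self):
        v = np.indices((6, 6)).sum(axis=0) % 2 * 255
        ch = ChannelImage(v.astype(np.uint8), "b", quantized=True)
        mask = binarize(ch, Threshold(128, "b"), "high")
        assert np.array_equal(mask, v == 255)

    def test_polarities_partition_with_ties_low(self, rng):
        v = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        ch = ChannelImage(v, "a", quantized=True)
        t = Threshold(int(v[3, 3]), "a")  # guarantee exact-t pixels exist
        hi = binarize(ch, t, "high")
        lo = binarize(ch, t, "low")
        assert not (hi & lo).any()
        assert (hi | lo).all()
        assert lo[v == t.value].all()

    def test_scale_mismatch_rejected(self):
        ch = ChannelImage(np.zeros((2, 2), dtype=np.uint8), "L", quantized=True)
        with pytest.raises(ValueError, match="mismatch"):
            binarize(ch, Threshold(10, "b"), "high")
        with pytest.raises(ValueError, match="quantized"):
            binarize(ChannelImage(np.zeros((2, 2)), "L"), Threshold(10, "L"), "high")


def test_extract_channel_tags(rng):
    img = rng.integers(0, 256, size=(5, 5, 3)).astype(np.uint8)
    assert np.allclose(extract_channel(img, "G").values, img[..., 1])
    assert np.allclose(extract_channel(img, "b").values, rgb_to_lab(img)[..., 2])
    assert np.allclose(extract_channel(img, "I").values, rgb_to_hsi(img)[..., 2])
    with pytest.raises(ValueError):
        extract_channel(img, "X")
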
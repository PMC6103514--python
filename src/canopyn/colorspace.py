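"""Color-space primitives for canopy image analysis.

Everything downstream (the segmentation cascade, the feature extractor) is
built from four operations defined here: conversion of 8-bit sRGB images to
CIELAB and HSI, affine quantization of a scalar channel to the 8-bit scale,
Otsu thresholding on the 256-bin histogram, and binarization against a
threshold with a configurable foreground polarity.

Conventions
-----------
* RGB images are ``(h, w, 3)`` integer arrays with components in [0, 255].
* CIELAB uses the sRGB companding / D65 white point of CIE 1976 L*a*b*
  (the standard consumer-camera assumption); L in [0, 100], a and b in
  [-128, 127] for 8-bit inputs.
* HSI follows the Gonzalez–Woods arccos formulation with hue normalized to
  [0, 1); achromatic pixels take H = 0 by convention.  S in [0, 1],
  I = (R+G+B)/(3*255) in [0, 1].
* Otsu operates only on quantized (uint8) channels and breaks ties toward
  the smallest maximizing threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "CHANNEL_RANGES",
    "ChannelImage",
    "Threshold",
    "rgb_to_lab",
    "rgb_to_hsi",
    "extract_channel",
    "quantize_channel",
    "otsu_threshold",
    "binarize",
]

#: Native value range of every channel tag the package knows about.
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "R": (0.0, 255.0),
    "G": (0.0, 255.0),
    "B": (0.0, 255.0),
    "H": (0.0, 1.0),
    "S": (0.0, 1.0),
    "I": (0.0, 1.0),
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}

#: Which color space each channel tag belongs to.
CHANNEL_SPACE = {
    "R": "rgb", "G": "rgb", "B": "rgb",
    "H": "hsi", "S": "hsi", "I": "hsi",
    "L": "lab", "a": "lab", "b": "lab",
}


@dataclass
class ChannelImage:
    """A single scalar channel extracted from an image.

    ``values`` is an ``(h, w)`` array on the channel's native scale, or
    uint8 in [0, 255] when ``quantized`` is True.
    """

    values: np.ndarray
    channel: str
    quantized: bool = False

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_RANGES:
            raise ValueError(f"unknown channel tag {self.channel!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("channel image must be a nonempty 2-D array")


@dataclass(frozen=True)
class Threshold:
    """An Otsu threshold on the 8-bit quantized scale of one channel."""

    value: int
    channel: str

    def __post_init__(self) -> None:
        if not (0 <= self.value <= 255):
            raise ValueError("threshold must lie in [0, 255]")

    def native(self) -> float:
        """The threshold mapped back to the channel's native scale."""
        lo, hi = CHANNEL_RANGES[self.channel]
        return lo + self.value / 255.0 * (hi - lo)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB array, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("empty image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("RGB components must lie in [0, 255]")
    return img.astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIELAB (D65).

    Returns an ``(h, w, 3)`` float array with planes (L, a, b).
    """
    img = _check_rgb(img)
    return _skcolor.rgb2lab(img)


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSI.

    H is the arccos hue normalized to [0, 1) (0 for achromatic pixels),
    S = 1 - 3*min(R,G,B)/(R+G+B) (0 for black), I = (R+G+B)/(3*255).
    """
    img = _check_rgb(img).astype(np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    total = r + g + b

    i = total / (3.0 * 255.0)

    s = np.zeros_like(total)
    nz = total > 0
    s[nz] = 1.0 - 3.0 * np.minimum(np.minimum(r, g), b)[nz] / total[nz]

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    h = np.zeros_like(total)
    chroma = den > 1e-12
    theta = np.arccos(np.clip(num[chroma] / den[chroma], -1.0, 1.0))
    hh = np.where(b[chroma] <= g[chroma], theta, 2.0 * np.pi - theta)
    h[chroma] = (hh / (2.0 * np.pi)) % 1.0
    return np.stack([h, s, i], axis=-1)


def extract_channel(img: np.ndarray, channel: str) -> ChannelImage:
    """Extract a named channel from an 8-bit RGB image, converting as needed."""
    if channel not in CHANNEL_SPACE:
        raise ValueError(f"unknown channel tag {channel!r}")
    space = CHANNEL_SPACE[channel]
    if space == "rgb":
        arr = _check_rgb(img).astype(np.float64)
        idx = "RGB".index(channel)
    elif space == "hsi":
        arr = rgb_to_hsi(img)
        idx = "HSI".index(channel)
    else:
        arr = rgb_to_lab(img)
        idx = "Lab".index(channel)
    return ChannelImage(arr[..., idx], channel)


def quantize_channel(ch: ChannelImage) -> ChannelImage:
    """Affinely map a channel from its native range onto uint8 [0, 255].

    Half-integers round up (L = 50 maps to 128).  The mapping is recorded
    through the channel tag, so a quantized threshold can be read back on
    the native scale via :meth:`Threshold.native`.
    """
    if ch.quantized:
        return ch
    lo, hi = CHANNEL_RANGES[ch.channel]
    scaled = (np.asarray(ch.values, dtype=np.float64) - lo) / (hi - lo) * 255.0
    q = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return ChannelImage(q, ch.channel, quantized=True)


def otsu_threshold(ch: ChannelImage) -> Threshold:
    """Otsu's threshold over the 256-bin histogram of a quantized channel.

    Maximizes the between-class variance over all candidate thresholds t
    (low class: value <= t; high class: value > t).  Ties are broken by the
    smallest maximizing t.  A constant channel has no valid split and raises
    ``ValueError``.
    """
    if not ch.quantized:
        ch = quantize_channel(ch)
    v = ch.values.ravel()
    hist = np.bincount(v, minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # weight of the low class at t
    mu = np.cumsum(p * np.arange(256))        # first moment of the low class
    mu_total = mu[-1]
    valid = (omega > 0) & (omega < 1)
    if not valid.any():
        raise ValueError(
            f"channel {ch.channel!r} is constant: Otsu has no valid split"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~valid] = -np.inf
    best = sigma_b.max()
    t = int(np.flatnonzero(sigma_b == best)[0])
    return Threshold(t, ch.channel)


def binarize(ch: ChannelImage, t: Threshold, polarity: str = "high") -> np.ndarray:
    """Threshold a quantized channel into a boolean foreground mask.

    ``polarity="high"``: foreground is strictly above t.  ``polarity="low"``:
    foreground is at or below t (pixels exactly at t belong to the low
    class), so the two polarities partition the image.
    """
    if polarity not in ("high", "low"):
        raise ValueError("polarity must be 'high' or 'low'")
    if not ch.quantized:
        raise ValueError(
            "binarize requires a quantized channel; thresholds live on the "
            "8-bit scale"
        )
    if ch.channel != t.channel:
        raise ValueError(
            f"scale mismatch: channel {ch.channel!r} vs threshold on "
            f"{t.channel!r}"
        )
    if polarity == "high":
        return ch.values > t.value
    return ch.values <= t.value
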
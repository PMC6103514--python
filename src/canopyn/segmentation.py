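"""Five-step segmentation cascade for a plant in a complex field background.

The target sapling is separated from soil, weeds and other plants using two
CIELAB channels with complementary roles: the blue–yellow opponent channel b
splits green vegetation from soil, and the lightness channel L splits the
(brighter) target plant from darker neighbouring vegetation.

The cascade:

1. convert the RGB image to Lab and extract the b and L channels;
2. Otsu-threshold both quantized channels, recording thresholds ``T_b`` and
   ``T_L`` and binary masks ``I_b`` and ``I_L``;
3. 7x7 median (majority) filter on ``I_b``, then mask the original image
   with the result -> ``I_b1``;
4. convert ``I_b1`` back to Lab, extract L, and binarize with the ORIGINAL
   ``T_L`` -> ``I_b2`` (pixels zeroed in step 3 can never return);
5. 7x7 median filter, then erode twice and dilate twice with a radius-5
   disk, then mask the original image -> final result ``I_b3``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colorspace import (
    ChannelImage,
    Threshold,
    binarize,
    extract_channel,
    otsu_threshold,
    quantize_channel,
    rgb_to_lab,
)

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "SegmentationError",
    "median_filter",
    "morphological_clean",
    "disk_element",
    "apply_mask",
    "segment",
]


class SegmentationError(RuntimeError):
    """A cascade step failed; the message names the step."""


@dataclass
class SegmentationConfig:
    """Tunables of the cascade.

    The two polarity flags choose which Otsu class counts as plant; the
    defaults (both "high") encode that vegetation is yellow-shifted in b
    relative to soil and that the target plant is brighter in L than the
    distractor plants it must be separated from.
    """

    b_polarity: str = "high"
    l_polarity: str = "high"
    median_size: int = 7
    morph_radius: int = 5
    morph_passes: int = 2


@dataclass
class SegmentationResult:
    """Final mask plus every intermediate artifact of the cascade."""

    mask: np.ndarray          # final boolean mask
    image: np.ndarray         # I_b3: original with background zeroed
    i_b: np.ndarray           # step-2 b-channel mask
    i_l: np.ndarray           # step-2 L-channel mask
    i_b1: np.ndarray          # step-3 masked RGB image
    i_b1_mask: np.ndarray     # the mask that produced i_b1
    i_b2: np.ndarray          # step-4 mask
    t_b: Threshold
    t_l: Threshold


def median_filter(mask: np.ndarray, size: int) -> np.ndarray:
    """Majority filter on a binary mask over a ``size x size`` window.

    Borders are handled by edge replication.  A pixel becomes foreground iff
    strictly more than half of its window is foreground, so an exact tie
    (possible only for even window areas) resolves to background.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("median filter size must be odd and >= 1")
    mask = np.asarray(mask).astype(bool)
    counts = ndimage.correlate(
        mask.astype(np.int32), np.ones((size, size), dtype=np.int32),
        mode="nearest",
    )
    return counts * 2 > size * size


def disk_element(radius: int) -> np.ndarray:
    """Disk structuring element: (dx, dy) included iff dx^2 + dy^2 <= r^2."""
    y, x = np.ogrid[-radius: radius + 1, -radius: radius + 1]
    return (x * x + y * y) <= radius * radius


def morphological_clean(
    mask: np.ndarray, radius: int = 5, passes: int = 2
) -> np.ndarray:
    """Erode ``passes`` times then dilate ``passes`` times with a disk.

    Out-of-image pixels count as background for erosion; dilation clips to
    the frame.  With the defaults this removes structures thinner than the
    radius-5 disk while approximately restoring larger blobs.
    """
    mask = np.asarray(mask).astype(bool)
    selem = disk_element(radius)
    out = mask
    for _ in range(passes):
        out = ndimage.binary_erosion(out, structure=selem, border_value=0)
    for _ in range(passes):
        out = ndimage.binary_dilation(out, structure=selem, border_value=0)
    return out


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero all background pixels of an RGB image ("multiply by the mask")."""
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    return np.where(mask[..., None], img, 0).astype(img.dtype)


def segment(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full five-step cascade on an 8-bit RGB image."""
    cfg = cfg or SegmentationConfig()
    img = np.asarray(img)

    # Step 1: Lab conversion, b and L channels.
    lab = rgb_to_lab(img)
    ch_b = quantize_channel(ChannelImage(lab[..., 2], "b"))
    ch_l = quantize_channel(ChannelImage(lab[..., 0], "L"))

    # Step 2: Otsu on both channels.
    try:
        t_b = otsu_threshold(ch_b)
    except ValueError as e:
        raise SegmentationError(f"step 2 (Otsu on b channel): {e}") from e
    try:
        t_l = otsu_threshold(ch_l)
    except ValueError as e:
        raise SegmentationError(f"step 2 (Otsu on L channel): {e}") from e
    i_b = binarize(ch_b, t_b, cfg.b_polarity)
    i_l = binarize(ch_l, t_l, cfg.l_polarity)

    # Step 3: median filter I_b, mask the original image.
    m1 = median_filter(i_b, cfg.median_size)
    i_b1 = apply_mask(img, m1)

    # Step 4: L channel of the masked image against the ORIGINAL T_L.
    lab1 = rgb_to_lab(i_b1)
    ch_l1 = quantize_channel(ChannelImage(lab1[..., 0], "L"))
    i_b2 = binarize(ch_l1, t_l, cfg.l_polarity)
    # Pixels zeroed in step 3 are background no matter what the threshold
    # says about L = 0 (relevant for "low" polarity).
    i_b2 &= m1

    # Step 5: median filter, morphology, final masking.
    m2 = median_filter(i_b2, cfg.median_size)
    final = morphological_clean(m2, cfg.morph_radius, cfg.morph_passes)
    i_b3 = apply_mask(img, final)

    return SegmentationResult(
        mask=final, image=i_b3, i_b=i_b, i_l=i_l, i_b1=i_b1, i_b1_mask=m1,
        i_b2=i_b2, t_b=t_b, t_l=t_l,
    )
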
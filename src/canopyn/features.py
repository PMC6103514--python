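"""Per-sample feature extraction: channel means, correlation screening,
and the normalizing ranges used by the exponential model family.

Each photographed tree yields one :class:`SampleRecord`: the mean of every
color channel over the segmented foreground (on the channel's native scale,
not the 8-bit quantized scale used inside Otsu), the two growth-status
ratios, and — when available — the laboratory-measured total nitrogen of
its leaves.  Total nitrogen is treated as unit-agnostic throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

from .colorspace import rgb_to_hsi, rgb_to_lab

__all__ = [
    "CHANNEL_COLUMNS",
    "COLOR_SYSTEMS",
    "PREDICTOR_COLUMNS",
    "SampleRecord",
    "channel_means",
    "records_frame",
    "pearson_screen",
    "compute_normalizers",
]

#: Feature-table columns holding the nine channel means, in fixed order.
CHANNEL_COLUMNS = [
    "mean_R", "mean_G", "mean_B",
    "mean_H", "mean_S", "mean_I",
    "mean_L", "mean_a", "mean_b",
]

#: The four candidate color systems and their ordered channel columns.
#: "RLI" mixes the three strongest single-channel nitrogen correlates:
#: R from RGB, L from Lab, I from HSI.
COLOR_SYSTEMS: dict[str, tuple[str, str, str]] = {
    "RGB": ("mean_R", "mean_G", "mean_B"),
    "HSI": ("mean_H", "mean_S", "mean_I"),
    "Lab": ("mean_L", "mean_a", "mean_b"),
    "RLI": ("mean_R", "mean_L", "mean_I"),
}

#: The 11 candidate predictors screened against total nitrogen.
PREDICTOR_COLUMNS = CHANNEL_COLUMNS + ["gs_mer", "gs_mcc"]


@dataclass
class SampleRecord:
    """Image-derived features (and optional measured nitrogen) for one tree."""

    sample_id: str
    mean_R: float = np.nan
    mean_G: float = np.nan
    mean_B: float = np.nan
    mean_H: float = np.nan
    mean_S: float = np.nan
    mean_I: float = np.nan
    mean_L: float = np.nan
    mean_a: float = np.nan
    mean_b: float = np.nan
    gs_mer: float | None = None
    gs_mcc: float | None = None
    total_N: float | None = None


def channel_means(img: np.ndarray, mask: np.ndarray, sample_id: str = "") -> SampleRecord:
    """Mean of all nine channels over the foreground pixels of ``mask``.

    ``img`` is the 8-bit RGB image (masked or original — only foreground
    pixels are read, so altering background pixels never changes the
    output).
    """
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    if not mask.any():
        raise ValueError("mask has no foreground pixels")

    rgb = img[mask].astype(np.float64)              # (n, 3)
    hsi = rgb_to_hsi(img)[mask]
    lab = rgb_to_lab(img)[mask]
    return SampleRecord(
        sample_id=sample_id,
        mean_R=rgb[:, 0].mean(), mean_G=rgb[:, 1].mean(), mean_B=rgb[:, 2].mean(),
        mean_H=hsi[:, 0].mean(), mean_S=hsi[:, 1].mean(), mean_I=hsi[:, 2].mean(),
        mean_L=lab[:, 0].mean(), mean_a=lab[:, 1].mean(), mean_b=lab[:, 2].mean(),
    )


def records_frame(records) -> pd.DataFrame:
    """Stack SampleRecords into a feature table (one row per sample)."""
    return pd.DataFrame([asdict(r) for r in records])


def pearson_screen(samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every predictor with total nitrogen.

    Returns one row per predictor present in ``samples`` with columns
    ``r``, ``p_value``, ``sig_0_01``, ``sig_0_05`` (two-tailed), and
    ``degenerate`` flagging zero-variance predictors (whose r is undefined
    and reported as NaN).
    """
    if isinstance(samples, (list, tuple)):
        samples = records_frame(samples)
    if "total_N" not in samples or samples["total_N"].notna().sum() < 3:
        raise ValueError("need at least 3 samples with measured total_N")
    sub = samples[samples["total_N"].notna()]
    y = sub["total_N"].to_numpy(dtype=float)

    rows = []
    for col in PREDICTOR_COLUMNS:
        if col not in sub or sub[col].isna().any():
            continue
        x = sub[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"predictor": col, "r": np.nan, "p_value": np.nan,
                         "sig_0_01": False, "sig_0_05": False, "degenerate": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"predictor": col, "r": r, "p_value": p,
                     "sig_0_01": p < 0.01, "sig_0_05": p < 0.05,
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("predictor")


def compute_normalizers(samples: pd.DataFrame, system: str) -> dict[str, float]:
    """Per-channel range x'_i = x_imax - x_imin over the modeling set.

    These normalize the exponent of the exponential model family and must
    be frozen from the modeling subset at fit time.
    """
    if isinstance(samples, (list, tuple)):
        samples = records_frame(samples)
    if system not in COLOR_SYSTEMS:
        raise ValueError(f"unknown color system {system!r}")
    out: dict[str, float] = {}
    for col in COLOR_SYSTEMS[system]:
        vals = samples[col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError("need >= 2 samples to compute channel ranges")
        rng = float(np.ptp(vals))
        if rng <= 0:
            raise ValueError(f"zero range for channel {col}: normalizer undefined")
        out[col] = rng
    return out
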
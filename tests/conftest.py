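"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by the most literal method
available (exhaustive scans, per-pixel counting, closed forms) so that the
package's faster implementations are checked against an independent path.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def otsu_brute(values_u8: np.ndarray) -> int:
    """Exhaustive 256-candidate Otsu scan (low class: <= t)."""
    v = values_u8.ravel().astype(np.float64)
    best_t, best_s = None, -np.inf
    for t in range(256):
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return best_t


def majority_brute(mask: np.ndarray, size: int) -> np.ndarray:
    """Naive majority filter with edge replication."""
    h, w = mask.shape
    r = size // 2
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            cnt = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    cnt += bool(mask[yy, xx])
            out[y, x] = cnt * 2 > size * size
    return out


def erode_brute(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Pixel-set erosion; out-of-image counts as background."""
    h, w = mask.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            keep = True
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not selem[dy + r, dx + r]:
                        continue
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                        keep = False
                        break
                if not keep:
                    break
            out[y, x] = keep
    return out


def dilate_brute(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Pixel-set (Minkowski) dilation clipped to the frame."""
    h, w = mask.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if not selem[dy + r, dx + r]:
                    continue
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    out[yy, xx] = True
    return out


def mec_brute(pts: np.ndarray):
    """O(n^3) minimum enclosing circle over pair/triple candidates."""
    pts = [tuple(p) for p in np.asarray(pts, dtype=float)]

    def contains(c, r):
        return all(np.hypot(p[0] - c[0], p[1] - c[1]) <= r + 1e-9 for p in pts)

    best = None
    for p, q in itertools.combinations(pts, 2):
        c = ((p[0] + q[0]) / 2, (p[1] + q[1]) / 2)
        r = np.hypot(p[0] - c[0], p[1] - c[1])
        if contains(c, r) and (best is None or r < best[1]):
            best = (c, r)
    for a, b, c3 in itertools.combinations(pts, 3):
        d = 2 * (a[0] * (b[1] - c3[1]) + b[0] * (c3[1] - a[1]) + c3[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        a2 = a[0] ** 2 + a[1] ** 2
        b2 = b[0] ** 2 + b[1] ** 2
        c2 = c3[0] ** 2 + c3[1] ** 2
        ux = (a2 * (b[1] - c3[1]) + b2 * (c3[1] - a[1]) + c2 * (a[1] - b[1])) / d
        uy = (a2 * (c3[0] - b[0]) + b2 * (a[0] - c3[0]) + c2 * (b[0] - a[0])) / d
        r = max(np.hypot(p[0] - ux, p[1] - uy) for p in (a, b, c3))
        if contains((ux, uy), r) and (best is None or r < best[1]):
            best = ((ux, uy), r)
    if best is None:
        best = (pts[0], 0.0)
    return best


def mer_area_brute(pts: np.ndarray) -> float:
    """Exhaustive hull-edge-orientation scan for the min-area rectangle."""
    from scipy.spatial import ConvexHull

    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    hull = pts[ConvexHull(pts).vertices]
    best = np.inf
    n = len(hull)
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        length = np.hypot(*e)
        if length < 1e-12:
            continue
        u = e / length
        v = np.array([-u[1], u[0]])
        s = (pts - hull[i]) @ u
        t = (pts - hull[i]) @ v
        best = min(best, (s.max() - s.min()) * (t.max() - t.min()))
    return best


def deming_closed_form(x: np.ndarray, y: np.ndarray):
    """Closed-form Deming (lambda = 1, orthogonal) regression."""
    mx, my = x.mean(), y.mean()
    sxx = ((x - mx) ** 2).sum()
    syy = ((y - my) ** 2).sum()
    sxy = ((x - mx) * (y - my)).sum()
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)
    return slope, my - slope * mx


def effective_coefficients(model) -> np.ndarray:
    """Identifiable coefficient vector of a fitted model.

    For the exponential family the slopes are reported per raw channel
    unit (a_i / x'_i), since normalizers are recomputed from each modeling
    set; logarithmic fits are already canonicalized by the fitter.
    """
    a = np.asarray(model.a, dtype=float)
    if model.spec.family == "exponential":
        a = a / np.asarray(model.normalizers, dtype=float)
    out = list(a) + [model.b0]
    if model.a0 is not None:
        out = [model.a0] + out
    if model.b1 is not None:
        out = out + [model.b1]
    return np.array(out)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def disk_mask():
    """Rasterized solid disk of radius 40 in a 120x120 frame."""
    ys, xs = np.mgrid[0:120, 0:120]
    return (xs - 60) ** 2 + (ys - 60) ** 2 <= 40 ** 2


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
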
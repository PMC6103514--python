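"""Synthetic fixtures with known ground truth.

Two generators make every stage of the pipeline testable without field
imagery:

:func:`render_scene`
    Paints a field scene — a green plant blob over soil, optionally with a
    darker distractor plant — directly in CIELAB and converts to 8-bit
    sRGB.  Rendering in Lab guarantees the channel structure the
    segmentation cascade exploits: plant and soil are separated in the
    blue–yellow channel b, plant and distractor in lightness L.  The exact
    foreground mask is returned alongside the image.

:func:`generate_samples`
    Draws feature/nitrogen tables from a known generative model: true
    predictors follow a latent nutrition gradient t in [0, 1] (channels
    co-vary along t, as they do across real fertilization gradients, plus
    independent per-channel jitter), the response is the model evaluated
    at the TRUE predictors plus Gaussian noise, and the observed
    predictors are the true ones plus Gaussian measurement noise.  True
    values ship alongside the observed columns for oracle checks.

All generation is deterministic given the spec's seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .models import FittedModel, ModelSpec, evaluate_family

__all__ = [
    "Distractor",
    "SceneSpec",
    "render_scene",
    "ChannelProfile",
    "DataGenSpec",
    "generate_samples",
    "default_study_model",
    "default_study_spec",
    "field_scene",
]


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class Distractor:
    """A second, darker plant: same b-channel signature, lower lightness."""

    center: tuple[float, float]           # (x, y)
    radius: float
    lab: tuple[float, float, float] = (28.0, -30.0, 35.0)
    jitter: float = 1.5


@dataclass
class SceneSpec:
    width: int = 320
    height: int = 240
    shape: str = "disk"                   # disk | ellipse | blob
    center: tuple[float, float] | None = None
    radius: float = 60.0
    axes: tuple[float, float] = (70.0, 45.0)   # ellipse semi-axes
    plant_lab: tuple[float, float, float] = (58.0, -38.0, 42.0)
    plant_jitter: float = 1.5
    soil_lab: tuple[float, float, float] = (46.0, 10.0, 22.0)
    soil_jitter: float = 2.0
    distractors: tuple[Distractor, ...] = ()
    seed: int = 0


def _shape_mask(spec: SceneSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    cx, cy = spec.center if spec.center is not None else (w / 2.0, h / 2.0)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    if spec.shape == "disk":
        if not (spec.radius <= cx <= w - 1 - spec.radius
                and spec.radius <= cy <= h - 1 - spec.radius):
            raise ValueError("plant disk does not fit inside the frame")
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= spec.radius ** 2
    if spec.shape == "ellipse":
        ax, ay = spec.axes
        if not (ax <= cx <= w - 1 - ax and ay <= cy <= h - 1 - ay):
            raise ValueError("plant ellipse does not fit inside the frame")
        return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    if spec.shape == "blob":
        r = spec.radius
        offs = [(0.0, 0.0), (0.8 * r, 0.25 * r), (-0.6 * r, -0.45 * r)]
        m = np.zeros((h, w), dtype=bool)
        for dx, dy in offs:
            bx, by, br = cx + dx, cy + dy, 0.62 * r
            if not (br <= bx <= w - 1 - br and br <= by <= h - 1 - br):
                raise ValueError("plant blob does not fit inside the frame")
            m |= (xs - bx) ** 2 + (ys - by) ** 2 <= br ** 2
        return m
    raise ValueError(f"unknown shape {spec.shape!r}")


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene; returns (uint8 RGB image, ground-truth plant mask)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    lab = np.empty((h, w, 3), dtype=np.float64)
    for i, v in enumerate(spec.soil_lab):
        lab[..., i] = v
    lab += rng.normal(0.0, spec.soil_jitter, size=lab.shape)

    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    for d in spec.distractors:
        dm = (xs - d.center[0]) ** 2 + (ys - d.center[1]) ** 2 <= d.radius ** 2
        for i, v in enumerate(d.lab):
            lab[..., i][dm] = v + rng.normal(0.0, d.jitter, size=int(dm.sum()))

    plant = _shape_mask(spec)
    for i, v in enumerate(spec.plant_lab):
        lab[..., i][plant] = v + rng.normal(0.0, spec.plant_jitter, size=int(plant.sum()))

    rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    img = np.floor(rgb * 255.0 + 0.5).astype(np.uint8)
    return img, plant


def field_scene(seed: int = 0, radius: float = 60.0, with_distractor: bool = True,
                shape: str = "disk") -> SceneSpec:
    """A ready-made field scene: plant over soil, optional darker plant."""
    distractors = ()
    if with_distractor:
        distractors = (Distractor(center=(52.0, 52.0), radius=34.0),)
    return SceneSpec(shape=shape, radius=radius,
                     center=(200.0, 130.0), distractors=distractors, seed=seed)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

@dataclass
class ChannelProfile:
    """True-value profile of one predictor along the nutrition gradient.

    value(t) = start + (stop - start) * t + U(-jitter, jitter)
    """

    start: float
    stop: float
    jitter: float = 0.0


@dataclass
class DataGenSpec:
    model: FittedModel
    n: int
    profiles: dict[str, ChannelProfile]
    sigma_y: float = 0.3
    sigma_x: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma_y < 0 or any(v < 0 for v in self.sigma_x.values()):
            raise ValueError("noise levels must be >= 0")


def generate_samples(spec: DataGenSpec) -> pd.DataFrame:
    """Draw a feature/nitrogen table from a known model.

    Columns: observed predictors (named as in the feature table), the
    noisy response ``total_N``, and ``true_<col>`` / ``true_total_N``
    oracle columns.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    mspec = model.spec
    n = spec.n

    t = rng.uniform(0.0, 1.0, size=n)
    cols = list(mspec.channels)
    gs_col = mspec.gs_column
    if gs_col is not None:
        cols.append(gs_col)

    true: dict[str, np.ndarray] = {}
    for col in cols:
        if col not in spec.profiles:
            raise ValueError(f"no profile for predictor {col!r}")
        p = spec.profiles[col]
        v = p.start + (p.stop - p.start) * t
        if p.jitter > 0:
            v = v + rng.uniform(-p.jitter, p.jitter, size=n)
        if col.startswith("gs_"):
            v = np.clip(v, 1e-3, 1.0)
        if mspec.family == "reciprocal":
            for _ in range(spec.max_redraws):
                bad = np.abs(v) < 1e-6
                if not bad.any():
                    break
                v[bad] = p.start + (p.stop - p.start) * rng.uniform(0, 1, int(bad.sum()))
            else:
                raise ValueError(
                    f"could not draw nonzero values for {col!r} "
                    f"within {spec.max_redraws} redraws"
                )
        true[col] = v

    X_true = np.column_stack([true[c] for c in mspec.channels])
    gs_true = None if gs_col is None else true[gs_col]
    y_true = evaluate_family(
        mspec.family, X_true, np.asarray(model.a), model.b0, a0=model.a0,
        b1=model.b1, gs=gs_true,
        normalizers=None if model.normalizers is None else np.asarray(model.normalizers),
        strict=True,
    )

    data: dict[str, np.ndarray] = {}
    for col in cols:
        sig = spec.sigma_x.get(col, 0.0)
        obs = true[col] + (rng.normal(0.0, sig, size=n) if sig > 0 else 0.0)
        if col.startswith("gs_"):
            obs = np.clip(obs, 1e-3, 1.0)
        data[col] = obs
    data["total_N"] = y_true + (
        rng.normal(0.0, spec.sigma_y, size=n) if spec.sigma_y > 0 else 0.0
    )
    for col in cols:
        data[f"true_{col}"] = true[col]
    data["true_total_N"] = y_true

    df = pd.DataFrame(data)
    df.insert(0, "sample_id", [f"s{i:04d}" for i in range(n)])
    return df


#: True-value profiles of the Lab predictors along the nutrition gradient,
#: shared by the study-condition generator and the recovery-test models.
LAB_PROFILES = {
    "mean_L": ChannelProfile(24.0, 28.0, 2.4),
    "mean_a": ChannelProfile(-3.5, -5.0, 0.6),
    "mean_b": ChannelProfile(23.0, 27.0, 2.4),
    "gs_mcc": ChannelProfile(0.35, 0.75, 0.03),
}
_LAB_MEANS = {"mean_L": 26.0, "mean_a": 4.25, "mean_b": 25.0, "gs_mcc": 0.55}
_LAB_NORMALIZERS = (20.0, 10.0, 20.0)

#: Wider profiles spanning the Lab values of typical green foliage
#: (L ~ 35-60, a ~ -25..-10, b ~ 20-43); used by the recovery-test models,
#: whose coefficients are drawn to match these spreads.
LAB_WIDE_PROFILES = {
    "mean_L": ChannelProfile(38.0, 58.0, 3.5),
    "mean_a": ChannelProfile(-12.0, -22.0, 2.5),
    "mean_b": ChannelProfile(22.0, 40.0, 3.0),
    "gs_mcc": ChannelProfile(0.35, 0.75, 0.03),
}
_LAB_WIDE_MEANS = {"mean_L": 48.0, "mean_a": 17.0, "mean_b": 31.0, "gs_mcc": 0.55}


def _profile_box(profiles, cols):
    lo, hi = [], []
    for c in cols:
        p = profiles[c]
        a, b = sorted((p.start, p.stop))
        lo.append(a - p.jitter)
        hi.append(b + p.jitter)
    return np.array(lo), np.array(hi)


def random_family_model(family: str, seed: int = 0) -> FittedModel:
    """A random true model of one family on the Lab/GS_MCC design.

    Coefficients are drawn from ranges that keep the response positive and
    within roughly the 1-40 band of measured foliar nitrogen over the
    :data:`LAB_PROFILES` predictor box (the a0 of the power and
    exponential families is solved from the target response level; the
    logarithmic direction is redrawn until its inner sum is sign-stable
    over the box).
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec(family, "Lab", "MCC")
    cols = list(spec.channels)
    lo, hi = _profile_box(LAB_WIDE_PROFILES, cols)
    xbar = (lo + hi) / 2.0
    b1 = rng.uniform(5.0, 20.0)
    gbar = 0.55

    def _signed(lo_mag, hi_mag, size=3):
        # magnitudes bounded away from 0 so every sign is estimable
        return rng.uniform(lo_mag, hi_mag, size) * rng.choice([-1.0, 1.0], size)

    def _off_zero(b0):
        return b0 if abs(b0) >= 1.0 else (1.5 if b0 >= 0 else -1.5)

    if family == "linear":
        a = _signed(0.1, 0.3) * np.array([1.0, 2.0, 1.0])
        b0 = _off_zero(15.0 - float(a @ xbar) - b1 * gbar)
        return FittedModel(spec=spec, a=tuple(a), b0=b0, b1=b1)
    if family == "reciprocal":
        a = _signed(200.0, 600.0) * np.array([1.0, 0.1, 0.4])
        b0 = _off_zero(15.0 - float(a @ (1.0 / xbar)) - b1 * gbar)
        return FittedModel(spec=spec, a=tuple(a), b0=b0, b1=b1)
    if family == "power":
        a = _signed(0.4, 1.0)
        a0 = 10.0 / float(np.exp(np.log(np.abs(xbar)) @ a))
        b0 = float(_signed(4.0, 8.0, 1)[0])
        return FittedModel(spec=spec, a=tuple(a), a0=a0, b0=b0, b1=b1)
    if family == "logarithmic":
        for _ in range(100):
            a = rng.uniform(0.25, 1.0, 3) * rng.choice([-1.0, 1.0], 3)
            a /= np.linalg.norm(a)
            corners = np.array(
                [[lo[i] if b & (1 << i) else hi[i] for i in range(3)]
                 for b in range(8)]
            )
            z = corners @ a
            if np.all(z > 0.5) or np.all(z < -0.5):
                break
        else:
            raise RuntimeError("could not draw a sign-stable log direction")
        nz = np.flatnonzero(np.abs(a) > 1e-12)
        if a[nz[0]] < 0:
            a = -a
        a0 = rng.uniform(2.0, 8.0) * rng.choice([-1.0, 1.0])
        b0 = _off_zero(15.0 - a0 * float(np.log(np.abs(xbar @ a))) - b1 * gbar)
        return FittedModel(spec=spec, a=tuple(a), a0=a0, b0=b0, b1=b1)
    if family == "exponential":
        a = _signed(0.2, 0.6)
        u = xbar / np.asarray(_LAB_NORMALIZERS)
        a0 = 10.0 / float(np.exp(u @ a))
        b0 = rng.uniform(-6.0, -1.0)
        return FittedModel(spec=spec, a=tuple(a), a0=a0, b0=b0, b1=b1,
                           normalizers=_LAB_NORMALIZERS)
    raise ValueError(f"unknown family {family!r}")


def family_recovery_spec(
    family: str,
    seed: int = 0,
    n: int = 60,
    sigma_y: float = 0.0,
    color_tolerance: float = 0.0,
) -> DataGenSpec:
    """A recovery-test generator: random true model + Lab profiles.

    ``color_tolerance`` scales predictor measurement noise as a fraction
    of each channel's mean magnitude (0 = error-free predictors).
    """
    model = random_family_model(family, seed=seed)
    sigma_x = {c: color_tolerance * m for c, m in _LAB_WIDE_MEANS.items()}
    return DataGenSpec(
        model=model, n=n, profiles=dict(LAB_WIDE_PROFILES),
        sigma_y=sigma_y, sigma_x=sigma_x, seed=seed + 77_000,
    )


def default_study_model() -> FittedModel:
    """The study-condition generative model for synthetic tables.

    Exponential family on Lab with a GS_MCC term, using the reference
    calibration's coefficients together with frozen normalizers chosen as
    realistic Lab channel spreads for a sandalwood canopy (L' = 20,
    a' = 10, b' = 20).
    """
    return FittedModel(
        spec=ModelSpec("exponential", "Lab", "MCC"),
        a0=237.374, a=(-4.471, -11.927, -2.782), b0=-4.274, b1=26.248,
        normalizers=(20.0, 10.0, 20.0),
    )


def default_study_spec(n: int = 48, seed: int = 0,
                       sigma_y: float = 0.3,
                       color_tolerance: float = 0.03) -> DataGenSpec:
    """Study-condition table generator.

    Defaults encode the calibration conditions: 48 modeling samples,
    response noise sigma_y = 0.3, and predictor measurement noise at the
    segmentation color tolerance (3% of the channel mean magnitude).  The
    channel profiles span realistic Lab values for canopies along a
    nitrogen gradient and keep the response within the ~1-40 band of
    measured foliar nitrogen.
    """
    sigma_x = {c: color_tolerance * m for c, m in _LAB_MEANS.items()}
    return DataGenSpec(
        model=default_study_model(), n=n, profiles=dict(LAB_PROFILES),
        sigma_y=sigma_y, sigma_x=sigma_x, seed=seed,
    )
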
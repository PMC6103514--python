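"""Parameter estimation: ordinary least squares and errors-in-variables.

Two estimators are provided for every model family:

``fit_lsm``
    Minimizes the residual sum of squares ``sum (y_i - f(x_i; c))^2``.
    The linear and reciprocal families are solved in closed form (linear
    regression on transformed predictors); power, logarithmic and
    exponential families use iterative nonlinear least squares with
    linearization-based warm starts plus seeded random multi-starts.

``fit_eiv``
    The errors-in-variables estimator.  Segmentation noise puts error into
    the color and growth-status predictors as well as the response, so the
    observed predictors x_i are modeled as noisy readings of latent true
    values xi_i.  With a diagonal error covariance (sigma_y for the
    response, sigma_j per predictor column) the estimator minimizes the
    weighted orthogonal objective

        sum_i (y_i - f(xi_i; c))^2 / sigma_y^2
              + sum_ij (x_ij - xi_ij)^2 / sigma_j^2

    jointly over the coefficients c and the latent predictors xi_i,
    initialized at the LSM solution with xi = x.  For a straight line with
    equal x/y noise this reduces to Deming (orthogonal) regression; as the
    predictor variances shrink to zero it degenerates to ordinary least
    squares.  Columns whose sigma is negligible relative to the column's
    spread are treated as error-free and carry no latent adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from .features import COLOR_SYSTEMS, compute_normalizers
from .models import FittedModel, ModelSpec, evaluate_family

__all__ = [
    "EivConfig",
    "FitResult",
    "fit_lsm",
    "fit_eiv",
    "fit_family_lsm",
    "fit_family_eiv",
    "estimate_sigma",
]

_TOL = 1e-12


@dataclass
class EivConfig:
    """Error model and optimizer settings for the EIV estimator.

    ``sigma_x`` maps predictor column names (channel mean columns, and the
    GS column when the spec has one) to error standard deviations;
    ``sigma_y`` is the response error standard deviation.  Either may be
    left None to be filled in by :func:`estimate_sigma`.
    """

    sigma_x: dict[str, float] | None = None
    sigma_y: float | None = None
    max_nfev: int = 5000
    tol: float = _TOL
    seed: int = 0
    n_starts: int = 5
    #: columns with sigma below this fraction of their spread are error-free
    error_free_rel: float = 1e-8

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.sigma_x is not None and any(v < 0 for v in self.sigma_x.values()):
            raise ValueError("error standard deviations must be >= 0")
        if self.sigma_y is not None and self.sigma_y <= 0:
            raise ValueError("response error standard deviation must be > 0")


@dataclass
class FitResult:
    model: FittedModel
    objective: float
    converged: bool
    n_iter: int
    method: str
    #: EIV only: xi_hat - x per error-laden predictor column, else None
    latent_adjustments: np.ndarray | None = None


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _has_a0(family: str) -> bool:
    return family in ("power", "logarithmic", "exponential")


def _pack(family: str, a, b0, a0=None, b1=None) -> np.ndarray:
    theta = []
    if _has_a0(family):
        theta.append(a0)
    theta.extend(np.atleast_1d(a))
    theta.append(b0)
    if b1 is not None:
        theta.append(b1)
    return np.asarray(theta, dtype=np.float64)


def _unpack(family: str, theta: np.ndarray, q: int, has_gs: bool) -> dict:
    i = 0
    a0 = None
    if _has_a0(family):
        a0 = theta[0]
        i = 1
    a = theta[i: i + q]
    b0 = theta[i + q]
    b1 = theta[i + q + 1] if has_gs else None
    return {"a": a, "a0": a0, "b0": b0, "b1": b1}


def _n_params(family: str, q: int, has_gs: bool) -> int:
    return q + 1 + (1 if _has_a0(family) else 0) + (1 if has_gs else 0)


def _eval(family, X, params, gs, normalizers, strict=False):
    return evaluate_family(
        family, X, params["a"], params["b0"], a0=params["a0"],
        b1=params["b1"], gs=gs, normalizers=normalizers, strict=strict,
    )


def _family_partials(family, X, params, gs, normalizers):
    """Model values and analytic partial derivatives of one family.

    Returns ``(f, d_theta, d_X, d_gs)`` where ``d_theta`` is (n, k) in the
    packed parameter order, ``d_X`` is (n, q) with df/dx_ij, and ``d_gs``
    is (n,) (zeros when the model has no GS term).  Uses the same floors
    as the non-strict evaluator so values and derivatives agree.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, q = X.shape
    a = np.asarray(params["a"], dtype=np.float64)
    a0, b0, b1 = params["a0"], params["b0"], params["b1"]
    has_gs = b1 is not None
    tiny = np.finfo(float).tiny

    ags = np.full(n, float(b0))
    d_gs = np.zeros(n)
    if has_gs:
        g = np.asarray(gs, dtype=np.float64)
        ags = ags + b1 * g
        d_gs = np.full(n, float(b1))

    if family == "linear":
        f = ags + X @ a
        d_a = X.copy()
        d_X = np.broadcast_to(a, (n, q)).copy()
        d_a0 = None
    elif family == "reciprocal":
        Xs = np.where(X == 0, tiny, X)
        f = ags + (1.0 / Xs) @ a
        d_a = 1.0 / Xs
        d_X = -a[None, :] / Xs ** 2
        d_a0 = None
    elif family == "power":
        base = np.abs(X)
        base = np.where(base == 0, tiny, base)
        lb = np.log(base)
        P = np.exp(lb @ a)
        f = ags + a0 * P
        d_a0 = P
        d_a = (a0 * P)[:, None] * lb
        Xs = np.where(X == 0, tiny, X)
        d_X = (a0 * P)[:, None] * a[None, :] / Xs
    elif family == "logarithmic":
        z = X @ a
        zs = np.where(np.abs(z) < tiny, tiny, z)
        f = ags + a0 * np.log(np.abs(zs))
        d_a0 = np.log(np.abs(zs))
        d_a = a0 * X / zs[:, None]
        d_X = (a0 / zs)[:, None] * a[None, :]
    elif family == "exponential":
        norm = np.asarray(normalizers, dtype=np.float64)
        u = X / norm
        E = np.exp(u @ a)
        f = ags + a0 * E
        d_a0 = E
        d_a = (a0 * E)[:, None] * u
        d_X = (a0 * E)[:, None] * (a / norm)[None, :]
    else:
        raise ValueError(family)

    cols = []
    if d_a0 is not None:
        cols.append(d_a0[:, None])
    cols.append(d_a)
    cols.append(np.ones((n, 1)))
    if has_gs:
        cols.append(g[:, None])
    d_theta = np.hstack(cols)
    return f, d_theta, d_X, d_gs


def _canonicalize_log(params: dict) -> dict:
    """Fix the scale/sign gauge of the logarithmic family.

    a -> k a shifts b0 by a0 ln k and flips of a leave |sum a_i x_i|
    unchanged, so fits are normalized to ||a|| = 1 with the first nonzero
    coefficient positive.
    """
    a = np.asarray(params["a"], dtype=float)
    k = np.linalg.norm(a)
    if k == 0:
        return params
    a = a / k
    b0 = params["b0"] + params["a0"] * np.log(k)
    nz = np.flatnonzero(np.abs(a) > 1e-12)
    if nz.size and a[nz[0]] < 0:
        a = -a
    return {"a": a, "a0": params["a0"], "b0": b0, "b1": params["b1"]}


# ---------------------------------------------------------------------------
# warm starts
# ---------------------------------------------------------------------------

def _lstsq(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return beta


def _linear_design(family: str, X: np.ndarray, gs) -> np.ndarray:
    T = X if family == "linear" else 1.0 / X
    cols = [T, np.ones((len(X), 1))]
    if gs is not None:
        cols.append(np.asarray(gs, dtype=float)[:, None])
    return np.hstack(cols)


def _initial_guesses(family, X, y, gs, normalizers, rng, n_starts):
    """Family-specific linearization seeds plus random perturbations."""
    n, q = X.shape
    has_gs = gs is not None
    seeds: list[np.ndarray] = []
    yspread = float(np.std(y)) or 1.0

    def _loglin(target_col):
        """Regress log of a positive transform of y on the log/linear design."""
        pos = target_col > 0
        if pos.sum() < q + 2:
            return None
        ly = np.log(target_col[pos])
        D = np.column_stack([np.ones(pos.sum()), design[pos]])
        beta = _lstsq(D, ly)
        return np.exp(beta[0]), beta[1:]

    if family == "power":
        design = np.log(np.maximum(np.abs(X), np.finfo(float).tiny))
        got = _loglin(y)
        if got is not None:
            a0, a = got
            seeds.append(_pack(family, a, 0.0, a0=a0, b1=0.0 if has_gs else None))
        seeds.append(_pack(family, np.zeros(q), float(np.mean(y)) - yspread,
                           a0=yspread, b1=0.0 if has_gs else None))
    elif family == "exponential":
        design = X / np.asarray(normalizers, dtype=float)
        got = _loglin(y)
        if got is not None:
            a0, a = got
            seeds.append(_pack(family, a, 0.0, a0=a0, b1=0.0 if has_gs else None))
        shift = float(np.min(y)) - 0.5 * yspread
        got = _loglin(y - shift)
        if got is not None:
            a0, a = got
            seeds.append(_pack(family, a, shift, a0=a0, b1=0.0 if has_gs else None))
        seeds.append(_pack(family, np.zeros(q), float(np.mean(y)) - yspread,
                           a0=yspread, b1=0.0 if has_gs else None))
    elif family == "logarithmic":
        # profile: for a trial direction a the model is linear in (a0,b0,b1)
        directions = [_lstsq(_linear_design("linear", X, None), y)[:q]]
        directions += [rng.standard_normal(q) for _ in range(8)]
        scored = []
        for d in directions:
            nd = np.linalg.norm(d)
            if nd == 0:
                continue
            d = d / nd
            z = np.log(np.maximum(np.abs(X @ d), np.finfo(float).tiny))
            cols = [z[:, None], np.ones((n, 1))]
            if has_gs:
                cols.append(np.asarray(gs, dtype=float)[:, None])
            D = np.hstack(cols)
            beta = _lstsq(D, y)
            resid = y - D @ beta
            theta = _pack(family, d, beta[1], a0=beta[0],
                          b1=beta[2] if has_gs else None)
            scored.append((float(resid @ resid), theta))
        scored.sort(key=lambda t: t[0])
        seeds.extend(t for _, t in scored[:3])
    else:
        raise ValueError(family)

    out = list(seeds)
    i = 0
    while len(out) < n_starts and seeds:
        base = seeds[i % len(seeds)]
        pert = base * (1 + 0.2 * rng.standard_normal(base.size)) \
            + 0.05 * rng.standard_normal(base.size)
        out.append(pert)
        i += 1
    return out


# ---------------------------------------------------------------------------
# LSM
# ---------------------------------------------------------------------------

def fit_family_lsm(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    gs: np.ndarray | None = None,
    normalizers: np.ndarray | None = None,
    seed: int = 0,
    n_starts: int = 5,
    max_nfev: int = 5000,
):
    """Least-squares fit of one family on raw arrays.

    Returns ``(params, sse, converged, n_iter)`` where ``params`` is a dict
    with keys ``a``, ``a0``, ``b0``, ``b1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, q = X.shape
    has_gs = gs is not None
    k = _n_params(family, q, has_gs)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples to fit {k} coefficients")

    if family in ("linear", "reciprocal"):
        if family == "reciprocal" and np.any(X == 0):
            raise ValueError("reciprocal family: a predictor value is 0")
        D = _linear_design(family, X, gs)
        beta = _lstsq(D, y)
        params = {"a": beta[:q], "a0": None, "b0": beta[q],
                  "b1": beta[q + 1] if has_gs else None}
        resid = y - D @ beta
        return params, float(resid @ resid), True, 1

    if family == "exponential" and normalizers is None:
        raise ValueError("exponential family requires normalizers")

    rng = np.random.default_rng(seed)
    gs_arr = None if gs is None else np.asarray(gs, dtype=np.float64)
    norm_arr = None if normalizers is None else np.asarray(normalizers, dtype=np.float64)

    def resid_fn(theta):
        params = _unpack(family, theta, q, has_gs)
        with np.errstate(over="ignore", invalid="ignore"):
            f = _eval(family, X, params, gs_arr, norm_arr, strict=False)
        return np.nan_to_num(f - y, nan=1e150, posinf=1e150, neginf=-1e150)

    def jac_fn(theta):
        params = _unpack(family, theta, q, has_gs)
        with np.errstate(over="ignore", invalid="ignore"):
            _, d_theta, _, _ = _family_partials(family, X, params, gs_arr, norm_arr)
        return np.nan_to_num(d_theta, nan=0.0, posinf=1e150, neginf=-1e150)

    best = None
    total_nfev = 0
    for theta0 in _initial_guesses(family, X, y, gs_arr, norm_arr, rng, n_starts):
        try:
            res = least_squares(
                resid_fn, theta0, jac=jac_fn, method="trf",
                xtol=_TOL, ftol=_TOL, gtol=_TOL, max_nfev=max_nfev,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError(f"all starts failed for {family} family")

    params = _unpack(family, best.x, q, has_gs)
    if family == "logarithmic":
        params = _canonicalize_log(params)
    converged = bool(best.status > 0)
    return params, float(2 * best.cost), converged, total_nfev


def _spec_arrays(spec: ModelSpec, samples):
    X = samples.loc[:, list(spec.channels)].to_numpy(dtype=float)
    y = samples["total_N"].to_numpy(dtype=float)
    gs_col = spec.gs_column
    gs = None if gs_col is None else samples[gs_col].to_numpy(dtype=float)
    return X, y, gs


def fit_lsm(spec: ModelSpec, samples, seed: int = 0, n_starts: int = 5) -> FitResult:
    """Least-squares fit of a ModelSpec on a feature table (modeling set).

    For the exponential family the channel normalizers are computed from
    this modeling set and frozen into the returned model.
    """
    X, y, gs = _spec_arrays(spec, samples)
    normalizers = None
    if spec.family == "exponential":
        norm_map = compute_normalizers(samples, spec.system)
        normalizers = np.array([norm_map[c] for c in spec.channels])
    params, sse, converged, n_iter = fit_family_lsm(
        spec.family, X, y, gs, normalizers=normalizers, seed=seed, n_starts=n_starts,
    )
    model = FittedModel(
        spec=spec, a=tuple(params["a"]), b0=float(params["b0"]),
        a0=None if params["a0"] is None else float(params["a0"]),
        b1=None if params["b1"] is None else float(params["b1"]),
        normalizers=None if normalizers is None else tuple(normalizers),
    )
    return FitResult(model, sse, converged, n_iter, method="lsm")


# ---------------------------------------------------------------------------
# EIV
# ---------------------------------------------------------------------------

def fit_family_eiv(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    sigma_x: np.ndarray,
    sigma_y: float,
    gs: np.ndarray | None = None,
    sigma_gs: float = 0.0,
    normalizers: np.ndarray | None = None,
    params0: dict | None = None,
    cfg: EivConfig | None = None,
):
    """EIV fit of one family on raw arrays.

    ``sigma_x`` gives the per-column predictor error SD (length q);
    ``sigma_gs`` the error SD of the GS predictor when present.  Returns
    ``(params, objective, converged, n_iter, latent_adjustments)``.
    """
    cfg = cfg or EivConfig()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, q = X.shape
    has_gs = gs is not None
    gs_arr = None if gs is None else np.asarray(gs, dtype=np.float64)
    norm_arr = None if normalizers is None else np.asarray(normalizers, dtype=np.float64)
    sigma_x = np.asarray(sigma_x, dtype=np.float64)
    if sigma_x.size != q:
        raise ValueError("sigma_x length must match predictor count")
    if sigma_y <= 0:
        raise ValueError("sigma_y must be positive (singular error covariance)")

    if params0 is None:
        params0, *_ = fit_family_lsm(
            family, X, y, gs_arr, normalizers=norm_arr,
            seed=cfg.seed, n_starts=cfg.n_starts,
        )
    theta0 = _pack(family, params0["a"], params0["b0"], params0["a0"], params0["b1"])
    k = theta0.size

    # observed predictor block: channels, then GS (if modeled with error)
    W_cols = [X[:, j] for j in range(q)]
    sig_cols = list(sigma_x)
    if has_gs:
        W_cols.append(gs_arr)
        sig_cols.append(sigma_gs)
    W = np.column_stack(W_cols)
    sig = np.asarray(sig_cols, dtype=np.float64)
    spread = np.maximum(W.max(axis=0) - W.min(axis=0), 1.0)
    err_cols = np.flatnonzero(sig > cfg.error_free_rel * spread)
    ne = err_cols.size
    sig_e = sig[err_cols]

    def _split(v):
        params = _unpack(family, v[:k], q, has_gs)
        Wlat = W.copy()
        if ne:
            Wlat[:, err_cols] = v[k:].reshape(n, ne)
        return params, Wlat, Wlat[:, :q], (Wlat[:, q] if has_gs else None)

    def resid_fn(v):
        params, Wlat, Xl, gl = _split(v)
        with np.errstate(over="ignore", invalid="ignore"):
            f = _eval(family, Xl, params, gl, norm_arr, strict=False)
        r1 = np.nan_to_num((f - y) / sigma_y, nan=1e150, posinf=1e150, neginf=-1e150)
        if not ne:
            return r1
        r2 = ((W[:, err_cols] - Wlat[:, err_cols]) / sig_e).ravel()
        return np.concatenate([r1, r2])

    m = n + n * ne
    p = k + n * ne
    rows = np.arange(n)
    diag = np.arange(n * ne)
    sig_rep = np.tile(sig_e, n)

    def jac_fn(v):
        params, Wlat, Xl, gl = _split(v)
        with np.errstate(over="ignore", invalid="ignore"):
            _, d_theta, d_X, d_gs = _family_partials(family, Xl, params, gl, norm_arr)
        J = np.zeros((m, p))
        J[:n, :k] = d_theta / sigma_y
        for j_local, col in enumerate(err_cols):
            dcol = d_gs if (has_gs and col == q) else d_X[:, col]
            J[rows, k + rows * ne + j_local] = dcol / sigma_y
        if ne:
            J[n + diag, k + diag] = -1.0 / sig_rep
        return np.nan_to_num(J, nan=0.0, posinf=1e150, neginf=-1e150)

    rng = np.random.default_rng(cfg.seed)
    lat0 = W[:, err_cols].ravel() if ne else np.empty(0)

    # dense analytic-Jacobian solves; Levenberg-Marquardt for small
    # problems (tightest convergence), trust-region reflective above
    use_lm = p <= 400 and m >= p
    best = None
    total_nfev = 0
    for s in range(max(1, cfg.n_starts)):
        theta_s = theta0 if s == 0 else theta0 * (
            1 + 0.05 * rng.standard_normal(k)
        ) + 0.01 * rng.standard_normal(k)
        v0 = np.concatenate([theta_s, lat0])
        try:
            res = least_squares(
                resid_fn, v0, jac=jac_fn, method="lm" if use_lm else "trf",
                xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol,
                max_nfev=cfg.max_nfev,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError(f"EIV optimization failed for {family} family")

    params = _unpack(family, best.x[:k], q, has_gs)
    if family == "logarithmic":
        params = _canonicalize_log(params)
    adjustments = np.zeros((n, W.shape[1]))
    if ne:
        adjustments[:, err_cols] = best.x[k:].reshape(n, ne) - W[:, err_cols]
    converged = bool(best.status > 0)
    return params, float(2 * best.cost), converged, total_nfev, adjustments


def fit_eiv(spec: ModelSpec, samples, cfg: EivConfig | None = None) -> FitResult:
    """EIV fit of a ModelSpec on a feature table.

    Missing pieces of the error model are filled by :func:`estimate_sigma`;
    the estimator is warm-started at the LSM solution.
    """
    cfg = cfg or EivConfig()
    X, y, gs = _spec_arrays(spec, samples)
    normalizers = None
    if spec.family == "exponential":
        norm_map = compute_normalizers(samples, spec.system)
        normalizers = np.array([norm_map[c] for c in spec.channels])

    lsm = fit_lsm(spec, samples, seed=cfg.seed, n_starts=cfg.n_starts)
    sigma_x_map, sigma_y = estimate_sigma(samples, spec, lsm_result=lsm)
    if cfg.sigma_x is not None:
        sigma_x_map = {**sigma_x_map, **cfg.sigma_x}
    if cfg.sigma_y is not None:
        sigma_y = cfg.sigma_y

    sigma_x = np.array([sigma_x_map[c] for c in spec.channels])
    sigma_gs = sigma_x_map.get(spec.gs_column, 0.0) if spec.gs_column else 0.0
    params0 = {"a": np.asarray(lsm.model.a), "a0": lsm.model.a0,
               "b0": lsm.model.b0, "b1": lsm.model.b1}
    params, obj, converged, n_iter, adj = fit_family_eiv(
        spec.family, X, y, sigma_x, sigma_y, gs=gs, sigma_gs=sigma_gs,
        normalizers=normalizers, params0=params0, cfg=cfg,
    )
    model = FittedModel(
        spec=spec, a=tuple(params["a"]), b0=float(params["b0"]),
        a0=None if params["a0"] is None else float(params["a0"]),
        b1=None if params["b1"] is None else float(params["b1"]),
        normalizers=None if normalizers is None else tuple(normalizers),
    )
    return FitResult(model, obj, converged, n_iter, method="eiv",
                     latent_adjustments=adj)


def estimate_sigma(
    samples,
    spec: ModelSpec,
    lsm_result: FitResult | None = None,
    color_tolerance: float = 0.03,
    floor: float = 1e-6,
    override: dict | None = None,
):
    """Default diagonal error model.

    Predictor error SDs follow the segmentation color-error bound:
    ``sigma_j = color_tolerance * |mean of column j|`` (3% by default),
    applied to the channel means and to the GS predictor.  The response
    error SD is the LSM root residual variance, floored at a small
    positive constant.  ``override`` entries replace the heuristic exactly
    (key ``"total_N"`` overrides sigma_y).

    Returns ``(sigma_x: dict, sigma_y: float)``.
    """
    if len(samples) < 10:
        raise ValueError("need >= 10 samples to estimate the error model")
    cols = list(spec.channels)
    if spec.gs_column:
        cols.append(spec.gs_column)
    sigma_x = {
        c: max(color_tolerance * abs(float(samples[c].mean())), floor) for c in cols
    }
    if lsm_result is None:
        lsm_result = fit_lsm(spec, samples)
    n = len(samples)
    k = len(lsm_result.model.a) + 2 + (1 if lsm_result.model.a0 is not None else 0)
    dof = max(n - k, 1)
    sigma_y = max(np.sqrt(lsm_result.objective / dof), floor)
    if override:
        sigma_y = float(override.get("total_N", sigma_y))
        sigma_x = {c: float(override.get(c, sigma_x[c])) for c in sigma_x}
    return sigma_x, float(sigma_y)
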
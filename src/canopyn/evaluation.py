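"""Fit/validation statistics and multi-criteria model ranking.

For observed values y_i, predictions y'_i and n samples the report holds:

* ``mean_residual``      e  = (1/n) sum (y_i - y'_i)
* ``residual_variance``  d2 = (1/(n-1)) sum (y_i - y'_i)^2
* ``mse``                e^2 + d2
* ``rmse``               sqrt(e^2 + d2)
* ``r2``                 1 - sum (y_i - y'_i)^2 / sum (y_i - ybar)^2

Two deliberate normalizations of the conventions this field sometimes
prints loosely: the coefficient of determination always squares both sums
(unsquared sums are not even sign-stable), and the quantity tabulated as
"MSE" in validation tables of this model class is sqrt(e^2 + d2) — the
report exposes it as ``rmse`` and keeps ``mse = e^2 + d2`` alongside.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import FittedModel, predict_frame

__all__ = ["EvalReport", "eval_stats", "evaluate", "rank_models", "RANK_CRITERIA"]


@dataclass
class EvalReport:
    n: int
    r2: float              # NaN when the response has zero variance
    mean_residual: float
    residual_variance: float
    mse: float
    rmse: float
    r2_defined: bool = True


def eval_stats(y: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """All evaluation statistics from observed/predicted pairs."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-D arrays of equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    resid = y - y_pred
    e_bar = float(resid.mean())
    ssr = float(resid @ resid)
    d2 = ssr / (n - 1)
    mse = e_bar ** 2 + d2
    sst = float(((y - y.mean()) ** 2).sum())
    if sst > 0:
        r2, defined = 1.0 - ssr / sst, True
    else:
        r2, defined = np.nan, False
    return EvalReport(
        n=n, r2=r2, mean_residual=e_bar, residual_variance=d2,
        mse=mse, rmse=float(np.sqrt(mse)), r2_defined=defined,
    )


def evaluate(model: FittedModel, samples: pd.DataFrame) -> EvalReport:
    """Evaluate a fitted model on a feature table with measured total_N."""
    sub = samples[samples["total_N"].notna()]
    if len(sub) < 2:
        raise ValueError("need at least 2 samples with measured total_N")
    y = sub["total_N"].to_numpy(dtype=float)
    y_pred = predict_frame(model, sub)
    return eval_stats(y, y_pred)


#: The six ranking criteria: (column, whether larger is better).
RANK_CRITERIA = [
    ("modeling_r2", True),
    ("modeling_abs_mean_residual", False),
    ("validation_r2", True),
    ("validation_abs_mean_residual", False),
    ("validation_residual_variance", False),
    ("validation_rmse", False),
]


def rank_models(
    candidates: pd.DataFrame, aggregate: str = "sum"
) -> pd.DataFrame:
    """Rank candidate models on six modeling/validation criteria.

    ``candidates`` needs columns ``modeling_r2``, ``modeling_mean_residual``,
    ``validation_r2``, ``validation_mean_residual``,
    ``validation_residual_variance`` and ``validation_rmse`` (one row per
    candidate).  Per criterion, rank 1 is best — higher R^2, smaller
    |mean residual|, residual variance and rmse — and ties share the lower
    rank.  The final order sorts the aggregate (sum of ranks by default,
    ``"mean"`` also accepted) ascending, stably by input position; exact
    aggregate ties are flagged.
    """
    required = [
        "modeling_r2", "modeling_mean_residual", "validation_r2",
        "validation_mean_residual", "validation_residual_variance",
        "validation_rmse",
    ]
    for col in required:
        if col not in candidates or candidates[col].isna().any():
            raise ValueError(f"missing ranking criterion {col!r}")
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")

    out = candidates.copy()
    out["modeling_abs_mean_residual"] = out["modeling_mean_residual"].abs()
    out["validation_abs_mean_residual"] = out["validation_mean_residual"].abs()

    rank_cols = []
    for col, larger_better in RANK_CRITERIA:
        vals = out[col].to_numpy(dtype=float)
        r = rankdata(-vals if larger_better else vals, method="min")
        out[f"rank_{col}"] = r.astype(int)
        rank_cols.append(f"rank_{col}")

    agg = out[rank_cols].sum(axis=1).to_numpy(dtype=float)
    if aggregate == "mean":
        agg = agg / len(rank_cols)
    elif aggregate != "sum":
        raise ValueError("aggregate must be 'sum' or 'mean'")
    out["aggregate"] = agg
    order_positions = np.argsort(agg, kind="stable")
    order = np.empty(len(out), dtype=int)
    order[order_positions] = np.arange(1, len(out) + 1)
    out["order"] = order
    counts = pd.Series(agg).value_counts()
    out["tied"] = [counts[v] > 1 for v in agg]
    return out
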
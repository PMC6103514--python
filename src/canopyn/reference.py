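"""Reference calibration shipped with the package.

These are the published statistics of the original sandalwood field
calibration this package's method reproduces: seven candidate models (the
families/color systems whose modeling R^2 exceeded 0.9 with a GS_MCC
term), each fitted on 48 modeling samples by both least squares (LSM) and
the errors-in-variables estimator (EIV) and evaluated on 24 held-out
validation samples.  The underlying 72-sample dataset is not deposited, so
these numbers serve as worked-example inputs — e.g. for the ranking
procedure and for consistency checks of the evaluation statistics — not as
refittable ground truth.

``mean_residual``/``residual_variance`` are the validation e-bar and
delta^2; ``rmse`` is the tabulated sqrt(e-bar^2 + delta^2).
"""
from __future__ import annotations

import pandas as pd

__all__ = [
    "REFERENCE_CANDIDATES",
    "reference_candidate_frame",
    "REFERENCE_FINAL_VALIDATION",
]

#: Seven candidates: per estimator, modeling (r2, mean_residual) and
#: validation (mean_residual, residual_variance, rmse, r2).
REFERENCE_CANDIDATES = [
    {
        "name": "reciprocal-Lab",
        "family": "reciprocal", "system": "Lab",
        "lsm": {"modeling_r2": 0.902, "modeling_mean_residual": -0.226,
                "validation_mean_residual": -0.2209,
                "validation_residual_variance": 4.7656,
                "validation_rmse": 2.1942, "validation_r2": 0.8718},
        "eiv": {"modeling_r2": 0.906, "modeling_mean_residual": -0.219,
                "validation_mean_residual": -0.2039,
                "validation_residual_variance": 4.2941,
                "validation_rmse": 2.0822, "validation_r2": 0.8956},
    },
    {
        "name": "power-RGB",
        "family": "power", "system": "RGB",
        "lsm": {"modeling_r2": 0.904, "modeling_mean_residual": -0.234,
                "validation_mean_residual": -0.2181,
                "validation_residual_variance": 4.2335,
                "validation_rmse": 2.0691, "validation_r2": 0.8901},
        "eiv": {"modeling_r2": 0.915, "modeling_mean_residual": -0.221,
                "validation_mean_residual": -0.1593,
                "validation_residual_variance": 4.0193,
                "validation_rmse": 2.0111, "validation_r2": 0.8991},
    },
    {
        "name": "power-Lab",
        "family": "power", "system": "Lab",
        "lsm": {"modeling_r2": 0.904, "modeling_mean_residual": -0.158,
                "validation_mean_residual": -0.0938,
                "validation_residual_variance": 4.4567,
                "validation_rmse": 2.1132, "validation_r2": 0.8793},
        "eiv": {"modeling_r2": 0.911, "modeling_mean_residual": -0.151,
                "validation_mean_residual": -0.0791,
                "validation_residual_variance": 4.3941,
                "validation_rmse": 2.0977, "validation_r2": 0.8957},
    },
    {
        "name": "logarithmic-RGB",
        "family": "logarithmic", "system": "RGB",
        "lsm": {"modeling_r2": 0.900, "modeling_mean_residual": -0.239,
                "validation_mean_residual": -0.2149,
                "validation_residual_variance": 4.7802,
                "validation_rmse": 2.1969, "validation_r2": 0.8719},
        "eiv": {"modeling_r2": 0.905, "modeling_mean_residual": -0.231,
                "validation_mean_residual": -0.1843,
                "validation_residual_variance": 4.5932,
                "validation_rmse": 2.1511, "validation_r2": 0.8817},
    },
    {
        "name": "exponential-RGB",
        "family": "exponential", "system": "RGB",
        "lsm": {"modeling_r2": 0.912, "modeling_mean_residual": -0.221,
                "validation_mean_residual": -0.1991,
                "validation_residual_variance": 4.3777,
                "validation_rmse": 2.1017, "validation_r2": 0.8783},
        "eiv": {"modeling_r2": 0.916, "modeling_mean_residual": -0.212,
                "validation_mean_residual": -0.1736,
                "validation_residual_variance": 4.0183,
                "validation_rmse": 2.0121, "validation_r2": 0.9063},
    },
    {
        "name": "exponential-Lab",
        "family": "exponential", "system": "Lab",
        "lsm": {"modeling_r2": 0.913, "modeling_mean_residual": -0.274,
                "validation_mean_residual": -0.2632,
                "validation_residual_variance": 3.7496,
                "validation_rmse": 1.9542, "validation_r2": 0.8894},
        "eiv": {"modeling_r2": 0.935, "modeling_mean_residual": -0.266,
                "validation_mean_residual": -0.2494,
                "validation_residual_variance": 3.5931,
                "validation_rmse": 1.9119, "validation_r2": 0.9110},
    },
    {
        "name": "exponential-RLI",
        "family": "exponential", "system": "RLI",
        "lsm": {"modeling_r2": 0.901, "modeling_mean_residual": -0.374,
                "validation_mean_residual": -0.3514,
                "validation_residual_variance": 4.3438,
                "validation_rmse": 2.1136, "validation_r2": 0.8813},
        "eiv": {"modeling_r2": 0.908, "modeling_mean_residual": -0.312,
                "validation_mean_residual": -0.3194,
                "validation_residual_variance": 4.0384,
                "validation_rmse": 2.0348, "validation_r2": 0.8931},
    },
]

#: Validation residual statistics of the optimal (exponential-Lab, LSM/EIV)
#: model, convenient for worked examples of the evaluation formulas.
REFERENCE_FINAL_VALIDATION = {
    "lsm": {"mean_residual": -0.2632, "residual_variance": 3.7496},
    "eiv": {"mean_residual": -0.2494, "residual_variance": 3.5931},
}


def reference_candidate_frame(method: str = "eiv") -> pd.DataFrame:
    """The seven reference candidates as a rank_models-ready table."""
    if method not in ("lsm", "eiv"):
        raise ValueError("method must be 'lsm' or 'eiv'")
    rows = []
    for cand in REFERENCE_CANDIDATES:
        row = {"name": cand["name"], **cand[method]}
        rows.append(row)
    return pd.DataFrame(rows).set_index("name")
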
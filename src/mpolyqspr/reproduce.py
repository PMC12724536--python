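"""Recompute the published metric tables from the embedded predictions.

Fit metrics (R^2, MSE, RMSE, MAE) are recomputed over the 19 training
pairs; residual metrics (mean residual, n-1 Std, linear-interpolation
IQR) over the 29 pooled train+test pairs.  Each recomputed cell is
compared with the published value at a relative tolerance that reflects
print rounding.

One known inconsistency is handled explicitly: the published residual
metrics for the MR (molar refractivity) property cannot be regenerated
from the published MR predictions themselves (the recomputed values
disagree by orders of magnitude, e.g. tuned-SVR Std ~0.095 vs the
published 3.0387, while every COM cell regenerates cleanly).  Those cells
are reported with status ``paper-inconsistent`` rather than ``fail`` so
the discrepancy stays visible without masking genuine regressions.
"""

from __future__ import annotations

import pandas as pd

from . import metrics
from .fixtures import (
    PUBLISHED_FIT_METRICS,
    PUBLISHED_RESIDUAL_METRICS,
    load_fixtures,
    prediction_set,
)

__all__ = ["reproduce_tables", "RTOL_DEFAULT"]

#: print-rounding tolerance: published cells carry 4-10 significant digits
RTOL_DEFAULT = 0.005

_FIT_FUNCS = {"r2": metrics.r2, "mse": metrics.mse, "rmse": metrics.rmse, "mae": metrics.mae}
_RESID_NAMES = ("mean_residual", "std_residual", "iqr_residual")


def reproduce_tables(rtol: float = RTOL_DEFAULT) -> pd.DataFrame:
    """Recompute every published COM/MR metric cell and grade it.

    Returns a DataFrame with one row per cell: metric, property, model,
    sample convention, published value, recomputed value, relative error
    and status (``pass`` / ``paper-inconsistent`` / ``fail``).
    """
    fx = load_fixtures()
    rows = []
    for (metric_name, prop, model), published in PUBLISHED_FIT_METRICS.items():
        p = prediction_set(fx, prop, model, "train")
        value = _FIT_FUNCS[metric_name](p)
        rows.append(_grade(metric_name, prop, model, "train", published, value, rtol))
    for (metric_name, prop, model), published in PUBLISHED_RESIDUAL_METRICS.items():
        p = prediction_set(fx, prop, model, "combined")
        mr, std, iqr = metrics.residual_metrics(p)
        value = {"mean_residual": mr, "std_residual": std, "iqr_residual": iqr}[metric_name]
        rows.append(_grade(metric_name, prop, model, "combined", published, value, rtol))
    return pd.DataFrame(rows)


def _grade(metric_name, prop, model, sample, published, value, rtol) -> dict:
    rel_err = abs(value - published) / max(abs(published), 1e-12)
    if rel_err <= rtol:
        status = "pass"
    elif prop == "MR" and metric_name in _RESID_NAMES:
        # the documented publication inconsistency, not a pipeline failure
        status = "paper-inconsistent"
    else:
        status = "fail"
    return {
        "metric": metric_name,
        "property": prop,
        "model": model,
        "sample": sample,
        "published": published,
        "recomputed": value,
        "rel_err": rel_err,
        "status": status,
    }
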
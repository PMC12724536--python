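"""Regression evaluation statistics and residual diagnostics.

Seven statistics over a set of (actual y_i, predicted yhat_i) pairs:

    MSE  = (1/n) sum (y_i - yhat_i)^2
    RMSE = sqrt(MSE)
    MAE  = (1/n) sum |y_i - yhat_i|
    R^2  = 1 - SSE/SST,  SST = sum (y_i - ybar)^2
    MR   = mean residual, r_i = y_i - yhat_i
    Std  = sample standard deviation of residuals (n-1 denominator)
    IQR  = Q3 - Q1 of residuals, linear-interpolation quantiles
           (quantile q located at rank (n-1)q)

The residual sign convention r = actual - predicted means a model that
over-predicts shows a negative mean residual.  Two evaluation conventions
are used by the study this package reproduces: fit metrics over the
training pairs alone, and residual metrics over the pooled train+test
pairs — callers pick the sample via the PredictionSet label, nothing is
pooled implicitly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .models import PredictionSet

__all__ = [
    "MetricReport",
    "mse",
    "rmse",
    "mae",
    "r2",
    "residual_metrics",
    "metric_report",
    "error_distribution",
    "residual_vs_predicted",
]


@dataclass(frozen=True)
class MetricReport:
    sample: str
    n: int
    mse: float
    rmse: float
    mae: float
    r2: float
    mean_residual: float
    std_residual: float
    iqr_residual: float
    q1: float
    q3: float

    def to_dict(self) -> dict:
        return asdict(self)


def mse(p: PredictionSet) -> float:
    return float(np.mean((p.actual - p.predicted) ** 2))


def rmse(p: PredictionSet) -> float:
    return float(np.sqrt(mse(p)))


def mae(p: PredictionSet) -> float:
    return float(np.mean(np.abs(p.actual - p.predicted)))


def r2(p: PredictionSet) -> float:
    """Coefficient of determination; undefined (rejected) when SST = 0."""
    if p.n < 2:
        raise ValueError("R^2 needs at least 2 pairs")
    sst = float(np.sum((p.actual - p.actual.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: actual values are all equal (SST = 0)")
    sse = float(np.sum((p.actual - p.predicted) ** 2))
    return 1.0 - sse / sst


def residual_metrics(p: PredictionSet) -> tuple[float, float, float]:
    """(mean residual, n-1 std of residuals, linear-interpolation IQR)."""
    if p.n < 2:
        raise ValueError("residual metrics need at least 2 pairs")
    r = p.residuals
    q1, q3 = np.percentile(r, [25.0, 75.0], method="linear")
    return float(np.mean(r)), float(np.std(r, ddof=1)), float(q3 - q1)


def metric_report(p: PredictionSet) -> MetricReport:
    """All seven statistics for one prediction set."""
    r = p.residuals
    q1, q3 = np.percentile(r, [25.0, 75.0], method="linear")
    mr, std, iqr = residual_metrics(p)
    return MetricReport(
        sample=p.label,
        n=p.n,
        mse=mse(p),
        rmse=rmse(p),
        mae=mae(p),
        r2=r2(p),
        mean_residual=mr,
        std_residual=std,
        iqr_residual=iqr,
        q1=float(q1),
        q3=float(q3),
    )


def error_distribution(p: PredictionSet, bins: int = 10) -> dict[str, np.ndarray]:
    """Plot-ready histogram + Gaussian-KDE summary of the residuals.

    Returns bin edges, counts, a density grid and density values;
    rendering is a thin consumer of these arrays.
    """
    if p.n < 2:
        raise ValueError("error distribution needs at least 2 pairs")
    r = p.residuals
    counts, edges = np.histogram(r, bins=bins)
    lo, hi = r.min(), r.max()
    pad = 0.5 * (hi - lo) if hi > lo else max(abs(hi), 1.0)
    grid = np.linspace(lo - pad, hi + pad, 256)
    spread = np.std(r, ddof=1)
    if spread == 0.0:
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - r[0]))] = 1.0
    else:
        # Silverman bandwidth; plain Gaussian kernel density
        bw = 1.06 * spread * p.n ** (-1 / 5)
        z = (grid[:, None] - r[None, :]) / bw
        density = np.exp(-0.5 * z**2).sum(axis=1) / (p.n * bw * np.sqrt(2 * np.pi))
    return {"bin_edges": edges, "counts": counts, "grid": grid, "density": density}


def residual_vs_predicted(p: PredictionSet) -> dict[str, np.ndarray]:
    """(yhat_i, r_i) pairs for residual-vs-predicted diagnostics."""
    return {"predicted": p.predicted.copy(), "residual": p.residuals}
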
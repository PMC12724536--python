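"""Property tables and the preprocessing chain.

A property table is a pandas DataFrame indexed by compound id, optionally
carrying a ``formula`` label column, then feature columns (topological
indices plus auxiliary descriptors) and target columns (COM, MR, MV, MW,
PO on their natural scales).

The preprocessing order is fixed: median imputation, then IQR outlier
removal on feature columns, then min-max scaling whose statistics are fit
on training rows only — test rows are transformed with the training
statistics and are deliberately not clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitDataset",
    "read_property_table",
    "write_property_table",
    "impute_median",
    "remove_outliers_iqr",
    "minmax_scale",
    "split",
    "hold_out",
]

TARGETS: tuple[str, ...] = ("COM", "MR", "MV", "MW", "PO")


@dataclass(frozen=True)
class SplitDataset:
    """A train/test partition of a property table."""

    train: pd.DataFrame
    test: pd.DataFrame
    split_seed: int | None = None
    fraction: float | None = None


def read_property_table(path) -> pd.DataFrame:
    """Read a property-table CSV.

    Layout: first column ``id``, optional second column ``formula``, then
    numeric feature and target columns.  Missing values are empty cells;
    numbers may contain thousands-commas and are parsed numerically.
    """
    df = pd.read_csv(path, index_col=0, thousands=",")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate compound ids: {dup}")
    return df


def write_property_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, float_format="%.6f")


def _numeric_columns(df: pd.DataFrame, columns) -> list[str]:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    return list(columns)


def impute_median(t: pd.DataFrame, columns) -> pd.DataFrame:
    """Replace missing cells by the column median over non-missing values."""
    columns = _numeric_columns(t, columns)
    out = t.copy()
    for c in columns:
        col = out[c]
        if col.isna().all():
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
        out[c] = col.fillna(col.median())
    return out


def remove_outliers_iqr(
    t: pd.DataFrame, columns, k: float = 1.5
) -> tuple[pd.DataFrame, list]:
    """Drop rows outside [Q1 - k*IQR, Q3 + k*IQR] in any named column.

    Quartiles use the linear-interpolation convention (quantile q at rank
    (n-1)q).  Returns the surviving table and the dropped ids.
    """
    if k <= 0:
        raise ValueError(f"IQR multiplier k must be positive, got {k}")
    columns = _numeric_columns(t, columns)
    if not columns:
        return t.copy(), []
    mask = pd.Series(True, index=t.index)
    for c in columns:
        col = t[c].astype(float)
        if col.isna().any():
            raise ValueError(f"column {c!r} has missing values; impute first")
        q1, q3 = col.quantile([0.25, 0.75], interpolation="linear")
        iqr = q3 - q1
        mask &= (col >= q1 - k * iqr) & (col <= q3 + k * iqr)
    dropped = t.index[~mask].tolist()
    return t.loc[mask].copy(), dropped


def minmax_scale(
    fit_on: pd.DataFrame, apply_to: pd.DataFrame, columns
) -> pd.DataFrame:
    """x -> (x - min_fit) / (max_fit - min_fit), statistics from ``fit_on``.

    Training data lands in [0, 1]; out-of-range values in ``apply_to`` are
    not clipped.  Constant fit columns scale to 0 everywhere.
    """
    columns = _numeric_columns(fit_on, columns)
    _numeric_columns(apply_to, columns)
    out = apply_to.copy()
    for c in columns:
        lo = fit_on[c].min()
        hi = fit_on[c].max()
        if hi > lo:
            out[c] = (apply_to[c] - lo) / (hi - lo)
        else:
            out[c] = 0.0
    return out


def split(t: pd.DataFrame, fraction: float = 0.8, seed: int = 0) -> SplitDataset:
    """Uniformly random train/test partition, deterministic per seed.

    Train size is round(fraction * n) clamped to [1, n-1].
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(t)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.clip(round(fraction * n), 1, n - 1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    return SplitDataset(
        train=t.iloc[train_idx].copy(),
        test=t.iloc[test_idx].copy(),
        split_seed=seed,
        fraction=fraction,
    )


def hold_out(train: pd.DataFrame, test: pd.DataFrame) -> SplitDataset:
    """Wrap a pre-specified external train/test pair (e.g. the 19/10 design)."""
    if len(test) == 0 or len(train) == 0:
        raise ValueError("hold-out train and test tables must be nonempty")
    overlap = train.index.intersection(test.index)
    if len(overlap):
        raise ValueError(f"train/test ids overlap: {overlap.tolist()}")
    return SplitDataset(train=train.copy(), test=test.copy())
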
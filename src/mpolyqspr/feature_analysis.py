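"""Feature selection, importances and leave-one-feature-out ablation.

Recursive feature elimination wraps a random forest: fit, drop the
lowest-importance feature, repeat until the requested number remain
(one elimination per round).  Importances are the forest's normalized
impurity-based weights.  The ablation study retrains the models once per
removed feature and reports test RMSE against an all-selected-features
baseline under an internal random train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .dataset import minmax_scale, split
from .models import FittedModel, ModelSpec, default_spec, predict, train

__all__ = [
    "FeatureImportanceReport",
    "rfe_select",
    "feature_importances",
    "ablation_study",
]


@dataclass(frozen=True)
class FeatureImportanceReport:
    target: str
    ranking: tuple[tuple[str, float], ...]  # (feature, weight), descending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["feature", "importance"])


def feature_importances(m: FittedModel, target: str = "") -> FeatureImportanceReport:
    """Normalized impurity importances of a fitted random forest, descending.

    Ties keep training column order (stable sort).
    """
    if m.spec.kind != "rf":
        raise ValueError(f"feature importances require an rf model, got {m.spec.kind!r}")
    imp = np.asarray(m.estimator.feature_importances_, dtype=float)
    order = np.argsort(-imp, kind="stable")
    ranking = tuple((m.feature_names[i], float(imp[i])) for i in order)
    return FeatureImportanceReport(target=target, ranking=ranking)


def rfe_select(
    t: pd.DataFrame,
    target: str,
    features: list[str],
    n_keep: int = 5,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination with a random-forest estimator.

    Iteratively fits an RF on the surviving features and drops the single
    lowest-importance one until ``n_keep`` remain.  Deterministic given
    the seed; ties break toward dropping the later column.
    """
    if n_keep >= len(features):
        raise ValueError(
            f"n_keep={n_keep} must be smaller than the candidate count {len(features)}"
        )
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if target in features:
        raise ValueError(f"target {target!r} must not appear among candidate features")
    surviving = list(features)
    spec = default_spec("rf", seed=seed)
    while len(surviving) > n_keep:
        fitted = train(spec, t, target, surviving)
        imp = np.asarray(fitted.estimator.feature_importances_)
        # last index among the minima -> drop the later column on ties
        worst = len(imp) - 1 - int(np.argmin(imp[::-1]))
        surviving.pop(worst)
    return surviving


def ablation_study(
    t: pd.DataFrame,
    target: str,
    selected: list[str],
    specs: dict[str, ModelSpec] | None = None,
    seed: int = 0,
    fraction: float = 0.8,
) -> pd.DataFrame:
    """Leave-one-feature-out retraining; RMSE per removed feature.

    For each feature f in ``selected``, each model is retrained on
    ``selected`` minus f and scored (RMSE) on the test side of an internal
    random split; the first row, labelled ``(baseline)``, keeps all
    selected features.  Features are min-max scaled on the training side
    of the split.
    """
    if not selected:
        raise ValueError("ablation needs a nonempty selected feature set")
    missing = [f for f in selected if f not in t.columns]
    if missing:
        raise KeyError(f"selected features not in table: {missing}")
    if specs is None:
        specs = {
            "rf": default_spec("rf", seed=seed),
            "svr_tuned": default_spec("svr_tuned", seed=seed),
        }
    parts = split(t, fraction=fraction, seed=seed)
    tr = minmax_scale(parts.train, parts.train, selected)
    te = minmax_scale(parts.train, parts.test, selected)
    tr[target] = parts.train[target]
    te[target] = parts.test[target]

    def _rmse_for(feats: list[str]) -> dict[str, float]:
        out = {}
        for name, spec in specs.items():
            fitted = train(spec, tr, target, feats)
            out[f"rmse_{name}"] = metrics.rmse(predict(fitted, te, target))
        return out

    rows = [{"removed": "(baseline)", **_rmse_for(list(selected))}]
    for f in selected:
        feats = [g for g in selected if g != f]
        if not feats:
            raise ValueError("cannot ablate the only selected feature")
        rows.append({"removed": f, **_rmse_for(feats)})
    return pd.DataFrame(rows).set_index("removed")
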
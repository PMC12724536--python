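"""Seeded simulation studies that validate the pipeline's behaviour.

These are the package's standard self-checks on synthetic data: parameter
recovery by the tuned SVR, the qualitative model ordering the published
study reports (tuned SVR >= random forest >= untuned SVR in median test
R^2), recursive-feature-elimination recovery of a planted signal against
pure-noise decoys, ablation of the sole informative feature, and the
tree-ensemble range property (forest predictions cannot leave the
training-target range).

The recovery construction is near-noiseless by design — the target is a
fixed smooth function of the first Zagreb index, y = 2*M1 + 0.05*M1^2,
with noise at 1e-6 of the signal spread — so failures indicate pipeline
defects rather than sampling luck.  Because the nine indices are strongly
collinear across random graphs (they all scale with molecular size),
identifiability questions (RFE, ablation) are posed against independent
noise decoys rather than against near-duplicate sibling indices.
"""

from __future__ import annotations

import numpy as np

from . import metrics
from .dataset import minmax_scale, split
from .feature_analysis import ablation_study, rfe_select
from .models import default_spec, predict, train
from .synthetic import SimulationConfig, simulate_property_table

__all__ = [
    "recovery_config",
    "model_ordering_study",
    "rfe_recovery_study",
    "ablation_strictness_study",
    "rf_range_study",
]

#: the planted signal: a smooth, monotone, nonlinear function of M1
RECOVERY_TARGET: dict[str, dict[str, float]] = {"y": {"M1": 2.0, "M1^2": 0.05}}

#: RFE candidates: the generating index, the three auxiliary descriptors,
#: and six independent noise decoys (ten candidates, five kept)
RFE_CANDIDATES = ("M1", "BP", "DE", "IR", "N1", "N2", "N3", "N4", "N5", "N6")

#: ablation set: the sole informative feature plus four noise decoys
ABLATION_SELECTED = ("M1", "N1", "N2", "N3", "N4")


def recovery_config(seed: int) -> SimulationConfig:
    """Near-noiseless study-shaped table with noise decoys, per seed."""
    return SimulationConfig(
        targets={k: dict(v) for k, v in RECOVERY_TARGET.items()},
        noise_sd=1e-6,
        n_noise_features=6,
        seed=seed,
    )


def _split_scaled(table, features, seed):
    parts = split(table, fraction=0.8, seed=seed)
    tr = minmax_scale(parts.train, parts.train, features)
    te = minmax_scale(parts.train, parts.test, features)
    tr["y"] = parts.train["y"]
    te["y"] = parts.test["y"]
    return tr, te


def model_ordering_study(n_replicates: int = 20, base_seed: int = 0) -> dict:
    """Train/test R^2 of the three models over seeded replicates.

    Returns per-model test-R^2 medians, the minimum tuned-SVR training
    R^2, and whether the median ordering svr_tuned >= rf >= svr_basic
    holds.
    """
    test_r2: dict[str, list[float]] = {"svr_tuned": [], "rf": [], "svr_basic": []}
    tuned_train: list[float] = []
    for rep in range(n_replicates):
        seed = base_seed + rep
        table, truth = simulate_property_table(recovery_config(seed))
        feats = truth["feature_columns"]
        tr, te = _split_scaled(table, feats, seed)
        for kind in test_r2:
            fitted = train(default_spec(kind, seed=seed), tr, "y", feats)
            if kind == "svr_tuned":
                tuned_train.append(metrics.r2(predict(fitted, tr, "y", "train")))
            test_r2[kind].append(metrics.r2(predict(fitted, te, "y")))
    medians = {k: float(np.median(v)) for k, v in test_r2.items()}
    return {
        "median_test_r2": medians,
        "min_tuned_train_r2": float(min(tuned_train)),
        "ordering_holds": medians["svr_tuned"] >= medians["rf"] >= medians["svr_basic"],
    }


def rfe_recovery_study(n_replicates: int = 20, base_seed: int = 0) -> dict:
    """Fraction of replicates whose RFE keeps the generating feature."""
    hits = 0
    for rep in range(n_replicates):
        seed = base_seed + rep
        table, _ = simulate_property_table(recovery_config(seed))
        selected = rfe_select(table, "y", list(RFE_CANDIDATES), n_keep=5, seed=seed)
        hits += "M1" in selected
    return {"recovery_rate": hits / n_replicates, "n_replicates": n_replicates}


def ablation_strictness_study(n_replicates: int = 3, base_seed: int = 0) -> dict:
    """Does removing the sole informative feature strictly raise RMSE?

    Checks both the random forest and the tuned SVR against the
    all-features baseline; returns per-model strictness fractions and the
    RMSE ratios (removed / baseline) of the last replicate.
    """
    strict = {"rf": 0, "svr_tuned": 0}
    ratios = {}
    for rep in range(n_replicates):
        seed = base_seed + rep
        table, _ = simulate_property_table(recovery_config(seed))
        report = ablation_study(table, "y", list(ABLATION_SELECTED), seed=seed)
        base = report.loc["(baseline)"]
        for model in strict:
            col = f"rmse_{model}"
            strict[model] += report.loc["M1", col] > base[col]
            ratios[model] = float(report.loc["M1", col] / base[col])
    return {
        "strict_fraction": {k: v / n_replicates for k, v in strict.items()},
        "last_rmse_ratio": ratios,
        "n_replicates": n_replicates,
    }


def rf_range_study(n_replicates: int = 20, base_seed: int = 0) -> dict:
    """Forest predictions stay within [min, max] of the training target."""
    violations = 0
    for rep in range(n_replicates):
        seed = base_seed + rep
        table, truth = simulate_property_table(recovery_config(seed))
        feats = truth["feature_columns"]
        tr, te = _split_scaled(table, feats, seed)
        fitted = train(default_spec("rf", seed=seed), tr, "y", feats)
        yhat = predict(fitted, te, "y").predicted
        lo, hi = tr["y"].min(), tr["y"].max()
        violations += int(np.any(yhat < lo) or np.any(yhat > hi))
    return {"runs_with_violations": violations, "n_replicates": n_replicates}
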
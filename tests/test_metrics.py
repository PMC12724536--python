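"""The seven evaluation statistics against a naive loop oracle and the
published-table conventions."""

import math

import numpy as np
import pytest
from sklearn.metrics import mean_squared_error, r2_score

from mpolyqspr import metrics
from mpolyqspr.fixtures import load_fixtures, prediction_set
from mpolyqspr.models import PredictionSet


def pset(actual, predicted, label="test"):
    n = len(actual)
    return PredictionSet(
        label=label,
        ids=tuple(range(n)),
        actual=np.asarray(actual, float),
        predicted=np.asarray(predicted, float),
    )


def oracle(actual, predicted):
    """Pure-loop reimplementation of all seven statistics."""
    n = len(actual)
    resid = [a - p for a, p in zip(actual, predicted)]
    ms = sum(r * r for r in resid) / n
    ybar = sum(actual) / n
    sst = sum((a - ybar) ** 2 for a in actual)
    mr = sum(resid) / n
    std = math.sqrt(sum((r - mr) ** 2 for r in resid) / (n - 1)) if n > 1 else 0.0

    def quantile(xs, q):
        xs = sorted(xs)
        pos = (len(xs) - 1) * q
        lo, hi = int(math.floor(pos)), int(math.ceil(pos))
        return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)

    return {
        "mse": ms,
        "rmse": math.sqrt(ms),
        "mae": sum(abs(r) for r in resid) / n,
        "r2": 1 - sum(r * r for r in resid) / sst,
        "mean_residual": mr,
        "std_residual": std,
        "iqr_residual": quantile(resid, 0.75) - quantile(resid, 0.25),
    }


class TestBasics:
    def test_hand_computed_mse(self):
        assert metrics.mse(pset([1, 2, 3], [1, 2, 4])) == pytest.approx(1 / 3)

    def test_perfect_predictions(self):
        p = pset([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        rep = metrics.metric_report(p)
        assert (rep.mse, rep.rmse, rep.mae) == (0, 0, 0)
        assert rep.r2 == 1
        assert (rep.mean_residual, rep.std_residual, rep.iqr_residual) == (0, 0, 0)

    def test_single_pair_rmse_equals_mae(self):
        p = pset([5.0], [3.0])
        assert metrics.rmse(p) == metrics.mae(p) == 2.0

    def test_predicting_the_mean_gives_zero_r2(self):
        y = [1.0, 2.0, 3.0, 6.0]
        assert metrics.r2(pset(y, [3.0] * 4)) == pytest.approx(0.0)

    def test_r2_can_be_negative(self):
        assert metrics.r2(pset([1.0, 2.0], [10.0, -10.0])) < 0

    def test_constant_actuals_rejected(self):
        with pytest.raises(ValueError, match="SST"):
            metrics.r2(pset([2.0, 2.0], [1.0, 3.0]))

    def test_constant_residuals(self):
        mr, std, iqr = metrics.residual_metrics(pset([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]))
        assert (mr, std, iqr) == (3.0, 0.0, 0.0)

    def test_residual_sign_convention(self):
        # over-prediction counts negative
        assert metrics.residual_metrics(pset([1.0, 1.0], [2.0, 3.0]))[0] < 0


class TestOracleEquivalence:
    def test_against_loop_oracle_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            scale = 10.0 ** rng.integers(-2, 4)
            y = rng.normal(0, scale, n)
            yhat = y + rng.normal(0, 0.3 * scale, n)
            if np.ptp(y) == 0:
                continue
            rep = metrics.metric_report(pset(y, yhat)).to_dict()
            exp = oracle(list(y), list(yhat))
            for key, val in exp.items():
                assert rep[key] == pytest.approx(val, rel=1e-12), key

    def test_against_sklearn_cross_check(self, rng):
        y, yhat = rng.normal(size=30), rng.normal(size=30)
        p = pset(y, yhat)
        assert metrics.mse(p) == pytest.approx(mean_squared_error(y, yhat), rel=1e-12)
        assert metrics.r2(p) == pytest.approx(r2_score(y, yhat), rel=1e-12)

    def test_translation_invariance_of_error_metrics(self, rng):
        y, yhat = rng.normal(size=25), rng.normal(size=25)
        a, b = pset(y, yhat), pset(y + 17.3, yhat + 17.3)
        for f in (metrics.mse, metrics.rmse, metrics.mae):
            assert f(a) == pytest.approx(f(b), rel=1e-12)
        assert metrics.residual_metrics(a) == pytest.approx(
            metrics.residual_metrics(b), rel=1e-9, abs=1e-9
        )


class TestPublishedConventions:
    """The two sample conventions recovered from the published tables."""

    def test_fit_metrics_use_the_19_training_pairs(self):
        fx = load_fixtures()
        p = prediction_set(fx, "COM", "svr_tuned", "train")
        assert p.n == 19
        assert metrics.mse(p) == pytest.approx(1.594848005, rel=0.005)
        assert metrics.rmse(p) == pytest.approx(1.262872917, rel=0.005)
        assert metrics.mae(p) == pytest.approx(0.883530924, rel=0.005)
        assert metrics.r2(p) == pytest.approx(0.999976452, rel=0.005)

    def test_residual_metrics_use_the_29_combined_pairs(self):
        fx = load_fixtures()
        p = prediction_set(fx, "COM", "svr_tuned", "combined")
        assert p.n == 29
        mr, std, iqr = metrics.residual_metrics(p)
        assert mr == pytest.approx(0.982566, rel=0.005)
        assert std == pytest.approx(3.159584389, rel=0.005)
        assert iqr == pytest.approx(1.4527288, rel=0.005)

    def test_training_pairs_alone_do_not_give_the_residual_values(self):
        # the pooled convention is essential: train-only residuals differ
        fx = load_fixtures()
        p = prediction_set(fx, "COM", "svr_tuned", "train")
        _, std, _ = metrics.residual_metrics(p)
        assert std != pytest.approx(3.159584389, rel=0.005)

    def test_iqr_order_statistics_of_combined_residuals(self):
        # rank-(n-1)/4 interpolated order statistics of the 29 residuals
        fx = load_fixtures()
        r = np.sort(prediction_set(fx, "COM", "svr_tuned", "combined").residuals)
        q1 = r[7]  # (29-1)*0.25 = 7 exactly
        q3 = r[21]
        assert q3 - q1 == pytest.approx(1.4527288, rel=0.005)


class TestDistributions:
    def test_histogram_counts_sum_to_n(self, rng):
        p = pset(rng.normal(size=40), rng.normal(size=40))
        dist = metrics.error_distribution(p, bins=8)
        assert dist["counts"].sum() == 40

    def test_symmetric_residuals_mode_near_zero(self, rng):
        y = rng.normal(size=500)
        p = pset(y, y + rng.normal(0, 0.5, 500))
        dist = metrics.error_distribution(p)
        assert abs(dist["grid"][np.argmax(dist["density"])]) < 0.3

    def test_basic_svr_fixture_residual_spread_is_hundreds_of_units(self):
        fx = load_fixtures()
        p = prediction_set(fx, "COM", "svr_basic", "train")
        assert np.ptp(p.residuals) > 500

    def test_residual_vs_predicted_pairs(self):
        p = pset([1.0, 2.0], [0.5, 2.5])
        rv = metrics.residual_vs_predicted(p)
        assert rv["predicted"].tolist() == [0.5, 2.5]
        assert rv["residual"].tolist() == [0.5, -0.5]
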
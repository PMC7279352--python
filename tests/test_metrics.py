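"""Unit and property tests for the validation-statistics battery.

Every statistic is checked against a literal, independent re-evaluation of
its defining formula on random instances, plus hand-computed cases.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permsvr.io import PredictionSet
from permsvr.metrics import (
    CriteriaThresholds,
    basic_metrics,
    check_criteria,
    external_metrics,
    external_report,
    loo_cv,
    origin_stats,
    r2_q2,
    rm2_family,
    s_from_rmse_mae,
    training_report,
    y_scramble,
)

from conftest import make_table


def pred_of(y, yhat, ids=None):
    y = np.asarray(y, dtype=float)
    ids = ids or [f"c{i}" for i in range(len(y))]
    return PredictionSet(ids, y, yhat)


def random_pred(rng, n=None):
    n = n or int(rng.integers(3, 30))
    y = rng.normal(-4.0, 1.0, n)
    return pred_of(y, y + rng.normal(0, 0.5, n))


class TestBasicMetrics:
    def test_perfect_predictions(self):
        rep = basic_metrics(pred_of([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert rep.rmse == rep.mae == rep.s == rep.delta_max == 0.0

    def test_hand_arithmetic(self):
        rep = basic_metrics(pred_of([0.0, 0.0], [1.0, -1.0]))
        assert rep.rmse == 1.0 and rep.mae == 1.0
        assert rep.s == 0.0 and rep.delta_max == 1.0
        assert rep.mean_residual == 0.0

    def test_literal_formula_oracle(self, rng):
        for _ in range(100):
            pred = random_pred(rng)
            rep = basic_metrics(pred)
            d = pred.observed - pred.predicted
            n = len(d)
            assert rep.rmse == pytest.approx(np.sqrt(np.sum(d**2) / n), rel=1e-12)
            assert rep.mae == pytest.approx(np.sum(np.abs(d)) / n, rel=1e-12)
            assert rep.s == pytest.approx(
                np.sqrt(np.sum((np.abs(d) - np.mean(np.abs(d))) ** 2) / (n - 1)),
                rel=1e-12,
            )

    def test_rmse_mae_s_identity(self, rng):
        """RMSE^2 = MAE^2 + ((n-1)/n) s^2 under the absolute-residual-SD
        convention for s."""
        for _ in range(100):
            rep = basic_metrics(random_pred(rng))
            n = rep.n
            assert rep.rmse**2 == pytest.approx(
                rep.mae**2 + (n - 1) / n * rep.s**2, rel=1e-10, abs=1e-14
            )
            assert rep.rmse >= rep.mae >= 0
            assert rep.delta_max >= rep.mae

    def test_s_recovery_inverse(self, rng):
        rep = basic_metrics(random_pred(rng, 20))
        assert s_from_rmse_mae(rep.rmse, rep.mae, 20) == pytest.approx(rep.s, rel=1e-10)


class TestR2Q2:
    def test_perfect_is_one(self):
        y = np.array([-4.0, -3.0, -5.0])
        assert r2_q2(pred_of(y, y)) == 1.0

    def test_mean_predictor_is_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r2_q2(pred_of(y, np.full(3, 1.0))) == 0.0

    def test_three_point_literal_oracle(self):
        y = np.array([0.0, 1.0, 2.0])
        yhat = np.array([0.1, 0.9, 2.1])
        expected = 1 - np.sum((yhat - y) ** 2) / np.sum((y - yhat.mean()) ** 2)
        assert r2_q2(pred_of(y, yhat)) == pytest.approx(expected, rel=1e-14)

    def test_strict_vs_classic_conventions(self, rng):
        pred = random_pred(rng, 15)
        strict = r2_q2(pred, "strict")
        classic = r2_q2(pred, "classic")
        y, yhat = pred.observed, pred.predicted
        assert classic == pytest.approx(
            1 - np.sum((yhat - y) ** 2) / np.sum((y - y.mean()) ** 2), rel=1e-12
        )
        assert strict != classic  # different centres in general

    def test_constant_observed_errors(self):
        with pytest.raises(ValueError):
            r2_q2(pred_of([1.0, 1.0], [1.0, 1.0]))


class TestOriginStats:
    def test_identity_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        ro2, ro2p, k, kp = origin_stats(pred_of(y, y))
        assert (ro2, ro2p, k, kp) == (1.0, 1.0, 1.0, 1.0)

    def test_doubled_prediction_halves_slope(self):
        y = np.array([1.0, 2.0, 3.0])
        _, _, k, _ = origin_stats(pred_of(y, 2 * y))
        assert k == pytest.approx(0.5)

    def test_matches_least_squares_through_origin_oracle(self, rng):
        for _ in range(100):
            pred = random_pred(rng, 10)
            y, yhat = pred.observed, pred.predicted
            ro2, ro2p, k, kp = origin_stats(pred)
            # oracle: numpy least squares with no intercept
            k_ls = np.linalg.lstsq(yhat[:, None], y, rcond=None)[0][0]
            kp_ls = np.linalg.lstsq(y[:, None], yhat, rcond=None)[0][0]
            assert k == pytest.approx(k_ls, rel=1e-10)
            assert kp == pytest.approx(kp_ls, rel=1e-10)
            assert ro2 == pytest.approx(
                1 - np.sum((y - k_ls * yhat) ** 2) / np.sum((y - y.mean()) ** 2),
                rel=1e-10,
            )
            assert ro2p == pytest.approx(
                1 - np.sum((yhat - kp_ls * y) ** 2) / np.sum((yhat - yhat.mean()) ** 2),
                rel=1e-10,
            )


class TestRm2Family:
    def test_published_training_row(self):
        # rm2=0.88, r'm2=0.90 -> mean 0.89, delta 0.02
        _, _, mean, delta = rm2_family(1.0, 1.0, 1.0)
        assert (mean, delta) == (1.0, 0.0)
        rm2, rm2p = 0.88, 0.90
        assert (rm2 + rm2p) / 2 == pytest.approx(0.89)
        assert abs(rm2 - rm2p) == pytest.approx(0.02)

    def test_zero_gap_returns_r2(self):
        rm2, rm2p, mean, delta = rm2_family(0.8, 0.8, 0.8)
        assert rm2 == rm2p == mean == pytest.approx(0.8)
        assert delta == 0.0

    def test_literal_formula(self, rng):
        for _ in range(100):
            r2, ro2, ro2p = rng.uniform(0, 1, 3)
            rm2, rm2p, mean, delta = rm2_family(r2, ro2, ro2p)
            assert rm2 == pytest.approx(r2 * (1 - abs(r2 - ro2)), rel=1e-14)
            assert rm2p == pytest.approx(r2 * (1 - abs(r2 - ro2p)), rel=1e-14)
            assert mean == pytest.approx((rm2 + rm2p) / 2, rel=1e-14)
            assert delta == pytest.approx(abs(rm2 - rm2p), rel=1e-14)


class TestExternalMetrics:
    def test_perfect_predictions_all_one(self, rng):
        y = rng.normal(size=8)
        qf12, qf22, qf32, ccc = external_metrics(pred_of(y, y), rng.normal(size=20))
        assert qf12 == qf22 == qf32 == ccc == 1.0

    def test_equal_means_make_qf1_equal_qf2(self, rng):
        y_ext = np.array([-4.0, -3.0, -5.0, -4.0])
        y_tr = np.array([-4.5, -3.5, -4.0, -4.0])  # same mean -4.0
        qf12, qf22, _, _ = external_metrics(
            pred_of(y_ext, y_ext + 0.3), y_tr
        )
        assert qf12 == pytest.approx(qf22, rel=1e-12)

    def test_five_point_literal_oracle(self, rng):
        for _ in range(100):
            y = rng.normal(-4, 1, 5)
            yhat = y + rng.normal(0, 0.4, 5)
            y_tr = rng.normal(-4, 1, 12)
            qf12, qf22, qf32, ccc = external_metrics(pred_of(y, yhat), y_tr)
            press = np.sum((y - yhat) ** 2)
            assert qf12 == pytest.approx(
                1 - press / np.sum((y - y_tr.mean()) ** 2), rel=1e-12
            )
            assert qf22 == pytest.approx(
                1 - press / np.sum((y - y.mean()) ** 2), rel=1e-12
            )
            assert qf32 == pytest.approx(
                1 - (press / 5) / (np.sum((y_tr - y_tr.mean()) ** 2) / 12), rel=1e-12
            )
            num = 2 * np.sum((y - y.mean()) * (yhat - yhat.mean()))
            den = (
                np.sum((y - y.mean()) ** 2)
                + np.sum((yhat - yhat.mean()) ** 2)
                + 5 * (y.mean() - yhat.mean()) ** 2
            )
            assert ccc == pytest.approx(num / den, rel=1e-12)

    def test_qf1_always_at_least_qf2(self, rng):
        """The training mean can only enlarge the reference sum of squares."""
        for _ in range(100):
            pred = random_pred(rng, 8)
            qf12, qf22, _, _ = external_metrics(pred, rng.normal(-3, 2, 15))
            assert qf12 >= qf22 - 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_ccc_bounded_and_exact_at_identity(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=6)
        yhat = rng.normal(size=6)
        if np.ptp(y) == 0 or np.ptp(yhat) == 0:
            return
        *_, ccc = external_metrics(pred_of(y, yhat), rng.normal(size=10))
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12
        *_, ccc_id = external_metrics(pred_of(y, y.copy()), rng.normal(size=10))
        assert ccc_id == pytest.approx(1.0)


class TestLooCv:
    class _MeanModel:
        def __init__(self, mean):
            self.mean = mean

        def predict(self, table):
            return np.full(table.n, self.mean)

    def test_matches_manual_loop_on_small_linear_data(self, rng):
        from permsvr.svr import SVRSpec, train_svr

        X = rng.normal(size=(8, 2))
        y = 0.9 * X[:, 0] - 0.4 * X[:, 1]
        t = make_table(X, y=y)
        spec = SVRSpec("epsilon", 100.0, 0.5, epsilon=0.01, subset=("d0", "d1"))
        factory = lambda tb, yy: train_svr(tb, yy, spec)
        got = loo_cv(t, y, factory)
        # manual loop oracle
        preds = np.empty(8)
        for i in range(8):
            keep = [t.ids[j] for j in range(8) if j != i]
            m = train_svr(t.select_rows(keep), np.delete(y, i), spec)
            preds[i] = m.predict(t.select_rows([t.ids[i]]))[0]
        expected = 1 - np.sum((preds - y) ** 2) / np.sum((y - preds.mean()) ** 2)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_mean_predictor_bounded_by_zero(self, rng):
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        t = make_table(X, y=y)
        factory = lambda tb, yy: self._MeanModel(np.mean(yy))
        assert loo_cv(t, y, factory, convention="classic") <= 0

    def test_deterministic(self, rng):
        from permsvr.svr import SVRSpec, train_svr

        X = rng.normal(size=(9, 2))
        y = X[:, 0] + 0.1 * rng.normal(size=9)
        t = make_table(X, y=y)
        spec = SVRSpec("nu", 10.0, 0.5, nu=0.5, subset=("d0", "d1"))
        factory = lambda tb, yy: train_svr(tb, yy, spec)
        assert loo_cv(t, y, factory) == loo_cv(t, y, factory)


class TestYScramble:
    def test_default_round_count(self, rng):
        t = make_table(rng.normal(size=(12, 2)))
        y = rng.normal(size=12)
        factory = lambda tb, yy: TestLooCv._MeanModel(np.mean(yy))
        mean, rounds = y_scramble(t, y, factory, seed=0)
        assert len(rounds) == 25

    def test_permutation_preserves_response_multiset(self, rng):
        seen = []

        class Spy:
            def __init__(self, yy):
                seen.append(np.sort(yy))

            def predict(self, table):
                return np.zeros(table.n) + 1e-6 * np.arange(table.n)

        t = make_table(rng.normal(size=(10, 2)))
        y = rng.normal(size=10)
        y_scramble(t, y, lambda tb, yy: Spy(yy), n_rounds=5, seed=1)
        for s in seen:
            np.testing.assert_allclose(s, np.sort(y))


class TestCheckCriteria:
    def _good_reports(self, rng):
        y = rng.normal(-4, 1, 30)
        tr = training_report(pred_of(y, y.copy()), qcv2=1.0)
        y2 = rng.normal(-4, 1, 10)
        ex = external_report(pred_of(y2, y2.copy()), y)
        return tr, ex

    def test_perfect_predictions_pass_everything(self, rng):
        tr, ex = self._good_reports(rng)
        verdicts = check_criteria(training=tr, external=ex)
        assert verdicts["training"].overall_pass
        assert verdicts["external"].overall_pass

    def test_applicability_pattern(self, rng):
        tr, ex = self._good_reports(rng)
        verdicts = check_criteria(training=tr, external=ex)
        assert not verdicts["training"]["concordance"].applicable
        assert verdicts["training"]["loo_agreement"].applicable
        assert not verdicts["external"]["loo_agreement"].applicable
        assert verdicts["external"]["concordance"].applicable

    def test_published_conforming_test_set_values_pass(self):
        """External-set statistics at the level of a strong published model
        (q2 0.81, qF 0.75-0.85, CCC 0.89, rm2 0.66, <rm2> 0.70, k 0.99)
        pass every applicable criterion."""
        from permsvr.metrics import MetricsReport

        rep = MetricsReport(
            context="external", n=13, r2=0.81, qf12=0.75, qf22=0.75, qf32=0.85,
            ccc=0.89, ro2=0.75, ro2_prime=0.80, k=0.99, rm2=0.66, rm2_prime=0.74,
            rm2_mean=0.70, rm2_delta=0.08,
        )
        verdict = check_criteria(external=rep)["external"]
        assert verdict.overall_pass

    def test_low_external_q2_fails_correlation_floor(self):
        from permsvr.metrics import MetricsReport

        rep = MetricsReport(
            context="external", n=13, r2=0.40, qf12=0.15, qf22=0.15, qf32=0.50,
            ccc=0.55, ro2=0.30, ro2_prime=0.35, k=1.0, rm2=0.3, rm2_prime=0.3,
            rm2_mean=0.3, rm2_delta=0.0,
        )
        verdict = check_criteria(external=rep)["external"]
        assert not verdict["correlation_floor"].passed
        assert not verdict.overall_pass

    def test_missing_qcv2_errors(self, rng):
        y = rng.normal(size=10)
        tr = training_report(pred_of(y, y + 0.01 * rng.normal(size=10)))
        with pytest.raises(ValueError, match="qcv2"):
            check_criteria(training=tr)

    def test_thresholds_configurable(self, rng):
        tr, ex = self._good_reports(rng)
        th = CriteriaThresholds(min_correlation=1.01)
        assert not check_criteria(external=ex, thresholds=th)["external"].overall_pass
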
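"""Metric suite: exactness against oracles, invariants, sign conventions."""

import math

import numpy as np
import pytest
from scipy.stats import norm, rankdata, spearmanr

from potency_uq import (
    CalibrationCurve,
    ErrorVarianceRanking,
    PredictionSet,
    SyntheticPredictionConfig,
    absolute_miscalibration_area,
    calibration_curve,
    expected_coverage,
    generate_prediction_set,
    miscalibration_area,
    mse,
    nll,
    r_squared,
    spearman_rho,
    uq_report,
)
from potency_uq.uq_metrics import MetricUnavailableError, UndefinedMetricError


def make_ps(y, pred, var=None):
    return PredictionSet(y_true=np.asarray(y, float), y_pred=np.asarray(pred, float),
                         variance=None if var is None else np.asarray(var, float))


def random_ps(rng, n=50):
    y = rng.normal(6.5, 1.2, n)
    pred = y + rng.normal(0, 0.7, n)
    var = rng.lognormal(-0.5, 0.6, n)
    return make_ps(y, pred, var)


class TestMseR2:
    def test_perfect_predictions(self):
        ps = make_ps([4, 5, 6], [4, 5, 6])
        assert mse(ps) == 0.0 and r_squared(ps) == 1.0

    def test_constant_predictor_at_label_mean_has_r2_zero(self):
        y = np.array([4.0, 5.0, 6.0, 9.0])
        ps = make_ps(y, np.full(4, y.mean()))
        assert r_squared(ps) == pytest.approx(0.0, abs=1e-15)

    def test_seven_point_toy_matches_direct_formula(self):
        y = np.array([4.1, 5.3, 6.2, 6.9, 7.4, 8.8, 9.5])
        pred = np.array([4.5, 5.0, 6.6, 6.4, 7.9, 8.1, 9.9])
        ps = make_ps(y, pred)
        exp_mse = sum((p - t) ** 2 for p, t in zip(pred, y)) / 7
        exp_r2 = 1 - sum((p - t) ** 2 for p, t in zip(pred, y)) / sum(
            (t - y.mean()) ** 2 for t in y
        )
        assert mse(ps) == pytest.approx(exp_mse, abs=1e-12)
        assert r_squared(ps) == pytest.approx(exp_r2, abs=1e-12)
        # independent route: sklearn
        from sklearn.metrics import mean_squared_error, r2_score

        assert mse(ps) == pytest.approx(mean_squared_error(y, pred), abs=1e-12)
        assert r_squared(ps) == pytest.approx(r2_score(y, pred), abs=1e-12)

    def test_zero_label_variance_signalled(self):
        with pytest.raises(UndefinedMetricError):
            r_squared(make_ps([6, 6, 6], [5, 6, 7]))


class TestNll:
    def test_exact_prediction_unit_variance(self):
        ps = make_ps([6.0], [6.0], [1.0])
        assert nll(ps) == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_error_equal_to_sigma(self):
        sigma2 = 0.49
        ps = make_ps([6.0], [6.0 + math.sqrt(sigma2)], [sigma2])
        expected = 0.5 * (math.log(2 * math.pi) + math.log(sigma2) + 1.0)
        assert nll(ps) == pytest.approx(expected, abs=1e-12)

    def test_matches_per_sample_loop_oracle(self):
        ps = random_ps(np.random.default_rng(0))
        total = 0.0
        for y, p, v in zip(ps.y_true, ps.y_pred, ps.variance):
            total += math.log(2 * math.pi) + math.log(v) + (p - y) ** 2 / v
        assert nll(ps) == pytest.approx(total / (2 * len(ps)), abs=1e-12)

    def test_unavailable_without_variances(self):
        with pytest.raises(MetricUnavailableError):
            nll(make_ps([6.0, 7.0], [6.0, 7.0]))

    def test_minimized_when_variance_equals_squared_error(self):
        rng = np.random.default_rng(3)
        y = rng.normal(6, 1, 30)
        pred = y + rng.normal(0, 0.5, 30)
        opt_var = (pred - y) ** 2 + 1e-12
        base = nll(make_ps(y, pred, opt_var))
        for factor in (0.5, 0.8, 1.25, 2.0):
            assert nll(make_ps(y, pred, opt_var * factor)) > base


class TestExpectedCoverage:
    def test_one_sigma_reference(self):
        assert expected_coverage(1.0) == pytest.approx(0.6827, abs=5e-5)

    def test_zero(self):
        assert expected_coverage(0.0) == 0.0

    def test_95_percent_quantile(self):
        assert expected_coverage(1.959964) == pytest.approx(0.95, abs=1e-6)
        # inverse-normal oracle
        assert expected_coverage(norm.ppf(0.975)) == pytest.approx(0.95, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expected_coverage(-0.5)


class TestCalibrationCurve:
    def test_infinite_bands_cover_everything(self):
        ps = make_ps([5, 6, 7], [9, 2, 14], [1e12, 1e12, 1e12])
        curve = calibration_curve(ps, n_levels=9)
        assert np.all(curve.observed == 1.0)

    def test_vanishing_bands_cover_nothing(self):
        ps = make_ps([5, 6, 7], [5.1, 6.1, 7.1], [1e-30, 1e-30, 1e-30])
        curve = calibration_curve(ps, n_levels=9)
        assert np.all(curve.observed == 0.0)

    def test_calibrated_curve_tracks_diagonal(self, calibrated_set):
        curve = calibration_curve(calibrated_set, n_levels=99)
        assert float(np.max(np.abs(curve.observed - curve.expected))) < 0.02

    def test_observed_coverage_non_decreasing(self):
        ps = random_ps(np.random.default_rng(5), n=200)
        curve = calibration_curve(ps)
        assert np.all(np.diff(curve.observed) >= 0)


def flat_curve(value, n_levels=99):
    p = np.arange(1, n_levels + 1) / (n_levels + 1)
    return CalibrationCurve(expected=p, sd_multiples=norm.ppf((1 + p) / 2),
                            observed=np.full(n_levels, float(value)))


class TestMiscalibrationAreas:
    def test_diagonal_curve_has_zero_area(self):
        # zero up to the O(grid step^2) p=1 endpoint term of the quadrature
        p = np.arange(1, 100) / 100
        curve = CalibrationCurve(expected=p, sd_multiples=norm.ppf((1 + p) / 2), observed=p)
        assert miscalibration_area(curve) == pytest.approx(0.0, abs=1e-4)
        assert absolute_miscalibration_area(curve) == pytest.approx(0.0, abs=1e-4)

    def test_zero_coverage_curve_attains_extremes(self):
        curve = flat_curve(0.0)
        assert absolute_miscalibration_area(curve) == pytest.approx(0.5, abs=1e-12)
        assert miscalibration_area(curve) == pytest.approx(-0.5, abs=1e-12)

    def test_cancellation_detected_by_absolute_variant(self):
        # observed = expected + d on the lower half, - d on the upper half
        p = np.arange(1, 100) / 100
        d = np.where(p < 0.5, 0.08, -0.08)
        o = np.clip(p + d, 0, 1)
        o = np.maximum.accumulate(o)  # keep monotone
        curve = CalibrationCurve(expected=p, sd_multiples=norm.ppf((1 + p) / 2), observed=o)
        assert abs(miscalibration_area(curve)) < absolute_miscalibration_area(curve)

    def test_area_bounds_on_random_monotone_curves(self):
        rng = np.random.default_rng(12)
        p = np.arange(1, 100) / 100
        for _ in range(50):
            o = np.sort(np.clip(rng.random(99) ** rng.uniform(0.3, 3), 0, 1))
            curve = CalibrationCurve(expected=p, sd_multiples=norm.ppf((1 + p) / 2), observed=o)
            A = miscalibration_area(curve)
            A_abs = absolute_miscalibration_area(curve)
            assert abs(A) <= A_abs + 1e-12
            assert A_abs <= 0.5 + 1e-12

    def test_equality_when_deviation_never_changes_sign(self):
        curve = flat_curve(1.0)  # observed above expected everywhere
        assert abs(miscalibration_area(curve)) == pytest.approx(
            absolute_miscalibration_area(curve), abs=1e-12
        )

    def test_sign_convention_over_confident_is_negative(self):
        for c, sign in ((2.0, -1), (0.5, +1)):
            ps = generate_prediction_set(
                SyntheticPredictionConfig(n=20_000, sigma_law=0.8, calibration_factor=c, seed=8)
            )
            assert np.sign(miscalibration_area(calibration_curve(ps))) == sign

    def test_area_strictly_decreasing_in_calibration_factor(self):
        areas = [
            miscalibration_area(
                calibration_curve(
                    generate_prediction_set(
                        SyntheticPredictionConfig(
                            n=100_000, sigma_law=0.8, calibration_factor=c, seed=10
                        )
                    )
                )
            )
            for c in (0.5, 1.0, 2.0)
        ]
        assert areas[0] > areas[1] > areas[2]


class TestSpearmanRho:
    def test_identical_vectors_give_one(self):
        r = ErrorVarianceRanking(v1=[1.0, 3.0, 2.0, 5.0], v2=[1.0, 3.0, 2.0, 5.0])
        assert spearman_rho(r) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_leaves_rho_unchanged(self):
        rng = np.random.default_rng(2)
        v1 = rng.random(40)
        v2 = rng.random(40)
        base = spearman_rho(ErrorVarianceRanking(v1=v1, v2=v2))
        assert spearman_rho(ErrorVarianceRanking(v1=np.exp(v1), v2=v2)) == pytest.approx(
            base, abs=1e-12
        )
        assert spearman_rho(ErrorVarianceRanking(v1=v1, v2=np.log(v2 + 1))) == pytest.approx(
            base, abs=1e-12
        )

    def test_tied_values_match_brute_force_average_ranks(self):
        v1 = np.array([0.3, 0.3, 1.0, 2.0, 5.0, 4.0])
        v2 = np.array([1.0, 2.0, 2.0, 3.0, 8.0, 6.0])
        # brute-force average ranks
        def avg_ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return np.array(ranks)

        r1, r2 = avg_ranks(v1), avg_ranks(v2)
        cov = np.mean((r1 - r1.mean()) * (r2 - r2.mean()))
        expected = cov / (r1.std() * r2.std())
        got = spearman_rho(ErrorVarianceRanking(v1=v1, v2=v2))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(spearmanr(v1, v2).statistic, abs=1e-12)

    def test_no_ties_matches_textbook_closed_form(self):
        rng = np.random.default_rng(7)
        v1 = rng.permutation(20).astype(float)
        v2 = rng.permutation(20).astype(float)
        d = rankdata(v1) - rankdata(v2)
        closed = 1 - 6 * float(np.sum(d**2)) / (20 * (20**2 - 1))
        assert spearman_rho(ErrorVarianceRanking(v1=v1, v2=v2)) == pytest.approx(
            closed, abs=1e-12
        )

    def test_constant_vector_signalled(self):
        with pytest.raises(UndefinedMetricError):
            spearman_rho(ErrorVarianceRanking(v1=[1.0, 1.0, 1.0], v2=[1.0, 2.0, 3.0]))


class TestOrderingInvariance:
    def test_all_metrics_invariant_to_compound_order(self):
        ps = random_ps(np.random.default_rng(20), n=80)
        perm = np.random.default_rng(21).permutation(80)
        shuffled = PredictionSet(
            y_true=ps.y_true[perm], y_pred=ps.y_pred[perm], variance=ps.variance[perm]
        )
        a, b = uq_report(ps), uq_report(shuffled)
        for attr in ("mse", "r2", "nll", "miscal_area", "miscal_area_abs", "spearman"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)

    def test_report_marks_uq_metrics_unavailable_without_variance(self):
        ps = make_ps([5.0, 6.0, 7.0], [5.2, 6.1, 6.8])
        rep = uq_report(ps)
        assert rep.nll is None and rep.miscal_area is None and rep.spearman is None
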
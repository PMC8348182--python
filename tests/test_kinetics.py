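"""Exponential decay fitting and the derived comparison statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pteryquant as pq
from pteryquant.kinetics import DecayFit, LinearTrend

DAYS = np.array([3.0, 7.0, 10.0, 15.0])


def _fit_of(a, k):
    return DecayFit(a, k, 1.0, 4, "log-linear")


class TestFit:
    @pytest.mark.parametrize("a, k", [(2e6, -0.174), (6.57e5, -0.1), (8111, -0.067)])
    def test_noiseless_recovery_is_exact(self, a, k):
        fit = pq.fit_exponential_decay(DAYS, a * np.exp(k * DAYS))
        assert fit.amplitude == pytest.approx(a, rel=1e-9)
        assert fit.rate == pytest.approx(k, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_series(self):
        fit = pq.fit_exponential_decay([1, 5, 9], [7.0, 7.0, 7.0])
        assert fit.rate == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(7.0)

    def test_nonpositive_values_need_nonlinear(self):
        with pytest.raises(ValueError, match="nonlinear"):
            pq.fit_exponential_decay(DAYS, [5.0, 2.0, 0.0, 1.0])
        fit = pq.fit_exponential_decay(DAYS, [5.0, 2.0, 0.0, 1.0], method="nonlinear")
        assert fit.method == "nonlinear" and np.isfinite(fit.rate)

    def test_loglinear_and_nonlinear_agree_on_clean_data(self):
        y = 8111 * np.exp(-0.067 * DAYS)
        a = pq.fit_exponential_decay(DAYS, y, "log-linear")
        b = pq.fit_exponential_decay(DAYS, y, "nonlinear")
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-4)
        assert b.rate == pytest.approx(a.rate, rel=1e-4)

    def test_replicate_average_recovers_mid_dose_rate(self):
        series = pq.generate_decay_series(
            pq.DecaySeriesParams(8111, -0.067, (3, 7, 10, 15), 6, 0.05, 2024)
        )
        rates = [
            pq.fit_exponential_decay([d for d, _ in r], [v for _, v in r]).rate
            for r in series
        ]
        assert np.mean(rates) == pytest.approx(-0.067, abs=0.01)

    def test_parameter_recovery_across_regimes(self):
        # simulated series across amplitudes and rates: median |k_hat - k| <= 0.01
        rng_seeds = iter(range(1000, 2000))
        errs = []
        for a in (1e3, 1e5, 1e7):
            for k in (-0.3, -0.15, -0.05, 0.0):
                for cv in (0.05, 0.10):
                    series = pq.generate_decay_series(
                        pq.DecaySeriesParams(a, k, (3, 7, 10, 15), 6, cv, next(rng_seeds))
                    )
                    day_means = np.mean([[v for _, v in r] for r in series], axis=0)
                    fit = pq.fit_exponential_decay(DAYS, day_means)
                    errs.append(abs(fit.rate - k))
        assert np.median(errs) <= 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pq.fit_exponential_decay([1, 2], [3.0, 2.0])


class TestComparisons:
    @pytest.mark.parametrize(
        "a_treat, expected", [(6.57e5, 67.15), (4.35e5, 78.25)]
    )
    def test_percent_initial_difference_reproduces_treatment_reductions(self, a_treat, expected):
        ref = _fit_of(2e6, -0.174)
        assert pq.percent_initial_difference(_fit_of(a_treat, -0.1), ref) == pytest.approx(
            expected, abs=0.005
        )

    def test_identical_fits_have_zero_difference(self):
        f = _fit_of(1e4, -0.1)
        assert pq.percent_initial_difference(f, f) == 0.0
        assert pq.rate_slowdown(f, f) == 0.0

    @pytest.mark.parametrize(
        "k_treat, expected", [(-0.1, 42.5), (-0.108, 37.9)]
    )
    def test_rate_slowdown_around_40pct_for_treatments(self, k_treat, expected):
        ref = _fit_of(2e6, -0.174)
        assert pq.rate_slowdown(_fit_of(1.0, k_treat), ref) == pytest.approx(expected, abs=0.1)

    def test_interval_decrease_values(self):
        assert pq.interval_decrease(_fit_of(8111, -0.067), 3, 15) == pytest.approx(55.2, abs=0.1)
        assert pq.interval_decrease(_fit_of(8111, 0.0), 3, 15) == 0.0
        assert pq.interval_decrease(_fit_of(9509, -0.259), 0, 12) == pytest.approx(95.5, abs=0.1)

    @given(
        st.floats(-0.3, -0.01),
        st.floats(1e2, 1e6),
        st.floats(0.0, 20.0),
        st.floats(1.0, 15.0),
    )
    def test_interval_decrease_depends_only_on_rate_and_span(self, k, a, t0, span):
        base = pq.interval_decrease(_fit_of(1.0, k), 0.0, span)
        assert pq.interval_decrease(_fit_of(a, k), t0, t0 + span) == pytest.approx(base)

    @pytest.mark.parametrize(
        "value, expected", [(38.5, 1.169), (33.0, 0.859), (28.8, 0.623)]
    )
    def test_fold_change_reproduces_opacity_factors(self, value, expected):
        assert pq.fold_change(value, 17.75) == pytest.approx(expected, abs=0.001)

    def test_fold_change_trivia_and_errors(self):
        assert pq.fold_change(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            pq.fold_change(1.0, 0.0)

    @pytest.mark.parametrize(
        "slope_a, slope_b, expected", [(0.004, 0.00002, 200.0), (0.001, 0.00002, 50.0)]
    )
    def test_trend_ratio_of_outline_roughness_slopes(self, slope_a, slope_b, expected):
        ta = LinearTrend(slope_a, 1.3, 1.0)
        tb = LinearTrend(slope_b, 1.35, 1.0)
        assert pq.trend_ratio(ta, tb) == pytest.approx(expected)
        assert pq.trend_ratio(ta, ta) == 1.0

    def test_trend_ratio_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pq.trend_ratio(LinearTrend(1.0, 0, 1), LinearTrend(0.0, 0, 1))


class TestLinearTrend:
    def test_exact_line_recovery(self):
        x = np.array([3, 7, 10, 15], dtype=float)
        tr = pq.fit_linear_trend(x, -0.0073 * x + 1.91)
        assert tr.slope == pytest.approx(-0.0073)
        assert tr.intercept == pytest.approx(1.91)
        assert tr.r2 == pytest.approx(1.0)
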
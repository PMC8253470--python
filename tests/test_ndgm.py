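import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import greycast as gc
from greycast.ndgm import _simulate_order1


def series_from(values, label="t", first_year=2005):
    years = tuple(range(first_year, first_year + len(values)))
    return gc.AnnualSeries(label, years, tuple(float(v) for v in values))


positive_series = st.lists(
    st.floats(min_value=0.1, max_value=1e7, allow_nan=False), min_size=1, max_size=40
).map(series_from)


class TestAgoRestore:
    def test_ago_running_totals(self):
        assert gc.ago(series_from([1, 2, 3])).values == (1.0, 3.0, 6.0)

    def test_ago_matches_published_cumulative(self, study_series):
        acc = gc.ago(study_series["Kenya"])
        assert acc.values[:2] == (28096.0, 56805.0)

    def test_single_element_identity(self):
        s = series_from([5])
        assert gc.ago(s).values == (5.0,)
        assert gc.restore(gc.ago(s)) == s

    def test_restore_first_differences(self):
        acc = gc.AccumulatedSeries("t", (2005, 2006, 2007), (1.0, 3.0, 6.0))
        assert gc.restore(acc).values == (1.0, 2.0, 3.0)

    @given(positive_series)
    @settings(max_examples=200, deadline=None)
    def test_restore_ago_identity(self, series):
        back = gc.restore(gc.ago(series))
        assert np.allclose(back.values_array(), series.values_array(), rtol=1e-12)
        assert back.years == series.years


class TestRegressionSystem:
    def test_direct_construction(self):
        acc = gc.AccumulatedSeries("t", (2005, 2006, 2007, 2008), (10, 20, 30, 40))
        design, response = gc.build_regression_system(acc)
        assert design.tolist() == [[10, 1, 1], [20, 2, 1], [30, 3, 1]]
        assert response.tolist() == [20, 30, 40]

    def test_fifteen_points_make_fourteen_rows(self, study_series):
        design, response = gc.build_regression_system(gc.ago(study_series["Pakistan"]))
        assert design.shape == (14, 3)
        assert response.shape == (14,)

    def test_short_series_rejected(self):
        acc = gc.AccumulatedSeries("t", (2005, 2006, 2007), (1, 2, 3))
        with pytest.raises(gc.InsufficientDataError):
            gc.build_regression_system(acc)


def exact_recursion_series(b1, b2, b3, x1_start, n, shift=0.0):
    """Accumulated series from the recursion, optionally off-manifold:

    a nonzero *shift* seeds the trajectory at x1_start + shift while the
    observed first element stays x1_start, the situation the shift
    estimator is built to recover.
    """
    z = _simulate_order1(x1_start + shift, b1, b2, b3, n)
    values = z.copy()
    values[0] = x1_start
    return gc.AccumulatedSeries("gen", tuple(range(2005, 2005 + n)), tuple(values))


class TestLinearParams:
    def test_recovers_exact_recursion(self):
        acc = exact_recursion_series(1.05, 10.0, 100.0, 1000.0, 10)
        b1, b2, b3 = gc.estimate_linear_params(*gc.build_regression_system(acc))
        assert abs(b1 - 1.05) / 1.05 < 1e-8
        assert abs(b2 - 10.0) / 10.0 < 1e-8
        assert abs(b3 - 100.0) / 100.0 < 1e-8

    def test_matches_normal_equations(self, study_series):
        for series in study_series.values():
            design, response = gc.build_regression_system(gc.ago(series))
            ours = np.array(gc.estimate_linear_params(design, response))
            normal = np.linalg.solve(design.T @ design, design.T @ response)
            assert np.allclose(ours, normal, rtol=1e-10, atol=1e-10 * np.abs(normal).max())

    def test_constant_accumulated_series_is_singular(self):
        # response equal to the first design column: beta1=1 world with no
        # drift leaves the design rank deficient
        design = np.array([[5.0, 1, 1], [5.0, 2, 1], [5.0, 3, 1], [5.0, 4, 1]])
        with pytest.raises(gc.SingularSystemError):
            gc.estimate_linear_params(design, design[:, 0])


class TestShiftEstimation:
    def test_recovers_planted_shift(self):
        acc = exact_recursion_series(1.05, 10.0, 100.0, 1000.0, 12, shift=50.0)
        b4 = gc.estimate_shift(acc, 1.05, 10.0, 100.0)
        assert abs(b4 - 50.0) < 1e-8

    def test_zero_shift_estimated_as_zero(self):
        acc = exact_recursion_series(0.95, -5.0, 200.0, 1500.0, 10)
        assert abs(gc.estimate_shift(acc, 0.95, -5.0, 200.0)) < 1e-8

    def test_exact_for_unit_beta1(self):
        acc = exact_recursion_series(1.0, 2.0, 50.0, 100.0, 8, shift=-7.0)
        assert abs(gc.estimate_shift(acc, 1.0, 2.0, 50.0) + 7.0) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_numeric_sse_minimiser(self, seed):
        rng = np.random.default_rng(seed)
        b1 = rng.uniform(0.7, 1.3)
        b2, b3 = rng.uniform(-20, 20), rng.uniform(10, 500)
        x1 = np.cumsum(rng.uniform(50, 150, size=12))
        acc = gc.AccumulatedSeries("r", tuple(range(2005, 2017)), tuple(x1))
        b4 = gc.estimate_shift(acc, b1, b2, b3)

        def sse(b4_try):
            z = _simulate_order1(x1[0] + b4_try, b1, b2, b3, len(x1))
            return float(np.sum((x1[1:] - z[1:]) ** 2))

        res = minimize_scalar(sse, bracket=(b4 - 100, b4, b4 + 100), method="brent")
        assert abs(b4 - res.x) <= 1e-6 * max(1.0, abs(b4))
        assert sse(b4) <= sse(res.x) * (1 + 1e-12) + 1e-9


class TestFit:
    def test_noiseless_generated_series_fits_exactly(self):
        spec = gc.GeneratorSpec(beta1=1.04, beta2=120.0, beta3=900.0, x0=5000.0)
        f = gc.fit(gc.generate(spec))
        assert f.mape_percent <= 1e-8
        assert abs(f.params.beta1 - 1.04) / 1.04 < 1e-6

    def test_study_restored_value_tracks_published(self, study_series):
        f = gc.fit(study_series["Pakistan"])
        assert f.restored.value_in(2006) == pytest.approx(297535, rel=0.01)

    def test_constant_series_restored_exactly(self):
        f = gc.fit(series_from([1000.0] * 10))
        assert np.allclose(f.restored.values_array(), 1000.0, rtol=1e-9)
        assert f.mape_percent < 1e-8

    def test_restored_is_first_difference_of_order1(self, study_series):
        f = gc.fit(study_series["Sweden"])
        x1 = np.array(f.fitted_order1)
        assert np.allclose(np.diff(x1), f.restored.values_array()[1:], rtol=1e-12)
        assert f.restored.values[0] == pytest.approx(x1[0])

    def test_order1_monotone_when_restored_positive(self, study_series):
        for series in study_series.values():
            f = gc.fit(series)
            if np.all(f.restored.values_array() > 0):
                assert np.all(np.diff(f.fitted_order1) > 0)


class TestForecast:
    def test_default_horizon_continues_calendar(self, study_series):
        f = gc.fit(study_series["Pakistan"])
        future = gc.forecast(f, 8)
        assert future.years == tuple(range(2020, 2028))

    def test_single_step_equals_next_recursion_value(self, study_series):
        f = gc.fit(study_series["Kenya"])
        one = gc.forecast(f, 1)
        p = f.params
        n = len(f.series)
        next_x1 = p.beta1 * f.fitted_order1[-1] + p.beta2 * n + p.beta3
        assert one.values[0] == pytest.approx(next_x1 - f.fitted_order1[-1], rel=1e-12)

    def test_forecast_of_exact_series_matches_generator_continuation(self):
        spec = gc.GeneratorSpec(beta1=1.03, beta2=40.0, beta3=600.0, x0=8000.0, n_years=12)
        longer = gc.generate(gc.GeneratorSpec(
            beta1=1.03, beta2=40.0, beta3=600.0, x0=8000.0, n_years=17))
        f = gc.fit(gc.generate(spec))
        future = gc.forecast(f, 5)
        assert np.allclose(
            future.values_array(), longer.values_array()[12:], rtol=1e-8
        )

    def test_zero_horizon_rejected(self, study_series):
        f = gc.fit(study_series["Kenya"])
        with pytest.raises(gc.DomainError):
            gc.forecast(f, 0)
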
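"""SPEI construction: PET, water balance, aggregation, fitting, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drought_greenness import (
    SeverityClass,
    aggregate_k,
    classify_severity,
    fit_loglogistic_pwm,
    fit_spei,
    standardize,
    thornthwaite_pet,
    water_balance,
)
from drought_greenness.spei import _day_length_hours

from conftest import monthly_series


def thornthwaite_oracle(temps_by_month, latitude):
    """Independent brute-force evaluation of the Thornthwaite formula
    (heat index, exponent, day-length factor) for a 12-month normal year."""
    import math

    mid_doy = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
    ndays = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    heat = sum((t / 5.0) ** 1.514 for t in temps_by_month if t > 0)
    a = (6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239)
    out = []
    for m, t in enumerate(temps_by_month):
        if t <= 0:
            out.append(0.0)
            continue
        if t < 26.5:
            base = 16.0 * (10.0 * t / heat) ** a
        else:
            base = -415.85 + 32.24 * t - 0.43 * t * t
        delta = 0.409 * math.sin(2 * math.pi * mid_doy[m] / 365 - 1.39)
        cosw = max(-1.0, min(1.0, -math.tan(math.radians(latitude))
                             * math.tan(delta)))
        daylen = 24.0 / math.pi * math.acos(cosw)
        out.append(base * (daylen / 12.0) * (ndays[m] / 30.0))
    return out


class TestThornthwaitePET:
    def test_freezing_month_gives_zero(self):
        t = monthly_series([-5.0] * 3 + [10.0] * 9)
        pet = thornthwaite_pet(t, latitude=26.5)
        assert (pet.iloc[:3] == 0.0).all()
        assert (pet.iloc[3:] > 0.0).all()

    def test_matches_independent_formula_oracle(self):
        t = monthly_series([10.0] * 12)
        pet = thornthwaite_pet(t, latitude=0.0)
        expected = thornthwaite_oracle([10.0] * 12, 0.0)
        np.testing.assert_allclose(pet.to_numpy(), expected, atol=1e-9)

    def test_matches_oracle_on_seasonal_cycle(self):
        temps = [5, 6, 10, 15, 19, 22, 24, 23, 20, 15, 10, 6]
        pet = thornthwaite_pet(monthly_series([float(x) for x in temps]),
                               latitude=26.5)
        expected = thornthwaite_oracle(temps, 26.5)
        np.testing.assert_allclose(pet.to_numpy(), expected, rtol=1e-12)

    def test_linear_in_day_length_correction(self):
        # PET scales with the day-length factor across latitudes, month-wise
        t = monthly_series([15.0] * 12)
        pet_a = thornthwaite_pet(t, latitude=0.0).to_numpy()
        pet_b = thornthwaite_pet(t, latitude=45.0).to_numpy()
        ratio = _day_length_hours(45.0) / _day_length_hours(0.0)
        np.testing.assert_allclose(pet_b / pet_a, ratio, rtol=1e-12)

    def test_missing_months_flagged(self):
        vals = [10.0] * 24
        vals[5] = np.nan
        pet = thornthwaite_pet(monthly_series(vals), latitude=30.0)
        assert np.isnan(pet.iloc[5]) and pet.drop(pet.index[5]).notna().all()

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            thornthwaite_pet(monthly_series([10.0] * 12), latitude=75.0)


class TestWaterBalance:
    def test_arithmetic(self):
        p = monthly_series([50.0, 60.0])
        pet = monthly_series([40.0, 80.0])
        np.testing.assert_array_equal(water_balance(p, pet).to_numpy(),
                                      [10.0, -20.0])

    def test_p_equal_pet_gives_zero(self):
        p = monthly_series([30.0] * 12)
        assert (water_balance(p, p) == 0.0).all()

    def test_missing_propagates(self):
        p = monthly_series([50.0, np.nan, 70.0])
        pet = monthly_series([40.0, 40.0, 40.0])
        d = water_balance(p, pet)
        assert np.isnan(d.iloc[1]) and d.iloc[[0, 2]].notna().all()

    def test_index_mismatch_names_months(self):
        p = monthly_series([1.0, 2.0], start="2001-01")
        pet = monthly_series([1.0, 2.0], start="2001-02")
        with pytest.raises(ValueError, match="2001-0[13]"):
            water_balance(p, pet)


class TestAggregateK:
    def test_k1_is_identity(self):
        d = monthly_series([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(aggregate_k(d, 1).to_numpy(),
                                      d.to_numpy())

    def test_rolling_sum(self):
        d = monthly_series([1.0, 2.0, 3.0, 4.0])
        out = aggregate_k(d, 2)
        assert np.isnan(out.iloc[0])
        np.testing.assert_array_equal(out.iloc[1:].to_numpy(), [3.0, 5.0, 7.0])

    def test_constant_series(self):
        d = monthly_series([2.5] * 24)
        assert (aggregate_k(d, 6).dropna() == 15.0).all()

    def test_missing_voids_window(self):
        vals = [1.0] * 12
        vals[4] = np.nan
        out = aggregate_k(monthly_series(vals), 3)
        assert out.iloc[4:7].isna().all()
        assert out.iloc[7:].notna().all()

    def test_k_longer_than_series_warns_empty(self):
        with pytest.warns(UserWarning, match="exceeds"):
            out = aggregate_k(monthly_series([1.0, 2.0]), 6)
        assert len(out) == 0

    @given(st.integers(1, 6), st.lists(st.floats(-100, 100), min_size=12,
                                       max_size=36))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_brute_force(self, k, values):
        d = monthly_series(values)
        out = aggregate_k(d, k)
        for m in range(k - 1, len(values)):
            assert out.iloc[m] == pytest.approx(sum(values[m - k + 1:m + 1]),
                                                abs=1e-9)


class TestLogLogisticFit:
    A, B, G = 50.0, 3.5, 120.0

    def _sample(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        return self.G + self.A * (u / (1 - u)) ** (1 / self.B)

    def test_parameter_recovery(self):
        p = fit_loglogistic_pwm(self._sample())
        assert p.alpha == pytest.approx(self.A, rel=0.10)
        assert p.beta == pytest.approx(self.B, rel=0.10)
        assert p.gamma == pytest.approx(self.G, rel=0.10)

    def test_cdf_at_sample_median_near_half(self):
        x = self._sample()
        p = fit_loglogistic_pwm(x)
        assert 0.4 <= float(p.cdf(np.median(x))) <= 0.6

    def test_location_equivariance(self):
        x = self._sample(seed=3)
        p0 = fit_loglogistic_pwm(x)
        p1 = fit_loglogistic_pwm(x + 37.5)
        assert p1.gamma - p0.gamma == pytest.approx(37.5, rel=1e-9)
        assert p1.alpha == pytest.approx(p0.alpha, rel=1e-9)
        assert p1.beta == pytest.approx(p0.beta, rel=1e-9)

    def test_cdf_matches_empirical_within_kolmogorov_0p1(self):
        x = np.sort(self._sample(seed=7))
        p = fit_loglogistic_pwm(x)
        ecdf = np.arange(1, len(x) + 1) / len(x)
        assert np.max(np.abs(p.cdf(x) - ecdf)) < 0.1

    def test_left_skewed_sample_fits_by_reflection(self):
        x = -self._sample(seed=5)
        p = fit_loglogistic_pwm(x)
        assert p.reflected
        # CDF still matches the empirical distribution
        xs = np.sort(x)
        ecdf = np.arange(1, len(xs) + 1) / len(xs)
        assert np.max(np.abs(p.cdf(xs) - ecdf)) < 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            fit_loglogistic_pwm(np.arange(5.0))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_loglogistic_pwm(np.full(50, 3.0))


class TestStandardize:
    def _params(self):
        rng = np.random.default_rng(11)
        sample = rng.gamma(4.0, 25.0, size=200) - 50.0
        return {m: fit_loglogistic_pwm(sample) for m in range(1, 13)}

    def test_fitted_median_maps_to_zero(self):
        params = self._params()
        median = params[1].ppf(0.5)
        d_k = monthly_series([float(median)] * 12)
        out = standardize(d_k, params)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-6)

    def test_monotone_within_calendar_month(self):
        params = self._params()
        jan = pd.PeriodIndex([f"{y}-01" for y in range(2001, 2011)], freq="M")
        vals = np.linspace(-40.0, 150.0, 10)
        out = [
            float(standardize(monthly_series([v] * 12), params).iloc[0])
            for v in vals
        ]
        assert all(a < b for a, b in zip(out, out[1:]))

    def test_below_origin_maps_to_finite_floor(self):
        params = self._params()
        origin = min(p.ppf(1e-9) for p in params.values())
        d_k = monthly_series([float(origin) - 1000.0] * 12)
        out = standardize(d_k, params)
        assert np.isfinite(out).all()
        assert (out < -4.0).all()  # deep lower tail, floored

    def test_missing_month_params_rejected(self):
        params = self._params()
        del params[7]
        with pytest.raises(ValueError, match="7"):
            standardize(monthly_series([0.0] * 12), params)

    def test_shift_invariance_of_standardization(self, climate_station):
        """Adding a constant to one calendar month's d_k leaves SPEI unchanged
        (location equivariance of the fit, then standardization)."""
        from drought_greenness.spei import (aggregate_k, thornthwaite_pet,
                                            water_balance)

        pet = thornthwaite_pet(climate_station.t, climate_station.latitude)
        d_k = aggregate_k(water_balance(climate_station.p, pet), 6)
        shifted = d_k.copy()
        is_may = shifted.index.month == 5
        shifted[is_may] += 123.0

        def spei_of(series):
            params = {
                m: fit_loglogistic_pwm(series[series.index.month == m])
                for m in range(1, 13)
            }
            return standardize(series, params)

        np.testing.assert_allclose(
            spei_of(shifted).dropna().to_numpy(),
            spei_of(d_k).dropna().to_numpy(),
            atol=1e-6,
        )


class TestSelfCalibration:
    def test_per_month_mean_and_sd(self, climate_station):
        """Self-calibrated SPEI-6 over 21 years: per-calendar-month mean within
        +-0.1 of 0 and sd in [0.85, 1.15]."""
        spei = fit_spei(climate_station, k=6).spei.dropna()
        grouped = spei.groupby(spei.index.month)
        assert grouped.mean().abs().max() <= 0.1
        assert grouped.std().between(0.85, 1.15).all()


class TestSeverityClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-0.4, SeverityClass.NONE),
            (0.7, SeverityClass.NONE),
            (-0.5, SeverityClass.MILD),
            (-0.9, SeverityClass.MILD),
            (-1.0, SeverityClass.MODERATE),
            (-1.3, SeverityClass.MODERATE),
            (-1.5, SeverityClass.SEVERE),
            (-1.78, SeverityClass.SEVERE),
            (-2.0, SeverityClass.EXTREME),
            (-3.7, SeverityClass.EXTREME),
        ],
    )
    def test_class_bounds(self, value, expected):
        assert classify_severity(value) is expected

    @given(st.floats(-10.0, 10.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partitions_the_line(self, v):
        cls = classify_severity(v)
        lower = {SeverityClass.NONE: (-0.5, np.inf),
                 SeverityClass.MILD: (-1.0, -0.5),
                 SeverityClass.MODERATE: (-1.5, -1.0),
                 SeverityClass.SEVERE: (-2.0, -1.5),
                 SeverityClass.EXTREME: (-np.inf, -2.0)}[cls]
        assert lower[0] < v <= lower[1]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(float("nan"))
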
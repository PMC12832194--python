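"""MVC compositing, drought-excluded baselines, anomalies and the lag metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drought_greenness import (
    GridSpec,
    MonthlyStack,
    SeasonWindow,
    anomaly,
    baseline_climatology,
    minimum_shift,
    monthly_anomalies,
    mvc_monthly,
    seasonal_anomaly,
)

GRID1 = GridSpec(1, 1)
GRID3 = GridSpec(3, 3)


def stack_from(values, start="2001-01", grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or GridSpec(*values.shape[1:])
    months = pd.period_range(start, periods=len(values), freq="M")
    return MonthlyStack(values, months, grid)


class TestMVC:
    def test_takes_maximum(self):
        comps = [np.full((1, 1), 0.31), np.full((1, 1), 0.47)]
        out = mvc_monthly(comps, ["2001-01-01", "2001-01-17"], GRID1)
        assert out.values[0, 0, 0] == 0.47

    def test_single_composite_identity(self):
        out = mvc_monthly([np.full((1, 1), 0.2)], ["2001-06-01"], GRID1)
        assert out.values[0, 0, 0] == 0.2

    def test_missing_composite_ignored(self):
        comps = [np.full((1, 1), np.nan), np.full((1, 1), 0.2)]
        out = mvc_monthly(comps, ["2001-01-01", "2001-01-17"], GRID1)
        assert out.values[0, 0, 0] == 0.2

    def test_all_missing_cell_stays_missing(self):
        comps = [np.full((1, 1), np.nan)] * 2
        out = mvc_monthly(comps, ["2001-01-01", "2001-01-17"], GRID1)
        assert np.isnan(out.values[0, 0, 0])

    def test_month_without_composites_warns(self):
        comps = [np.full((1, 1), 0.3), np.full((1, 1), 0.4)]
        with pytest.warns(UserWarning, match="2001-02"):
            out = mvc_monthly(comps, ["2001-01-01", "2001-03-01"], GRID1)
        assert np.isnan(out.layer("2001-02")).all()

    def test_output_bounds_every_composite(self):
        rng = np.random.default_rng(0)
        comps = [rng.uniform(0, 1, (3, 3)) for _ in range(6)]
        dates = ["2001-01-01", "2001-01-17", "2001-02-01", "2001-02-17",
                 "2001-03-01", "2001-03-17"]
        out = mvc_monthly(comps, dates, GRID3)
        for comp, date in zip(comps, dates):
            layer = out.layer(pd.Period(pd.Timestamp(date), "M"))
            assert (layer >= comp - 1e-12).all()

    def test_out_of_range_values_flagged_invalid(self):
        out = mvc_monthly([np.full((1, 1), 1.7)], ["2001-01-01"], GRID1)
        assert np.isnan(out.values).all()


class TestBaselineClimatology:
    def test_plain_mean_without_mask(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (36, 3, 3))
        stk = stack_from(values)
        clim = baseline_climatology(stk)
        np.testing.assert_allclose(clim.baseline[0], values[::12].mean(axis=0))

    def test_masked_years_excluded(self):
        # 21 Octobers, 2 drought-masked: baseline is the mean of the other 19
        years = 21
        values = np.arange(years, dtype=float).reshape(-1, 1, 1)
        months = pd.PeriodIndex([f"{2001 + y}-10" for y in range(years)],
                                freq="M")
        stk = MonthlyStack(values, months, GRID1)
        mask = pd.Series(False, index=months)
        mask.iloc[3] = mask.iloc[10] = True
        clim = baseline_climatology(stk, mask)
        expected = np.delete(np.arange(years, dtype=float), [3, 10]).mean()
        assert clim.baseline[9][0, 0] == pytest.approx(expected)
        assert clim.counts[9][0, 0] == 19

    def test_constant_series_any_mask(self):
        values = np.full((48, 2, 2), 0.6)
        stk = stack_from(values)
        mask = pd.Series(False, index=stk.months)
        mask.iloc[5:20] = True
        clim = baseline_climatology(stk, mask)
        np.testing.assert_allclose(clim.baseline, 0.6)

    def test_fully_masked_month_missing_or_fallback(self):
        values = np.random.default_rng(2).uniform(0, 1, (24, 1, 1))
        stk = stack_from(values)
        mask = pd.Series(stk.months.month == 3, index=stk.months)
        with pytest.warns(UserWarning, match="month 3"):
            clim = baseline_climatology(stk, mask)
        assert np.isnan(clim.baseline[2]).all()
        with pytest.warns(UserWarning):
            clim2 = baseline_climatology(stk, mask, fallback_all_years=True)
        assert np.isfinite(clim2.baseline[2]).all()

    def test_anomalies_mean_center_on_contributing_years(self):
        """Per calendar month, anomalies averaged over exactly the
        baseline-contributing years are 0 by construction (1e-9)."""
        rng = np.random.default_rng(3)
        values = rng.uniform(0.2, 0.9, (252, 3, 3))
        stk = stack_from(values)
        mask = pd.Series(False, index=stk.months)
        mask.iloc[100:109] = True
        clim = baseline_climatology(stk, mask)
        anom, _ = monthly_anomalies(stk, clim)
        contributing = ~mask.to_numpy()
        for m in range(1, 13):
            sel = (stk.months.month == m) & contributing
            np.testing.assert_allclose(anom.values[sel].mean(axis=0), 0.0,
                                       atol=1e-9)


class TestAnomaly:
    def test_arithmetic(self):
        res = anomaly(0.45, 0.50)
        assert res.absolute == pytest.approx(-0.05)
        assert res.percent == pytest.approx(-10.0)

    def test_zero_at_baseline(self):
        res = anomaly(0.5, 0.5)
        assert res.absolute == 0.0 and res.percent == 0.0

    def test_printed_pair_consistency(self):
        # a -0.16 absolute with -28.54% back-implies baseline ~ 0.5606;
        # forward evaluation reproduces both printed numbers to 2 decimals
        baseline = -0.16 / (-28.54 / 100.0)
        res = anomaly(baseline - 0.16, baseline)
        assert res.absolute == pytest.approx(-0.16, abs=5e-3)
        assert res.percent == pytest.approx(-28.54, abs=5e-3)

    def test_small_baseline_percent_undefined(self):
        res = anomaly(0.005, 0.002)
        assert np.isnan(res.percent)
        assert res.absolute == pytest.approx(0.003)

    @given(st.floats(-1, 1, allow_nan=False), st.floats(-1, 1, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetric(self, a, b):
        assert anomaly(a, b).absolute == pytest.approx(-anomaly(b, a).absolute,
                                                       abs=1e-12)

    def test_sign_consistency_where_baseline_positive(self):
        rng = np.random.default_rng(5)
        obs = rng.uniform(-0.2, 1.0, 100)
        base = rng.uniform(0.05, 1.0, 100)
        res = anomaly(obs, base)
        assert (np.sign(res.percent) == np.sign(res.absolute)).all()


class TestSeasonalAnomaly:
    def _series(self, anoms, bases, start="2005-09"):
        idx = pd.period_range(start, periods=len(anoms), freq="M")
        return (pd.Series(anoms, index=idx), pd.Series(bases, index=idx))

    def test_constant_months(self):
        a, b = self._series([-0.06] * 3, [0.5] * 3)
        res = seasonal_anomaly(a, b, SeasonWindow("autumn", 2005))
        assert res.absolute == pytest.approx(-0.06)
        assert res.percent == pytest.approx(100 * -0.06 / 0.5)

    def test_cancellation(self):
        a, b = self._series([0.1, -0.1, 0.0], [0.5, 0.5, 0.5])
        res = seasonal_anomaly(a, b, SeasonWindow("autumn", 2005))
        assert res.absolute == pytest.approx(0.0)

    def test_missing_member_warns(self):
        a, b = self._series([0.1, np.nan, 0.0], [0.5, 0.5, 0.5])
        with pytest.warns(UserWarning):
            res = seasonal_anomaly(a, b, SeasonWindow("autumn", 2005))
        assert np.isnan(res.absolute)


class TestMinimumShift:
    def _curve(self, min_month):
        x = np.arange(12)
        return np.cos(2 * np.pi * (x - min_month) / 12)  # minimum at +6

    def test_two_month_delay(self):
        baseline = -np.cos(2 * np.pi * np.arange(12) / 12)  # min in Jan (idx 0)
        observed = np.roll(baseline, 2)                      # min in Mar
        assert minimum_shift(observed, baseline) == 2

    def test_identical_curves(self):
        base = -np.cos(2 * np.pi * np.arange(12) / 12)
        assert minimum_shift(base, base) == 0

    def test_earlier_minimum_negative(self):
        baseline = -np.cos(2 * np.pi * (np.arange(12) - 3) / 12)  # min in Apr
        observed = np.roll(baseline, -1)                           # min in Mar
        assert minimum_shift(observed, baseline) == -1

    def test_tie_breaks_early_with_warning(self):
        baseline = np.ones(12)
        baseline[[2, 5]] = 0.0
        observed = np.ones(12)
        observed[4] = 0.0
        with pytest.warns(UserWarning, match="tie"):
            assert minimum_shift(observed, baseline) == 2

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            minimum_shift(np.zeros(11), np.zeros(12))
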
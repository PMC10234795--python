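"""Time-use classification, valid-wear screening, average acceleration
and intensity gradient."""

import numpy as np
import pandas as pd
import pytest

from move24.accel import (CutPoints, average_acceleration, classify_time_use,
                          intensity_gradient_day, screen_valid_days,
                          weighted_week, intensity_gradient, _ig_fit)
from move24.sleep import SleepWindow
from tests.conftest import make_series

EPD = 86400 // 5  # 5-s epochs per day


def week_series(values_by_day, start="2022-09-05"):
    """Build a series of constant-ENMO complete days (start is a Monday)."""
    enmo = np.concatenate([np.full(EPD, v, dtype=float) for v in values_by_day])
    return make_series(enmo, start=start)


class TestScreenValidDays:
    def test_three_weekdays_one_saturday_valid(self):
        # Wed..Sat: 3 weekdays + 1 weekend day
        s = week_series([10] * 4, start="2022-09-07")
        days, valid = screen_valid_days(s)
        assert valid and len(days) == 4

    def test_seven_days_all_retained(self):
        s = week_series([10] * 7)
        days, valid = screen_valid_days(s)
        assert valid and len(days) == 7

    def test_weekdays_only_invalid(self):
        s = week_series([10] * 5)  # Mon..Fri
        days, valid = screen_valid_days(s)
        assert not valid and len(days) == 5

    def test_partial_day_not_counted(self):
        enmo = np.full(EPD + EPD // 2, 10.0)
        s = make_series(enmo, start="2022-09-05")
        days, _ = screen_valid_days(s, min_weekdays=1, min_weekend=0)
        assert len(days) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            screen_valid_days(make_series(np.zeros(0)))


class TestCutPoints:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            CutPoints(st_upper=300, mpa_lower=200)


class TestClassifyTimeUse:
    def test_all_zero_no_sleep_is_pure_st(self):
        s = week_series([0.0])
        tu = classify_time_use(s)
        row = tu.iloc[0]
        assert row["st"] == pytest.approx(1440.0)
        assert row[["sleep", "lpa", "mpa", "vpa"]].sum() == 0.0

    def test_boundary_epoch_joins_higher_category(self):
        enmo = np.zeros(EPD)
        enmo[1000] = 48.0   # exactly at the ST/LPA cut-point -> LPA
        enmo[2000] = 201.0  # -> MPA
        enmo[3000] = 707.0  # -> VPA
        tu = classify_time_use(make_series(enmo)).iloc[0]
        assert tu["lpa"] == pytest.approx(5 / 60)
        assert tu["mpa"] == pytest.approx(5 / 60)
        assert tu["vpa"] == pytest.approx(5 / 60)

    def test_planted_vpa_minutes_counted(self):
        enmo = np.zeros(EPD)
        enmo[: 30 * 12] = 800.0  # 30 min at 12 epochs/min
        tu = classify_time_use(make_series(enmo)).iloc[0]
        assert tu["vpa"] == pytest.approx(30.0)

    def test_sleep_window_attributed_to_onset_day(self):
        s = week_series([0.0, 0.0])
        w = SleepWindow(onset=pd.Timestamp("2022-09-05 22:00"),
                        offset=pd.Timestamp("2022-09-06 06:00"))
        tu = classify_time_use(s, sleep_windows=[w])
        # full 480-min window on the onset day, none on the next
        assert tu.iloc[0]["sleep"] == pytest.approx(480.0)
        assert tu.iloc[1]["sleep"] == 0.0

    def test_closure_to_1440(self, small_cohort):
        from move24.sleep import detect_all_nights
        s = small_cohort.series[0]
        tu = classify_time_use(s, sleep_windows=detect_all_nights(s))
        np.testing.assert_allclose(tu.sum(axis=1), 1440.0, atol=1e-6)

    def test_raising_st_cut_never_decreases_st(self):
        rng = np.random.default_rng(0)
        enmo = rng.uniform(0, 300, EPD)
        s = make_series(enmo)
        st_at = [classify_time_use(s, CutPoints(st_upper=c)).iloc[0]["st"]
                 for c in (30, 48, 80, 150)]
        assert all(a <= b for a, b in zip(st_at, st_at[1:]))

    def test_overlapping_windows_rejected(self):
        s = week_series([0.0, 0.0])
        w1 = SleepWindow(onset=pd.Timestamp("2022-09-05 22:00"),
                         offset=pd.Timestamp("2022-09-06 06:00"))
        w2 = SleepWindow(onset=pd.Timestamp("2022-09-06 05:00"),
                         offset=pd.Timestamp("2022-09-06 07:00"))
        with pytest.raises(ValueError):
            classify_time_use(s, sleep_windows=[w1, w2])


class TestAverageAcceleration:
    def test_constant_series(self):
        assert average_acceleration(week_series([50] * 7)) == pytest.approx(50.0)

    def test_weighted_week_of_unequal_days(self):
        # weekdays at 100, weekend at 170 -> (5*100 + 2*170)/7 = 120
        s = week_series([100] * 5 + [170] * 2)
        assert average_acceleration(s) == pytest.approx(120.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        enmo = rng.uniform(0, 120, 7 * EPD)
        s = make_series(enmo, start="2022-09-05")
        day_means = enmo.reshape(7, EPD).mean(axis=1)
        oracle = (5 * day_means[:5].mean() + 2 * day_means[5:].mean()) / 7
        assert average_acceleration(s) == pytest.approx(oracle, abs=1e-9)

    def test_weekend_only_rejected(self):
        s = week_series([10, 10], start="2022-09-10")  # Sat, Sun
        with pytest.raises(ValueError):
            average_acceleration(s)


class TestWeightedWeek:
    def test_all_equal(self):
        daily = {pd.Timestamp(f"2022-09-{d:02d}").date(): 7.0
                 for d in range(5, 12)}
        assert weighted_week(daily) == pytest.approx(7.0)

    def test_five_two_arithmetic(self):
        daily = {pd.Timestamp("2022-09-05").date(): 100.0,
                 pd.Timestamp("2022-09-10").date(): 170.0}
        assert weighted_week(daily) == pytest.approx(120.0)

    def test_random_split_matches_oracle(self):
        rng = np.random.default_rng(2)
        dates = pd.date_range("2022-09-05", periods=7).date
        daily = {d: float(rng.uniform(0, 100)) for d in dates}
        wd = [v for d, v in daily.items() if pd.Timestamp(d).weekday() < 5]
        we = [v for d, v in daily.items() if pd.Timestamp(d).weekday() >= 5]
        oracle = (5 * np.mean(wd) + 2 * np.mean(we)) / 7
        assert weighted_week(daily) == pytest.approx(oracle)

    def test_missing_day_type_rejected(self):
        with pytest.raises(ValueError):
            weighted_week({pd.Timestamp("2022-09-05").date(): 1.0})


class TestIntensityGradient:
    def test_power_law_slope_exact(self):
        # minutes(bin) proportional to midpoint^-2 -> slope exactly -2
        mids = np.arange(12.5, 25 * 10, 25.0)
        minutes = 1e5 * mids ** -2.0
        slope, _, r2 = _ig_fit(minutes, mids)
        assert slope == pytest.approx(-2.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_ols_oracle(self):
        rng = np.random.default_rng(4)
        mids = np.arange(12.5, 25 * 8, 25.0)
        minutes = rng.uniform(1, 500, mids.size)
        slope, intercept, _ = _ig_fit(minutes, mids)
        x, y = np.log(mids), np.log(minutes)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert slope == pytest.approx(sxy / sxx)
        assert intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean())

    def test_realistic_day_negative_slope(self, small_cohort):
        slope, _, _ = intensity_gradient(small_cohort.series[0])
        assert slope < 0

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        enmo = rng.gamma(1.2, 40, EPD)
        s1, _, _ = intensity_gradient_day(enmo, 5)
        s2, _, _ = intensity_gradient_day(np.tile(enmo, 2), 5)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            intensity_gradient_day(np.full(EPD, 5.0), 5)
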
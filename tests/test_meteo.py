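"""Meteorological forcing: means, degree days, photoperiod, PET."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchfor import SiteInfo
from switchfor.meteo import (InsufficientInputs, daily_mean_temperature,
                             day_length, degree_days, par_from_solar,
                             pet_penman_monteith, pet_thornthwaite,
                             prepare_forcing, validate_weather)


@pytest.mark.parametrize("tmin,tmax,expected", [
    (0.0, 10.0, 5.0),
    (-5.0, -5.0, -5.0),
    (8.2, 19.6, 13.9),
])
def test_daily_mean_is_midpoint(tmin, tmax, expected):
    assert daily_mean_temperature(tmin, tmax) == pytest.approx(expected)


def test_daily_mean_rejects_inverted_extremes():
    with pytest.raises(ValueError):
        daily_mean_temperature(10.0, 5.0)


@pytest.mark.parametrize("series,base,expected", [
    ([12, 8, 15], 10.0, [2, 2, 7]),
    ([12, 8, 15], 0.0, [12, 20, 35]),
    ([5, -3, 9], 10.0, [0, 0, 0]),
])
def test_degree_days_accumulates_clamped_excess(series, base, expected):
    np.testing.assert_allclose(degree_days(series, base), expected)


def test_degree_days_rejects_empty():
    with pytest.raises(ValueError):
        degree_days([], 10.0)


@given(st.lists(st.floats(-30, 45), min_size=2, max_size=60),
       st.integers(1, 59))
@settings(max_examples=50, deadline=None)
def test_degree_days_split_invariance(tmeans, cut):
    """Splitting a series and summing partial totals matches one pass."""
    cut = min(cut, len(tmeans) - 1)
    whole = degree_days(tmeans, 10.0)[-1]
    left = degree_days(tmeans[:cut], 10.0)[-1]
    right = degree_days(tmeans[cut:], 10.0)[-1]
    assert whole == pytest.approx(left + right, abs=1e-9)
    assert np.all(np.diff(degree_days(tmeans, 10.0)) >= -1e-12)


def test_day_length_reference_points():
    # equator: always close to 12 h
    assert day_length(0.0, 172) == pytest.approx(12.0, abs=0.2)
    # mid-latitude summer solstice from cos(h) = -tan(phi) tan(delta)
    assert day_length(40.0, 172) == pytest.approx(14.9, abs=0.1)
    # polar day
    assert day_length(70.0, 172) == 24.0
    assert day_length(70.0, 355) == 0.0


@given(st.floats(-65, 65), st.integers(1, 365))
@settings(max_examples=100, deadline=None)
def test_day_length_hemispheric_complement(lat, doy):
    """Same day, opposite hemispheres: day lengths sum to 24 h exactly;
    same hemisphere half a year apart: approximately 24 h."""
    assert (day_length(lat, doy) + day_length(-lat, doy)
            == pytest.approx(24.0, abs=1e-9))
    shifted = (doy + 182 - 1) % 365 + 1
    assert (day_length(lat, doy) + day_length(lat, shifted)
            == pytest.approx(24.0, abs=0.3))


@pytest.mark.parametrize("solar,fpar,expected", [
    (0.0, 0.5, 0.0), (20.0, 0.5, 10.0), (20.0, 0.45, 9.0),
])
def test_par_fraction(solar, fpar, expected):
    assert par_from_solar(solar, fpar) == pytest.approx(expected)


def test_par_rejects_negative_radiation():
    with pytest.raises(ValueError):
        par_from_solar(-1.0)


class TestThornthwaite:
    def test_subzero_year_gives_zero(self):
        dates = pd.date_range("2001-01-01", "2001-12-31")
        pet = pet_thornthwaite(dates, np.full(len(dates), -5.0), 45.0)
        assert np.all(pet == 0.0)

    def test_constant_equatorial_climate_is_nearly_uniform(self):
        dates = pd.date_range("2001-01-01", "2001-12-31")
        pet = pet_thornthwaite(dates, np.full(len(dates), 20.0), 0.0)
        monthly = pd.Series(pet, index=dates).resample("MS").sum()
        assert np.all(pet > 0.0)
        # only month length and tiny day-length wiggle differ
        per_day = monthly / monthly.index.days_in_month
        assert per_day.max() / per_day.min() == pytest.approx(1.0, abs=0.02)

    def test_single_warm_month_matches_hand_evaluation(self):
        """One 15 degC July among sub-zero months, evaluated by hand:
        I = (15/5)^1.514, a = cubic(I), PET = 16 (L/12)(N/30)(10T/I)^a."""
        dates = pd.date_range("2001-01-01", "2001-12-31")
        t = np.where(dates.month == 7, 15.0, -2.0)
        pet = pet_thornthwaite(dates, t, 0.0)
        july_total = pet[dates.month == 7].sum()
        heat_index = (15.0 / 5.0) ** 1.514
        a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
             + 1.792e-2 * heat_index + 0.49239)
        mean_l = np.mean(day_length(0.0, dates[dates.month == 7].dayofyear))
        hand = 16.0 * (mean_l / 12.0) * (31 / 30) * (150.0 / heat_index) ** a
        assert july_total == pytest.approx(hand, rel=1e-9)
        assert np.all(pet[dates.month != 7] == 0.0)

    def test_rejects_short_series(self):
        dates = pd.date_range("2001-01-01", periods=200)
        with pytest.raises(ValueError):
            pet_thornthwaite(dates, np.full(200, 10.0), 45.0)


class TestPenmanMonteith:
    def test_reference_worked_example(self):
        """Standard FAO-56 worked example (6 July, 50.8 N, 100 m: Tmax 21.5,
        Tmin 12.3 degC, Rs 22.07 MJ, u2 2.078 m/s, ea 1.409 kPa) -> 3.9 mm."""
        site = SiteInfo(latitude=50.8, elevation=100.0)
        et0 = pet_penman_monteith(
            pd.DatetimeIndex(["2000-07-06"]), [12.3], [21.5], [22.07],
            [2.078], site, ea=[1.409])
        assert et0[0] == pytest.approx(3.9, abs=0.1)

    def test_no_driving_gradient_gives_near_zero(self):
        site = SiteInfo(latitude=40.0)
        et0 = pet_penman_monteith(
            pd.DatetimeIndex(["2000-07-06"]), [15.0], [15.0], [0.0],
            [0.0], site, rh=[100.0])
        assert 0.0 <= et0[0] < 0.3

    def test_deterministic_and_nonnegative(self):
        site = SiteInfo(latitude=36.0)
        dates = pd.DatetimeIndex(["2000-06-01"] * 2)
        args = ([10.0, 10.0], [25.0, 25.0], [20.0, 20.0], [2.0, 2.0])
        et0 = pet_penman_monteith(dates, *args, site, rh=[50.0, 50.0])
        assert et0[0] == et0[1] >= 0.0

    def test_signals_missing_inputs(self):
        site = SiteInfo(latitude=36.0)
        with pytest.raises(InsufficientInputs):
            pet_penman_monteith(pd.DatetimeIndex(["2000-06-01"]),
                                [10], [25], [20], None, site)


class TestWeatherFrame:
    def test_rejects_gapped_series(self):
        df = pd.DataFrame({
            "date": ["2001-01-01", "2001-01-02", "2001-01-04"],
            "tmin": 0.0, "tmax": 5.0, "precip": 0.0, "solar": 10.0})
        with pytest.raises(ValueError, match="contiguous"):
            validate_weather(df)

    def test_rejects_par_above_solar(self):
        df = pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=3),
            "tmin": 0.0, "tmax": 5.0, "precip": 0.0,
            "solar": 10.0, "par": 11.0})
        with pytest.raises(ValueError, match="PAR"):
            validate_weather(df)

    def test_pet_method_selection_follows_available_columns(self, site):
        dates = pd.date_range("2001-01-01", "2002-12-31")
        n = len(dates)
        base = pd.DataFrame({
            "date": dates, "tmin": 5.0, "tmax": 15.0, "precip": 1.0,
            "solar": np.full(n, 15.0)})
        f = prepare_forcing(base, site)
        assert f.attrs["pet_method"] == "thornthwaite"
        withpm = base.assign(wind=2.0, rh=60.0)
        f2 = prepare_forcing(withpm, site)
        assert f2.attrs["pet_method"] == "penman_monteith"
        assert np.all(f["pet"].to_numpy() >= 0.0)
        assert np.all(f2["pet"].to_numpy() >= 0.0)
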
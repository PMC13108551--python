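"""Fixed-window means, relative reproductive periods and window enumeration."""

import numpy as np
import pytest

from thermotrack.calendar365 import doy_from_april_day, doy_from_month_day
from thermotrack.intervals import (Period, enumerate_calendar_windows,
                                   fixed_interval_annual_means,
                                   relative_period_bounds,
                                   relative_period_temperatures,
                                   relative_period_temperature_table)
from thermotrack.io import BreedingAttempt, DailyTemperatureSeries


def _constant_series(years, value):
    return DailyTemperatureSeries({y: np.full(365, float(value)) for y in years})


def _attempt(**kw):
    base = dict(attempt_id="a", year=2000, female_id="f", laying_date=20,
                clutch_size=8, n_fledged=5, n_recruits=1, n_neighbors=2,
                incubation_start=28, hatch_date=41)
    base.update(kw)
    return BreedingAttempt(**base)


class TestFixedInterval:
    def test_constant_series(self):
        ann = fixed_interval_annual_means(_constant_series(range(2000, 2005), 10.0))
        assert len(ann) == 5
        assert np.allclose(ann.values.to_numpy(), 10.0)

    def test_window_has_111_days_and_matches_brute_force(self, rng):
        vals = rng.normal(8, 4, 365)
        s = DailyTemperatureSeries({2000: vals})
        ann = fixed_interval_annual_means(s)
        d0 = doy_from_month_day(2, 15)
        d1 = doy_from_month_day(6, 5)
        assert d1 - d0 + 1 == 111
        brute = sum(vals[d - 1] for d in range(d0, d1 + 1)) / 111
        assert ann.values.loc[2000] == pytest.approx(brute, abs=1e-12)

    def test_incomplete_year_dropped(self):
        vals = np.full(365, 9.0)
        vals[40:80] = np.nan  # > 10% of the fixed window missing
        s = DailyTemperatureSeries({2000: vals, 2001: np.full(365, 9.0)})
        ann = fixed_interval_annual_means(s)
        assert list(ann.years) == [2001]


class TestRelativePeriods:
    def test_worked_example(self):
        """Laying 20 Apr, clutch 8, incubation from 28 Apr, hatch 11 May."""
        a = _attempt(laying_date=20, clutch_size=8, incubation_start=28,
                     hatch_date=41)
        p = relative_period_bounds(a)
        assert p.laying == (20, 27)          # 20-27 Apr, 8 d
        assert p.incubation == (28, 40)      # 28 Apr - 10 May, 13 d
        assert p.hatching == (41, 48)        # 11-18 May, 8 d
        assert p.nestling == (49, 56)        # 19-26 May, 8 d
        assert p.fledging == (57, 62)        # 27 May - 1 Jun, 6 d

    def test_hatching_window_spans_eight_days(self):
        p = relative_period_bounds(_attempt())
        lo, hi = p.hatching
        assert hi - lo + 1 == 8

    def test_periods_partition_full_span(self):
        """With all dates present the five periods tile [laying, hatch+21]."""
        a = _attempt()
        p = relative_period_bounds(a)
        spans = [p.laying, p.incubation, p.hatching, p.nestling, p.fledging]
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert s1 == e0 + 1
        assert spans[0][0] == a.laying_date
        assert spans[-1][1] == a.hatch_date + 21

    def test_laying_fallback_one_egg_per_day(self):
        a = _attempt(incubation_start=None, hatch_date=None)
        p = relative_period_bounds(a)
        assert p.laying == (20, 27)  # laying + clutch - 1
        assert p.incubation is None

    def test_inconsistent_dates_raise(self):
        with pytest.raises(Exception):
            relative_period_bounds(
                _attempt(incubation_start=28, hatch_date=20))


class TestRelativeTemperatures:
    def test_constant_series_every_period(self):
        s = _constant_series([2000], 7.5)
        recs = relative_period_temperatures(_attempt(), s)
        assert {r.period for r in recs} == set(Period)
        assert all(r.mean_temp == pytest.approx(7.5) for r in recs)

    def test_two_day_window_average(self):
        vals = np.full(365, np.nan)
        d = doy_from_april_day(20)
        vals[d - 1], vals[d] = 10.0, 12.0
        s = DailyTemperatureSeries({2000: vals})
        a = _attempt(clutch_size=2, incubation_start=22, hatch_date=None)
        recs = relative_period_temperatures(a, s)
        lay = [r for r in recs if r.period is Period.LAYING][0]
        assert lay.mean_temp == pytest.approx(11.0)

    def test_matches_brute_force_and_stays_in_range(self, rng):
        vals = rng.normal(10, 3, 365)
        s = DailyTemperatureSeries({2000: vals})
        a = _attempt()
        for r in relative_period_temperatures(a, s):
            lo = doy_from_april_day(r.start_april_day)
            hi = doy_from_april_day(r.end_april_day)
            window = vals[lo - 1:hi]
            assert r.mean_temp == pytest.approx(window.mean(), abs=1e-12)
            assert window.min() <= r.mean_temp <= window.max()

    def test_bulk_table_agrees_with_scalar_path(self, rng):
        vals = rng.normal(10, 3, 365)
        s = DailyTemperatureSeries({2000: vals})
        attempts = [_attempt(attempt_id=f"a{i}", laying_date=15 + i,
                             incubation_start=23 + i, hatch_date=36 + i)
                    for i in range(10)]
        table = relative_period_temperature_table(attempts, s)
        for a in attempts:
            for r in relative_period_temperatures(a, s):
                row = table[(table.attempt_id == a.attempt_id)
                            & (table.period == r.period.value)]
                assert row["mean_temp"].iloc[0] == pytest.approx(r.mean_temp)


class TestWindowEnumeration:
    def test_season_has_804_windows(self):
        windows = enumerate_calendar_windows()
        assert len(windows) == 804

    @pytest.mark.parametrize("min_len,max_len", [(8, 15), (3, 3), (1, 10)])
    def test_count_matches_closed_form(self, min_len, max_len):
        windows = enumerate_calendar_windows((2, 15), (6, 5), min_len, max_len)
        span = 111
        assert len(windows) == sum(span - L + 1 for L in range(min_len, max_len + 1))
        # inclusive length bounds
        lengths = {e - s + 1 for s, e in windows}
        assert lengths == set(range(min_len, max_len + 1))

    def test_single_window_when_length_equals_span(self):
        windows = enumerate_calendar_windows((2, 15), (6, 5), 111, 111)
        assert windows == [(doy_from_month_day(2, 15), doy_from_month_day(6, 5))]

    def test_overlong_window_errors(self):
        with pytest.raises(ValueError):
            enumerate_calendar_windows((2, 15), (6, 5), 8, 200)

    def test_deterministic_order(self):
        w1 = enumerate_calendar_windows()
        w2 = enumerate_calendar_windows()
        assert w1 == w2
        lengths = [e - s + 1 for s, e in w1]
        assert lengths == sorted(lengths)
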
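"""Half-fall statistic, match/mismatch, mismatch curves and cue-window search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotrack.calendar365 import doy_from_april_day
from thermotrack.intervals import (Period, enumerate_calendar_windows,
                                   relative_period_temperature_table)
from thermotrack.io import (AnnualSeries, BreedingAttempt, CaterpillarFallSeries,
                            DailyTemperatureSeries)
from thermotrack.phenology import (compute_match, compute_match_table,
                                   cue_window_search, half_fall_date,
                                   half_fall_trend, mismatch_temperature_curve,
                                   temperature_at_half_fall)
from thermotrack.simulate import GeneratorTruth, simulate_climate


def _series(year, counts):
    return CaterpillarFallSeries(year=year, counts=counts)


def _hf_brute_force(counts):
    """Independent oracle: earliest date with cumulative count >= half total."""
    total = sum(counts.values())
    cum = 0
    for doy in sorted(counts):
        cum += counts[doy]
        if cum >= total / 2:
            return doy
    raise AssertionError


class TestHalfFall:
    def test_single_date_carries_everything(self):
        hf = half_fall_date(_series(2000, {140: 50}))
        assert hf.half_fall_doy == 140
        assert hf.total_count == 50

    def test_cumulative_crossing_fixture(self):
        """Counts 10,30,40,20: cumulative 10,40,80 -> third day crosses 50%."""
        hf = half_fall_date(_series(2000, {140: 10, 141: 30, 142: 40, 143: 20}))
        assert hf.half_fall_doy == 142

    def test_exact_half_at_earlier_day_wins(self):
        """Cumulative exactly 50% counts as reached (earliest->=-half rule)."""
        hf = half_fall_date(_series(2000, {140: 10, 141: 40, 142: 50}))
        assert hf.half_fall_doy == 141

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            half_fall_date(_series(2000, {140: 0}))

    def test_april_day_conversion(self):
        hf = half_fall_date(_series(2000, {doy_from_april_day(56): 9}))
        assert hf.half_fall_april_day == 56

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.dictionaries(st.integers(min_value=100, max_value=200),
                           st.integers(min_value=0, max_value=50),
                           min_size=1, max_size=30))
    def test_equals_brute_force_oracle(self, counts):
        if sum(counts.values()) == 0:
            return
        hf = half_fall_date(_series(1999, counts))
        assert hf.half_fall_doy == _hf_brute_force(counts)
        # defining invariant: strictly before the date < half; at the date >= half
        total = hf.total_count
        before = sum(c for d, c in counts.items() if d < hf.half_fall_doy)
        at = before + counts[hf.half_fall_doy]
        assert before < total / 2 <= at


class TestHalfFallTrend:
    def test_five_point_fixture_matches_normal_equations(self):
        years = np.array([2000, 2001, 2002, 2003, 2004])
        hf_days = np.array([60.0, 58.0, 59.0, 55.0, 54.0])
        hfs = [half_fall_date(_series(int(y), {doy_from_april_day(int(d)): 10}))
               for y, d in zip(years, hf_days)]
        fit = half_fall_trend(hfs)
        x = years - years.mean()
        slope = np.dot(x, hf_days - hf_days.mean()) / np.dot(x, x)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.n == 5


class TestTemperatureAtHalfFall:
    @pytest.fixture()
    def flat_series(self):
        return DailyTemperatureSeries({2000: np.full(365, 9.25)})

    def test_constant_series(self, flat_series):
        hf = half_fall_date(_series(2000, {150: 10}))
        assert temperature_at_half_fall(flat_series, hf) == pytest.approx(9.25)

    @pytest.mark.parametrize("halfwidth,n_days", [(7, 15), (15, 31), (20, 41)])
    def test_window_widths_match_brute_force(self, rng, halfwidth, n_days):
        vals = rng.normal(10, 3, 365)
        series = DailyTemperatureSeries({2000: vals})
        hf = half_fall_date(_series(2000, {150: 10}))
        got = temperature_at_half_fall(series, hf, halfwidth=halfwidth)
        window = vals[150 - halfwidth - 1:150 + halfwidth]
        assert len(window) == n_days
        assert got == pytest.approx(window.mean(), abs=1e-12)


class TestMatch:
    def _attempt(self, hatch):
        return BreedingAttempt("a", 2000, "f", 20, 8, 5, 1, 2, 28, hatch)

    def _hf(self, april_day):
        return half_fall_date(_series(2000, {doy_from_april_day(april_day): 10}))

    def test_match_arithmetic(self):
        rec = compute_match(self._attempt(hatch=30), self._hf(42))
        assert rec.match_days == -2
        assert rec.abs_mismatch == 2

    def test_perfect_match_is_zero(self):
        rec = compute_match(self._attempt(hatch=32), self._hf(42))
        assert rec.match_days == 0

    def test_antisymmetry(self):
        """Swapping the demand date (hatch+10) and half-fall flips the sign."""
        a = compute_match(self._attempt(hatch=30), self._hf(42))   # 40 vs 42
        b = compute_match(self._attempt(hatch=32), self._hf(40))   # 42 vs 40
        assert a.match_days == -b.match_days
        assert a.abs_mismatch == b.abs_mismatch >= 0

    def test_missing_hatch_gives_no_record(self):
        att = BreedingAttempt("a", 2000, "f", 20, 8, 5, 1, 2, None, None)
        assert compute_match(att, self._hf(42)) is None

    def test_match_table_restricted_to_half_fall_years(self, small_cohort):
        _, _, attempts, falls, _ = small_cohort
        hfs = [half_fall_date(s) for s in falls[:5] if s.usable]
        table = compute_match_table(attempts, hfs)
        assert set(table.columns) == {"attempt_id", "match_days", "abs_mismatch"}
        years_with_hf = {h.year for h in hfs}
        by_id = {a.attempt_id: a for a in attempts}
        assert all(by_id[i].year in years_with_hf for i in table["attempt_id"])
        assert (table["abs_mismatch"] == table["match_days"].abs()).all()


class TestMismatchCurve:
    def _synthetic(self, rng, t0=10.5, n=2000, flat=False):
        years = rng.integers(0, 25, n)
        fems = rng.integers(0, 100, n)
        temp = rng.normal(t0 + 0.3, 1.5, n)
        mism = (np.full(n, 3.0) if flat
                else (temp - t0) ** 2 + rng.normal(0, 1.0, n))
        attempts = [BreedingAttempt(f"s{i}", 2000 + int(years[i]), f"f{fems[i]}",
                                    20, 8, 5, 1, 3, 28, 41) for i in range(n)]
        temps = pd.DataFrame({
            "attempt_id": [a.attempt_id for a in attempts],
            "period": "laying", "mean_temp": temp,
            "start_april_day": 20, "end_april_day": 27,
            "year": [a.year for a in attempts],
            "female_id": [a.female_id for a in attempts],
            "n_days": 8, "n_missing": 0})
        match = pd.DataFrame({"attempt_id": [a.attempt_id for a in attempts],
                              "match_days": np.rint(mism).astype(int),
                              "abs_mismatch": np.abs(np.rint(mism)).astype(int)})
        return attempts, temps, match

    def test_quadratic_minimum_recovered(self, rng):
        """abs mismatch ~ (T - 10.5)^2: minimiser within 0.5 degC of 10.5."""
        attempts, temps, match = self._synthetic(rng)
        _, mn = mismatch_temperature_curve(attempts, temps, match, "laying",
                                           n_boot=0)
        assert mn.kind == "min"
        assert abs(mn.peak_temp - 10.5) <= 0.5

    def test_constant_mismatch_flagged_unidentifiable(self, rng):
        attempts, temps, match = self._synthetic(rng, flat=True)
        _, mn = mismatch_temperature_curve(attempts, temps, match, "laying",
                                           n_boot=0)
        assert not mn.identifiable

    def test_fledging_period_excluded(self, rng):
        attempts, temps, match = self._synthetic(rng, n=200)
        with pytest.raises(ValueError, match="fledging"):
            mismatch_temperature_curve(attempts, temps, match, "fledging")

    def test_four_periods_produce_curves(self, small_cohort):
        _, clim, attempts, falls, temps = small_cohort
        hfs = [half_fall_date(s) for s in falls if s.usable]
        match = compute_match_table(attempts, hfs)
        fitted = {}
        for period in (Period.LAYING, Period.INCUBATION, Period.HATCHING,
                       Period.NESTLING):
            fit, _ = mismatch_temperature_curve(attempts, temps, match, period,
                                                n_boot=0)
            fitted[period.value] = fit.curve
        assert len(fitted) == 4
        assert all(np.isfinite(c).all() for c in fitted.values())


class TestCueWindowSearch:
    def test_planted_window_recovered(self, rng):
        """Laying driven by one window's mean temperature: AICc finds its start."""
        truth = GeneratorTruth(seed=51)
        series = simulate_climate(truth)
        years, mat = series.matrix()
        true_start, length = 60, 45  # planted cue window
        cue = np.nanmean(mat[:, true_start - 1:true_start - 1 + length], axis=1)
        lay = 70.0 - 6.0 * (cue - cue.mean()) + rng.normal(0, 1.0, len(years))
        ann = AnnualSeries(values=pd.Series(lay, index=pd.Index(years, name="year")))
        candidates = [(s, s + length - 1) for s in range(40, 81)]
        res = cue_window_search(ann, series, candidates)
        assert abs(res.best_window[0] - true_start) <= 2
        assert len(res.support) == len(candidates)

    def test_single_candidate_returned(self, rng):
        truth = GeneratorTruth(seed=52, year_start=2000, year_end=2012)
        series = simulate_climate(truth)
        years = np.array(series.years)
        ann = AnnualSeries(values=pd.Series(rng.normal(70, 4, len(years)),
                                            index=pd.Index(years, name="year")))
        res = cue_window_search(ann, series, [(46, 105)])
        assert res.best_window == (46, 105)
        assert len(res.support) == 1
        assert res.support.loc[0, "delta_aicc"] == 0.0

    def test_needs_ten_years(self, rng):
        truth = GeneratorTruth(seed=53, year_start=2000, year_end=2005)
        series = simulate_climate(truth)
        ann = AnnualSeries(values=pd.Series(
            rng.normal(70, 4, 6), index=pd.Index(series.years, name="year")))
        with pytest.raises(ValueError, match="10 years"):
            cue_window_search(ann, series, [(46, 105)])

    def test_empty_candidates_error(self, rng):
        truth = GeneratorTruth(seed=54, year_start=2000, year_end=2012)
        series = simulate_climate(truth)
        ann = AnnualSeries(values=pd.Series(
            rng.normal(70, 4, 13), index=pd.Index(series.years, name="year")))
        with pytest.raises(ValueError, match="candidate"):
            cue_window_search(ann, series, [])
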
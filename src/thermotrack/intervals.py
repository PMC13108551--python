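"""Fixed- and individually-anchored temperature intervals.

Two perspectives on the thermal environment of a breeding season:

* a **fixed calendar window** (default 15 February – 5 June, 111 days on the
  365-day grid), the same in every year, and all sub-windows of 8–15
  consecutive days within it;
* **relative periods** anchored to each nest's own timing — laying,
  incubation, hatching (hatch to 7 d post-hatch), nestling (8–15 d) and
  fledging (16–21 d).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .calendar365 import doy_from_april_day, doy_from_month_day
from .io import AnnualSeries, BreedingAttempt, DailyTemperatureSeries

__all__ = [
    "Period",
    "ReproductivePeriods",
    "IntervalTemperature",
    "FIXED_WINDOW_START",
    "FIXED_WINDOW_END",
    "fixed_interval_annual_means",
    "relative_period_bounds",
    "relative_period_temperatures",
    "relative_period_temperature_table",
    "enumerate_calendar_windows",
]

#: default fixed-interval anchors (month, day): 15 Feb — 5 Jun
FIXED_WINDOW_START = (2, 15)
FIXED_WINDOW_END = (6, 5)


class Period(str, Enum):
    LAYING = "laying"
    INCUBATION = "incubation"
    HATCHING = "hatching"
    NESTLING = "nestling"
    FLEDGING = "fledging"


#: periods excluded from mismatch models (occur mostly after the food peak)
MISMATCH_PERIODS = (Period.LAYING, Period.INCUBATION, Period.HATCHING, Period.NESTLING)


@dataclass(frozen=True)
class ReproductivePeriods:
    """Closed April-day bounds per reproductive stage; None when undefinable."""

    laying: tuple[int, int] | None
    incubation: tuple[int, int] | None
    hatching: tuple[int, int] | None
    nestling: tuple[int, int] | None
    fledging: tuple[int, int] | None

    def bounds(self, period: Period) -> tuple[int, int] | None:
        return getattr(self, period.value)

    def defined(self) -> list[Period]:
        return [p for p in Period if self.bounds(p) is not None]


@dataclass(frozen=True)
class IntervalTemperature:
    attempt_id: str
    period: Period
    start_april_day: int
    end_april_day: int
    mean_temp: float
    n_days: int
    n_missing: int


def fixed_interval_annual_means(
    series: DailyTemperatureSeries,
    start: tuple[int, int] = FIXED_WINDOW_START,
    end: tuple[int, int] = FIXED_WINDOW_END,
    max_missing_frac: float = 0.10,
) -> AnnualSeries:
    """Per-year mean temperature over the fixed [start, end] window.

    Years with no days in the window are absent; years with more than
    ``max_missing_frac`` missing days are dropped with a flag in the label.
    The attached SE is the standard error of the daily values.
    """
    d0 = doy_from_month_day(*start)
    d1 = doy_from_month_day(*end)
    if d1 < d0:
        raise ValueError("fixed window end precedes start")
    years, mat = series.matrix()
    chunk = mat[:, d0 - 1:d1]
    n_days = d1 - d0 + 1
    n_present = np.isfinite(chunk).sum(axis=1)
    keep = n_present >= (1 - max_missing_frac) * n_days
    flagged = [int(y) for y, ok, n in zip(years, keep, n_present) if not ok and n > 0]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(chunk[keep], axis=1)
        sds = np.nanstd(chunk[keep], axis=1, ddof=1)
    ses = sds / np.sqrt(n_present[keep])
    label = f"fixed window {start}-{end}"
    if flagged:
        label += f" (dropped incomplete years: {flagged})"
    return AnnualSeries(
        values=pd.Series(means, index=pd.Index(years[keep], name="year")),
        se=pd.Series(ses, index=pd.Index(years[keep], name="year")),
        label=label,
    )


def relative_period_bounds(attempt: BreedingAttempt) -> ReproductivePeriods:
    """April-day bounds of the five reproductive periods for one attempt.

    laying = [laying_date, incubation_start - 1], falling back to
    laying_date + clutch_size - 1 for the end when incubation start is
    unrecorded (one egg laid per day); incubation = [incubation_start,
    hatch - 1] so hatch day belongs to the hatching period only; hatching,
    nestling and fledging are hatch+0..7, +8..15 and +16..21.
    """
    lay = attempt.laying_date
    inc = attempt.incubation_start
    hatch = attempt.hatch_date
    if inc is not None and hatch is not None and hatch < inc:
        raise ValueError(f"{attempt.attempt_id}: hatch date precedes incubation start")

    if inc is not None:
        laying = (lay, max(lay, inc - 1))
    else:
        laying = (lay, lay + attempt.clutch_size - 1)

    incubation = None
    if inc is not None and hatch is not None:
        incubation = (inc, max(inc, hatch - 1))

    hatching = nestling = fledging = None
    if hatch is not None:
        hatching = (hatch, hatch + 7)
        nestling = (hatch + 8, hatch + 15)
        fledging = (hatch + 16, hatch + 21)

    return ReproductivePeriods(laying, incubation, hatching, nestling, fledging)


def relative_period_temperatures(
    attempt: BreedingAttempt,
    series: DailyTemperatureSeries,
    min_coverage: float = 0.5,
) -> list[IntervalTemperature]:
    """Window-mean temperature for every defined period of one attempt.

    A record is emitted when at least ``min_coverage`` of the window's days
    are present; the number of missing days is always reported.
    """
    periods = relative_period_bounds(attempt)
    out: list[IntervalTemperature] = []
    for period in Period:
        b = periods.bounds(period)
        if b is None:
            continue
        start_doy = doy_from_april_day(b[0])
        end_doy = doy_from_april_day(b[1])
        mean, n_days, n_missing = series.window_mean(
            attempt.year, start_doy, end_doy, min_coverage=min_coverage)
        if np.isnan(mean):
            continue
        out.append(IntervalTemperature(
            attempt_id=attempt.attempt_id, period=period,
            start_april_day=b[0], end_april_day=b[1],
            mean_temp=mean, n_days=n_days, n_missing=n_missing))
    return out


def relative_period_temperature_table(
    attempts: list[BreedingAttempt],
    series: DailyTemperatureSeries,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Vectorised per-attempt period temperatures for a whole cohort.

    Uses per-year cumulative sums so a 10k-attempt cohort resolves in
    milliseconds.  Columns: attempt_id, year, female_id, period, start/end
    April-day, mean_temp, n_days, n_missing.
    """
    years, mat = series.matrix()
    year_row = {int(y): i for i, y in enumerate(years)}
    filled = np.nan_to_num(mat, nan=0.0)
    csum = np.concatenate([np.zeros((mat.shape[0], 1)), np.cumsum(filled, axis=1)], axis=1)
    cnt = np.concatenate(
        [np.zeros((mat.shape[0], 1)), np.cumsum(np.isfinite(mat), axis=1)], axis=1)

    rows = []
    for a in attempts:
        ri = year_row.get(a.year)
        periods = relative_period_bounds(a)
        for period in Period:
            b = periods.bounds(period)
            if b is None:
                continue
            s = doy_from_april_day(b[0])
            e = doy_from_april_day(b[1])
            n_days = e - s + 1
            if ri is None or s < 1 or e > mat.shape[1]:
                continue
            n_present = int(cnt[ri, e] - cnt[ri, s - 1])
            n_missing = n_days - n_present
            if n_present < max(1, min_coverage * n_days):
                continue
            mean = (csum[ri, e] - csum[ri, s - 1]) / n_present
            rows.append((a.attempt_id, a.year, a.female_id, period.value,
                         b[0], b[1], mean, n_days, n_missing))
    return pd.DataFrame(rows, columns=[
        "attempt_id", "year", "female_id", "period", "start_april_day",
        "end_april_day", "mean_temp", "n_days", "n_missing"])


def enumerate_calendar_windows(
    start: tuple[int, int] = FIXED_WINDOW_START,
    end: tuple[int, int] = FIXED_WINDOW_END,
    min_len: int = 8,
    max_len: int = 15,
) -> list[tuple[int, int]]:
    """All (start_doy, end_doy) windows of min_len..max_len days inside [start, end].

    Lengths are inclusive bounds; windows are ordered by length then start
    day.  For a 111-day season and lengths 8–15 this yields
    sum_L (111 - L + 1) = 804 windows.
    """
    d0 = doy_from_month_day(*start)
    d1 = doy_from_month_day(*end)
    span = d1 - d0 + 1
    if not 1 <= min_len <= max_len:
        raise ValueError("require 1 <= min_len <= max_len")
    if max_len > span:
        raise ValueError(f"max_len {max_len} exceeds span {span}")
    return [(s, s + length - 1)
            for length in range(min_len, max_len + 1)
            for s in range(d0, d1 - length + 2)]
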
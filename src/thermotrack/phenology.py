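"""Caterpillar half-fall timing, trophic match/mismatch, and the laying-cue window.

The half-fall date — the earliest day by which the cumulative water-trap
count reaches 50% of the seasonal total — proxies the peak of caterpillar
availability.  Match for a nest is ``(hatch date + 10) - half-fall date``
(nestling food demand peaks around day 10); its absolute value measures
trophic desynchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar365 import april_day_from_doy, doy_from_april_day
from .fitness import (FitnessModelResult, PeakEstimate, fit_fitness_spline_model,
                      locate_peak_with_interval)
from .intervals import MISMATCH_PERIODS, Period
from .io import AnnualSeries, BreedingAttempt, CaterpillarFallSeries, DailyTemperatureSeries
from .trends import TrendFit, fit_annual_trend

__all__ = [
    "HalfFallEstimate", "MismatchRecord", "half_fall_date", "half_fall_trend",
    "temperature_at_half_fall", "temperature_at_half_fall_series",
    "compute_match", "compute_match_table", "mismatch_temperature_curve",
    "cue_window_search", "CueWindowResult",
]

#: nestling food demand peaks at about this age (days post-hatch)
PEAK_DEMAND_AGE = 10


@dataclass(frozen=True)
class HalfFallEstimate:
    year: int
    half_fall_doy: int
    half_fall_april_day: int
    total_count: int


@dataclass(frozen=True)
class MismatchRecord:
    attempt_id: str
    match_days: int
    abs_mismatch: int


def half_fall_date(series: CaterpillarFallSeries) -> HalfFallEstimate:
    """Earliest date whose cumulative count reaches half the seasonal total."""
    total = series.total
    if total <= 0:
        raise ValueError(f"year {series.year}: zero seasonal total, unusable")
    half = total / 2.0
    cum = 0
    for doy in sorted(series.counts):
        cum += series.counts[doy]
        if cum >= half:
            return HalfFallEstimate(
                year=series.year, half_fall_doy=doy,
                half_fall_april_day=april_day_from_doy(doy), total_count=total)
    raise AssertionError("unreachable: cumulative count never reached half")


def half_fall_trend(half_falls: list[HalfFallEstimate]) -> TrendFit:
    """OLS trend of the half-fall April-day on year."""
    ann = AnnualSeries(values=pd.Series(
        {hf.year: float(hf.half_fall_april_day) for hf in half_falls}),
        label="half-fall April-day")
    return fit_annual_trend(ann)


def temperature_at_half_fall(
    series: DailyTemperatureSeries,
    hf: HalfFallEstimate,
    halfwidth: int = 7,
) -> float:
    """Mean temperature over half-fall +- halfwidth days (15 days at default)."""
    mean, _, _ = series.window_mean(
        hf.year, hf.half_fall_doy - halfwidth, hf.half_fall_doy + halfwidth)
    return mean


def temperature_at_half_fall_series(
    series: DailyTemperatureSeries,
    half_falls: list[HalfFallEstimate],
    halfwidth: int = 7,
) -> AnnualSeries:
    vals = {}
    for hf in half_falls:
        t = temperature_at_half_fall(series, hf, halfwidth=halfwidth)
        if np.isfinite(t):
            vals[hf.year] = t
    return AnnualSeries(values=pd.Series(vals),
                        label=f"temperature at half-fall +-{halfwidth} d")


def compute_match(attempt: BreedingAttempt, hf: HalfFallEstimate) -> MismatchRecord | None:
    """match = (hatch date + 10) - half-fall date, on the April-day scale.

    None (with no record) when the hatch date is missing or the half-fall
    estimate belongs to another year.
    """
    if attempt.hatch_date is None or hf.year != attempt.year:
        return None
    match = (attempt.hatch_date + PEAK_DEMAND_AGE) - hf.half_fall_april_day
    return MismatchRecord(attempt_id=attempt.attempt_id, match_days=int(match),
                          abs_mismatch=int(abs(match)))


def compute_match_table(
    attempts: list[BreedingAttempt],
    half_falls: list[HalfFallEstimate],
) -> pd.DataFrame:
    """Match/mismatch records for every attempt with a usable half-fall year."""
    by_year = {hf.year: hf for hf in half_falls}
    rows = []
    for a in attempts:
        hf = by_year.get(a.year)
        if hf is None:
            continue
        rec = compute_match(a, hf)
        if rec is not None:
            rows.append((rec.attempt_id, rec.match_days, rec.abs_mismatch))
    return pd.DataFrame(rows, columns=["attempt_id", "match_days", "abs_mismatch"])


def mismatch_temperature_curve(
    attempts: list[BreedingAttempt],
    interval_temps: pd.DataFrame,
    mismatch: pd.DataFrame,
    period: Period | str,
    df_spline: int = 7,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[FitnessModelResult, PeakEstimate]:
    """Gaussian spline model of absolute mismatch on period temperature.

    Returns the fitted curve and the minimizing temperature with its
    bootstrap interval.  The fledging period is excluded (it falls mostly
    after the food peak).
    """
    period = Period(period)
    if period not in MISMATCH_PERIODS:
        raise ValueError(f"mismatch models exclude the {period.value} period")
    ids = set(mismatch["attempt_id"])
    restricted = [a for a in attempts if a.attempt_id in ids]
    fit = fit_fitness_spline_model(
        restricted, interval_temps, response="abs_mismatch", period=period,
        df_spline=df_spline, mismatch=mismatch, include_mismatch=False,
        family="gaussian")
    minimum = locate_peak_with_interval(fit, n_boot=n_boot, seed=seed, kind="min")
    return fit, minimum


@dataclass
class CueWindowResult:
    """AICc ranking of candidate cue windows for annual mean laying date."""

    best_window: tuple[int, int]          # (start_doy, end_doy)
    support: pd.DataFrame                 # one row per candidate, AICc ascending


def cue_window_search(
    annual_laying_means: AnnualSeries,
    series: DailyTemperatureSeries,
    candidate_windows: list[tuple[int, int]],
) -> CueWindowResult:
    """Which calendar window's mean temperature best predicts laying date?

    One OLS of annual mean laying date on the window's annual mean
    temperature per candidate; candidates ranked by AICc (equivalent to R^2
    ranking at fixed n for a single predictor).
    """
    if not candidate_windows:
        raise ValueError("no candidate windows")
    if len(annual_laying_means) < 10:
        raise ValueError("cue-window search needs >= 10 years")
    years = annual_laying_means.years
    lay = annual_laying_means.values.to_numpy()
    ymat_years, mat = series.matrix(years)
    rows = []
    n = len(years)
    k = 3  # intercept, slope, residual variance
    for (s, e) in candidate_windows:
        with np.errstate(invalid="ignore"):
            tmean = np.nanmean(mat[:, s - 1:e], axis=1)
        ok = np.isfinite(tmean)
        if ok.sum() < 10:
            continue
        x = tmean[ok] - tmean[ok].mean()
        y = lay[ok]
        slope = float(np.dot(x, y) / np.dot(x, x))
        resid = y - y.mean() - slope * x
        nn = int(ok.sum())
        rss = float(np.dot(resid, resid))
        aicc = nn * np.log(rss / nn) + 2 * k + 2 * k * (k + 1) / (nn - k - 1)
        r2 = 1.0 - rss / float(np.dot(y - y.mean(), y - y.mean()))
        rows.append((s, e, e - s + 1, slope, r2, aicc, nn))
    support = pd.DataFrame(rows, columns=[
        "start_doy", "end_doy", "length", "slope", "r_squared", "aicc", "n_years"])
    if support.empty:
        raise ValueError("no candidate window overlaps the data")
    support = support.sort_values(["aicc", "start_doy", "length"]).reset_index(drop=True)
    support["delta_aicc"] = support["aicc"] - support["aicc"].iloc[0]
    best = (int(support.loc[0, "start_doy"]), int(support.loc[0, "end_doy"]))
    return CueWindowResult(best_window=best, support=support)
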
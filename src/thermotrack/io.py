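"""Domain containers and file I/O for temperature, breeding and caterpillar data.

Three tabular inputs drive the analysis:

* a daily mean-temperature series (tidy CSV or the Met Office CET daily
  fixed-layout dialect),
* a breeding-attempt table (one row per nest, timing on the April-day scale),
* per-year caterpillar water-trap counts.

Everything is validated on ingest; 29 February is dropped so all years share
the 365-day grid of :mod:`thermotrack.calendar365`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io as _io
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar365 import (
    DAYS_PER_YEAR,
    april_day_from_doy,
    doy_from_april_day,
    doy_from_month_day,
    month_day_from_doy,
)

__all__ = [
    "DailyTemperatureSeries",
    "BreedingAttempt",
    "CaterpillarFallSeries",
    "AnnualSeries",
    "ValidationError",
    "read_daily_temperature",
    "write_daily_temperature",
    "read_breeding_table",
    "write_breeding_table",
    "read_caterpillar_counts",
    "write_caterpillar_counts",
]

#: CET missing-value sentinel (tenths of a degree); after /10 scaling any
#: value below -90 degC is treated as missing.
CET_MISSING_SENTINEL = -999
MISSING_CELSIUS_FLOOR = -90.0

BREEDING_COLUMNS = [
    "attempt_id", "year", "female_id", "laying_april_day", "clutch_size",
    "incubation_start_april_day", "hatch_april_day", "n_fledged",
    "n_recruits", "n_neighbors",
]


class ValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Daily temperature series
# ---------------------------------------------------------------------------

class DailyTemperatureSeries:
    """Calendar-indexed daily mean temperatures (degC) on the 365-day grid.

    Internally one float vector of length 365 per year, NaN marking missing
    days; this makes month-day anchored window means identical operations in
    every year.
    """

    def __init__(self, data: Mapping[int, np.ndarray], provenance: str = ""):
        self._data: dict[int, np.ndarray] = {}
        for year, arr in sorted(data.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (DAYS_PER_YEAR,):
                raise ValidationError(
                    f"year {year}: expected {DAYS_PER_YEAR} daily slots, got {arr.shape}")
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite < MISSING_CELSIUS_FLOOR).any():
                raise ValidationError(f"year {year}: temperature below {MISSING_CELSIUS_FLOOR} degC")
            self._data[int(year)] = arr
        self.provenance = provenance

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, years: Iterable[int], doys: Iterable[int],
                     temps: Iterable[float], provenance: str = "") -> "DailyTemperatureSeries":
        years = np.asarray(list(years), dtype=int)
        doys = np.asarray(list(doys), dtype=int)
        temps = np.asarray(list(temps), dtype=float)
        if not (years.shape == doys.shape == temps.shape):
            raise ValidationError("years, doys and temps must have equal length")
        if ((doys < 1) | (doys > DAYS_PER_YEAR)).any():
            raise ValidationError("day-of-year out of [1, 365]")
        if not np.isfinite(temps).all():
            raise ValidationError("non-finite temperature value")
        data: dict[int, np.ndarray] = {}
        for y in np.unique(years):
            data[int(y)] = np.full(DAYS_PER_YEAR, np.nan)
        seen: set[tuple[int, int]] = set()
        for y, d, t in zip(years, doys, temps):
            key = (int(y), int(d))
            if key in seen:
                raise ValidationError(f"duplicate date: year {y} doy {d}")
            seen.add(key)
            data[int(y)][d - 1] = t
        return cls(data, provenance=provenance)

    # -- queries ------------------------------------------------------------

    @property
    def years(self) -> list[int]:
        """Years with at least one observed day, ascending."""
        return [y for y, a in self._data.items() if np.isfinite(a).any()]

    def year_values(self, year: int) -> np.ndarray:
        """The 365-vector for one year (NaN = missing); read-only view."""
        v = self._data[year].view()
        v.flags.writeable = False
        return v

    def matrix(self, years: Iterable[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(years, n_years x 365 array) for the requested (default: all) years."""
        ys = np.asarray(sorted(self.years) if years is None else list(years), dtype=int)
        out = np.full((len(ys), DAYS_PER_YEAR), np.nan)
        for i, y in enumerate(ys):
            if int(y) in self._data:
                out[i] = self._data[int(y)]
        return ys, out

    def get(self, year: int, doy: int) -> float:
        """Temperature for (year, doy); NaN if missing or year absent."""
        arr = self._data.get(year)
        return float("nan") if arr is None else float(arr[doy - 1])

    def window_mean(self, year: int, start_doy: int, end_doy: int,
                    min_coverage: float = 0.5) -> tuple[float, int, int]:
        """Mean over the closed doy window; returns (mean, n_days, n_missing).

        The mean is NaN when fewer than ``min_coverage`` of the days are
        present.  Windows must not wrap the year boundary.
        """
        if end_doy < start_doy:
            raise ValueError("window end before start")
        arr = self._data.get(year)
        n_days = end_doy - start_doy + 1
        if arr is None:
            return float("nan"), n_days, n_days
        chunk = arr[start_doy - 1:end_doy]
        n_missing = int(np.isnan(chunk).sum())
        if n_days - n_missing < max(1, min_coverage * n_days):
            return float("nan"), n_days, n_missing
        return float(np.nanmean(chunk)), n_days, n_missing

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns date (ISO, non-leap grid), year, doy, tmean_c."""
        rows = []
        for y, arr in self._data.items():
            present = np.flatnonzero(np.isfinite(arr))
            for d in present:
                month, day = month_day_from_doy(int(d) + 1)
                rows.append((f"{y:04d}-{month:02d}-{day:02d}", y, int(d) + 1, arr[d]))
        return pd.DataFrame(rows, columns=["date", "year", "doy", "tmean_c"])

    def __len__(self) -> int:
        return int(sum(np.isfinite(a).sum() for a in self._data.values()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ys = self.years
        span = f"{ys[0]}-{ys[-1]}" if ys else "empty"
        return f"DailyTemperatureSeries({len(self)} days, {span})"


def _parse_iso_date(text: str) -> tuple[int, int, int]:
    d = _dt.date.fromisoformat(str(text).strip())
    return d.year, d.month, d.day


def read_daily_temperature(path: str | Path, dialect: str = "tidy_csv") -> DailyTemperatureSeries:
    """Read a daily temperature file.

    ``tidy_csv``: columns ``date`` (ISO-8601) and ``tmean_c`` (degC).
    ``cet_daily``: the Met Office Hadley Centre daily layout — whitespace
    rows of ``year day m1 … m12`` in tenths of a degree, -999 missing.
    29 February rows are dropped in both dialects.
    """
    path = Path(path)
    if dialect == "tidy_csv":
        return _read_tidy_csv(path)
    if dialect == "cet_daily":
        return _read_cet_daily(path)
    raise ValueError(f"unknown temperature dialect: {dialect!r}")


def _read_tidy_csv(path: Path) -> DailyTemperatureSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    for col in ("date", "tmean_c"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    years, doys, temps = [], [], []
    for _, row in df.iterrows():
        y, m, d = _parse_iso_date(row["date"])
        if m == 2 and d == 29:
            continue
        t = float(row["tmean_c"])
        if not np.isfinite(t) or t < MISSING_CELSIUS_FLOOR:
            continue
        years.append(y)
        doys.append(doy_from_month_day(m, d))
        temps.append(t)
    return DailyTemperatureSeries.from_records(years, doys, temps, provenance=str(path))


def _read_cet_daily(path: Path) -> DailyTemperatureSeries:
    data: dict[int, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 14:
                raise ValidationError(
                    f"{path}:{lineno}: expected 14 columns (year day m1..m12), got {len(parts)}")
            try:
                year, day = int(parts[0]), int(parts[1])
                tenths = [int(p) for p in parts[2:]]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer field") from exc
            if not 1 <= day <= 31:
                raise ValidationError(f"{path}:{lineno}: day {day} out of range")
            arr = data.setdefault(year, np.full(DAYS_PER_YEAR, np.nan))
            for month0, v in enumerate(tenths):
                month = month0 + 1
                if v == CET_MISSING_SENTINEL:
                    continue
                try:
                    doy = doy_from_month_day(month, day)
                except ValueError:
                    continue  # 29-31 Feb, 31 Apr, ... : layout padding / leap day
                t = v / 10.0
                if t < MISSING_CELSIUS_FLOOR:
                    continue
                arr[doy - 1] = t
    empty = [y for y, a in data.items() if not np.isfinite(a).any()]
    for y in empty:
        warnings.warn(f"CET file {path}: year {y} has no usable days; dropped")
        del data[y]
    if not data:
        raise ValidationError(f"{path}: no usable temperature data")
    return DailyTemperatureSeries(data, provenance=str(path))


def write_daily_temperature(series: DailyTemperatureSeries, path: str | Path) -> None:
    """Write the tidy CSV dialect (columns date, tmean_c)."""
    df = series.to_frame()[["date", "tmean_c"]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Breeding attempts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreedingAttempt:
    """One nesting attempt; timing on the April-day scale (1 = 1 April)."""

    attempt_id: str
    year: int
    female_id: str
    laying_date: int
    clutch_size: int
    n_fledged: int
    n_recruits: int
    n_neighbors: int
    incubation_start: int | None = None
    hatch_date: int | None = None

    def validate(self) -> None:
        if self.clutch_size < 1:
            raise ValidationError(f"{self.attempt_id}: clutch_size must be >= 1")
        if self.n_fledged < 0 or self.n_recruits < 0 or self.n_neighbors < 0:
            raise ValidationError(f"{self.attempt_id}: negative count")
        if self.n_fledged > self.clutch_size:
            raise ValidationError(
                f"{self.attempt_id}: n_fledged ({self.n_fledged}) exceeds "
                f"clutch_size ({self.clutch_size})")
        if self.n_recruits > self.n_fledged:
            raise ValidationError(
                f"{self.attempt_id}: n_recruits ({self.n_recruits}) exceeds "
                f"n_fledged ({self.n_fledged})")
        if self.incubation_start is not None and self.laying_date > self.incubation_start:
            raise ValidationError(f"{self.attempt_id}: laying_date after incubation_start")
        if (self.incubation_start is not None and self.hatch_date is not None
                and self.incubation_start > self.hatch_date):
            raise ValidationError(f"{self.attempt_id}: incubation_start after hatch_date")

    @property
    def laying_doy(self) -> int:
        return doy_from_april_day(self.laying_date)


def _opt_int(cell) -> int | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return None
    return int(float(cell))


def read_breeding_table(path: str | Path, strict: bool = True) -> list[BreedingAttempt]:
    """Read and validate the breeding-attempt CSV.

    ``strict=True`` raises on the first invalid row (with its id); otherwise
    invalid rows are dropped with a warning naming each.
    """
    df = pd.read_csv(path, dtype={"attempt_id": str, "female_id": str})
    missing = [c for c in BREEDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    attempts: list[BreedingAttempt] = []
    for idx, row in df.iterrows():
        try:
            a = BreedingAttempt(
                attempt_id=str(row["attempt_id"]),
                year=int(row["year"]),
                female_id=str(row["female_id"]),
                laying_date=int(row["laying_april_day"]),
                clutch_size=int(row["clutch_size"]),
                incubation_start=_opt_int(row["incubation_start_april_day"]),
                hatch_date=_opt_int(row["hatch_april_day"]),
                n_fledged=int(row["n_fledged"]),
                n_recruits=int(row["n_recruits"]),
                n_neighbors=int(row["n_neighbors"]),
            )
            a.validate()
        except (ValidationError, ValueError) as exc:
            msg = f"{path} row {idx + 2}: {exc}"
            if strict:
                raise ValidationError(msg) from exc
            warnings.warn(msg)
            continue
        attempts.append(a)
    return attempts


def attempts_to_frame(attempts: Iterable[BreedingAttempt]) -> pd.DataFrame:
    rows = []
    for a in attempts:
        rows.append((a.attempt_id, a.year, a.female_id, a.laying_date, a.clutch_size,
                     a.incubation_start, a.hatch_date, a.n_fledged, a.n_recruits,
                     a.n_neighbors))
    df = pd.DataFrame(rows, columns=[
        "attempt_id", "year", "female_id", "laying_april_day", "clutch_size",
        "incubation_start_april_day", "hatch_april_day", "n_fledged", "n_recruits",
        "n_neighbors"])
    return df


def write_breeding_table(attempts: Iterable[BreedingAttempt], path: str | Path) -> None:
    df = attempts_to_frame(attempts)
    for col in ("incubation_start_april_day", "hatch_april_day"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Caterpillar water-trap counts
# ---------------------------------------------------------------------------

@dataclass
class CaterpillarFallSeries:
    """Daily water-trap caterpillar counts for one year (doy -> count)."""

    year: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for doy, c in sorted(self.counts.items()):
            c = int(c)
            if c < 0:
                raise ValidationError(f"year {self.year} doy {doy}: negative count {c}")
            clean[int(doy)] = c
        self.counts = clean

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def usable(self) -> bool:
        return self.total > 0


def read_caterpillar_counts(path: str | Path) -> list[CaterpillarFallSeries]:
    """Read the caterpillar CSV (year, date, count) into per-year series."""
    df = pd.read_csv(path)
    for col in ("year", "date", "count"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    by_year: dict[int, dict[int, int]] = {}
    for idx, row in df.iterrows():
        year = int(row["year"])
        _, m, d = _parse_iso_date(row["date"])
        if m == 2 and d == 29:
            continue
        c = int(row["count"])
        if c < 0:
            raise ValidationError(f"{path} row {idx + 2}: negative count {c}")
        doy = doy_from_month_day(m, d)
        by_year.setdefault(year, {})
        by_year[year][doy] = by_year[year].get(doy, 0) + c
    return [CaterpillarFallSeries(year=y, counts=cnt) for y, cnt in sorted(by_year.items())]


def write_caterpillar_counts(series: Iterable[CaterpillarFallSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for doy, c in sorted(s.counts.items()):
            month, day = month_day_from_doy(doy)
            rows.append((s.year, f"{s.year:04d}-{month:02d}-{day:02d}", c))
    pd.DataFrame(rows, columns=["year", "date", "count"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annual summaries
# ---------------------------------------------------------------------------

@dataclass
class AnnualSeries:
    """Yearly values (optionally with standard errors), e.g. window means."""

    values: pd.Series          # index: year, ascending
    se: pd.Series | None = None
    label: str = ""

    def __post_init__(self) -> None:
        v = pd.Series(self.values).astype(float)
        if v.index.duplicated().any():
            raise ValidationError("duplicate years in AnnualSeries")
        v = v.sort_index()
        if not np.isfinite(v.to_numpy()).all():
            raise ValidationError("non-finite annual value")
        self.values = v
        if self.se is not None:
            self.se = pd.Series(self.se).astype(float).reindex(v.index)

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "value": self.values.to_numpy()})
        if self.se is not None:
            df["se"] = self.se.to_numpy()
        return df
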
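"""365-day calendar grid shared by every module.

All temperature windows, breeding periods and phenology statistics live on a
fixed 365-day year (29 February is dropped on ingest), so a month-day anchor
such as 15 February addresses the same grid cell in every year.  Two
coordinate systems are used:

* ``doy`` — day of the 365-day year, 1 = 1 January … 365 = 31 December.
* ``April-day`` — breeding-season scale, 1 = 1 April (31 March = 0,
  1 March = -30).
"""

from __future__ import annotations

import numpy as np

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
MONTH_STARTS = tuple(int(x) for x in np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]]))

#: doy of 1 April minus one; april_day = doy - APRIL_OFFSET
APRIL_OFFSET = MONTH_STARTS[3]  # 90

DAYS_PER_YEAR = 365


def doy_from_month_day(month: int, day: int) -> int:
    """Day-of-year (1-based) on the 365-day grid for a (month, day) anchor."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= MONTH_LENGTHS[month - 1]:
        raise ValueError(f"day out of range for month {month}: {day}")
    return MONTH_STARTS[month - 1] + day


def month_day_from_doy(doy: int) -> tuple[int, int]:
    """Inverse of :func:`doy_from_month_day`."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"doy out of range: {doy}")
    month = int(np.searchsorted(MONTH_STARTS, doy, side="left"))
    return month, doy - MONTH_STARTS[month - 1]


def april_day_from_doy(doy: int) -> int:
    return doy - APRIL_OFFSET


def doy_from_april_day(april_day: int) -> int:
    return april_day + APRIL_OFFSET


def format_month_day(doy: int) -> str:
    month, day = month_day_from_doy(doy)
    names = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
             "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
    return f"{day:02d} {names[month - 1]}"
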
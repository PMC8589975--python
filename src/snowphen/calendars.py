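"""Day-of-year calendar conventions.

All dates are 1-based integer days of a 365-day year (Jan 1 = 1).  Leap days
are normalised out: a Feb 29 observation is mapped to Feb 28 before
conversion, so day-of-year values are comparable across years.
"""

from __future__ import annotations

import datetime as _dt

# cumulative days before each month in a non-leap year
_CUM = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)

APR_1 = 91
MAY_1 = 121
MAY_15 = 135
JUN_24 = 175
AUG_31 = 243

_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def doy(month: int, day: int) -> int:
    """Day-of-year of (month, day) in the 365-day convention."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return _CUM[month - 1] + day


def date_to_doy(date: _dt.date) -> int:
    """Convert a calendar date, mapping Feb 29 to Feb 28."""
    if date.month == 2 and date.day == 29:
        return doy(2, 28)
    # computed from month/day, not the ordinal, so leap years stay aligned
    return doy(date.month, date.day)


def iso_to_year_doy(iso: str) -> tuple[int, int]:
    date = _dt.date.fromisoformat(iso)
    return date.year, date_to_doy(date)


def doy_to_iso(year: int, day: int) -> str:
    """Inverse of :func:`date_to_doy` for a non-leap day grid."""
    day = int(day)
    if not 1 <= day <= 365:
        raise ValueError(f"day-of-year out of range: {day}")
    month = 0
    while month < 11 and _CUM[month + 1] < day:
        month += 1
    dom = day - _CUM[month]
    return f"{year:04d}-{month + 1:02d}-{dom:02d}"


def format_doy(day: float) -> str:
    """Human-readable 'Jun 24'-style label for a (possibly fractional) day."""
    d = int(round(day))
    d = min(max(d, 1), 365)
    month = 0
    while month < 11 and _CUM[month + 1] < d:
        month += 1
    return f"{_MONTHS[month]} {d - _CUM[month]}"
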
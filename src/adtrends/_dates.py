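"""Calendar arithmetic helpers.

All interval logic in the package uses half-open day-resolution intervals
``[start, end)`` expressed as :class:`datetime.date` or proleptic-Gregorian
ordinals.  Month and year offsets are true calendar offsets with end-of-month
clamping (Jan 31 + 1 month = Feb 28/29), matching how prescription gaps and
registration lookbacks are stated in months and years.
"""

from __future__ import annotations

import calendar
from datetime import date

__all__ = [
    "add_months",
    "add_years",
    "year_start",
    "year_start_ordinal",
    "days_in_year",
    "to_date",
]


def add_months(d: date, months: int) -> date:
    """Return ``d`` shifted by ``months`` calendar months, day-of-month clamped."""
    y, m = divmod((d.year * 12 + d.month - 1) + months, 12)
    m += 1
    day = min(d.day, calendar.monthrange(y, m)[1])
    return date(y, m, day)


def add_years(d: date, years: int) -> date:
    """Return ``d`` shifted by whole calendar years (Feb 29 clamps to Feb 28)."""
    return add_months(d, 12 * years)


def year_start(year: int) -> date:
    return date(year, 1, 1)


def year_start_ordinal(year: int) -> int:
    return date(year, 1, 1).toordinal()


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def to_date(value) -> date:
    """Coerce a date-like value (date, Timestamp, ISO string) to datetime.date."""
    if isinstance(value, date) and type(value) is date:
        return value
    if hasattr(value, "date"):  # Timestamp / datetime
        return value.date()
    return date.fromisoformat(str(value))
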
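"""Half-day time indexing and the Rabi/Zaid/Kharif season calendar.

The simulator advances in half-day steps (a morning and an afternoon market
session per calendar day).  Day 1 is 2017-10-01; its morning is half-day 1 and
its afternoon half-day 2, so morning indices are odd.  The season calendar
gates marketing frequency, land allocation and yields: farmers market once
every 5 days in Rabi (Oct-Feb), every 7 in Zaid (Mar-May) and every 8 in
Kharif (Jun-Sep).  Aggregation happens on mornings only; self-supplying
farmers may visit the market in either session.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "EPOCH",
    "SCENARIO_START",
    "HORIZON_END",
    "MORNING",
    "AFTERNOON",
    "Season",
    "RABI",
    "ZAID",
    "KHARIF",
    "SEASONS",
    "HalfDay",
    "season_of",
    "half_day_count",
    "index_of",
    "date_of",
    "marketing_fraction",
    "iter_half_days",
    "is_season_start",
]

#: First simulated calendar day (morning = half-day index 1).
EPOCH = dt.date(2017, 10, 1)
#: Future scenarios switch on at this morning.
SCENARIO_START = dt.date(2018, 10, 1)
#: Last simulated calendar day.
HORIZON_END = dt.date(2021, 9, 30)

MORNING = "morning"
AFTERNOON = "afternoon"


@dataclass(frozen=True)
class Season:
    """One cropping season: its months and the marketing-trip interval."""

    name: str
    months: frozenset
    marketing_interval_days: int


RABI = Season("Rabi", frozenset({10, 11, 12, 1, 2}), 5)
ZAID = Season("Zaid", frozenset({3, 4, 5}), 7)
KHARIF = Season("Kharif", frozenset({6, 7, 8, 9}), 8)
SEASONS = (RABI, ZAID, KHARIF)

_MONTH_TO_SEASON = {m: s for s in SEASONS for m in s.months}
# First calendar day of each season (year-independent month/day).
_SEASON_START_MONTHS = {10: RABI, 3: ZAID, 6: KHARIF}


def season_of(date: dt.date) -> Season:
    """Season containing *date* (month lookup, year independent).

    The leap day 2020-02-29 falls in February and is therefore a Rabi day.
    """
    return _MONTH_TO_SEASON[date.month]


def half_day_count(start_date: dt.date, end_date: dt.date) -> int:
    """Number of half-days in the inclusive interval [start_date, end_date].

    One calendar day contributes two half-days; the proleptic Gregorian
    calendar (via :mod:`datetime`) handles leap years.
    """
    if start_date > end_date:
        raise ValueError(
            f"start_date {start_date} is after end_date {end_date}"
        )
    return 2 * ((end_date - start_date).days + 1)


def index_of(date: dt.date, phase: str = MORNING) -> int:
    """1-based half-day index of (date, phase) relative to :data:`EPOCH`."""
    days = (date - EPOCH).days
    if phase == MORNING:
        return 2 * days + 1
    if phase == AFTERNOON:
        return 2 * days + 2
    raise ValueError(f"unknown phase {phase!r}")


def date_of(index: int) -> tuple:
    """Inverse of :func:`index_of`: (date, phase) of a 1-based index."""
    if index < 1:
        raise ValueError("half-day index is 1-based")
    days, rem = divmod(index - 1, 2)
    return EPOCH + dt.timedelta(days=days), MORNING if rem == 0 else AFTERNOON


@dataclass(frozen=True)
class HalfDay:
    """One simulation timestep."""

    index: int
    date: dt.date
    phase: str

    @property
    def season(self) -> Season:
        return season_of(self.date)

    @property
    def is_morning(self) -> bool:
        return self.phase == MORNING


def marketing_fraction(season: Season, *, loop: bool, phase: str) -> float:
    """Fraction of a farmer population marketing on one half-day.

    Self-supplying (non-Loop channel) farmers spread 1/interval_days over
    both sessions; Loop aggregation concentrates the whole 1/interval_days
    on the morning session and contributes nothing in the afternoon.
    """
    interval = season.marketing_interval_days
    if loop:
        return 1.0 / interval if phase == MORNING else 0.0
    return 1.0 / (2 * interval)


def is_season_start(date: dt.date) -> bool:
    """True on the first calendar day of a season (investment evaluation day)."""
    return date.day == 1 and date.month in _SEASON_START_MONTHS


def iter_half_days(
    start_date: dt.date = EPOCH, end_date: dt.date = HORIZON_END
) -> Iterator[HalfDay]:
    """Iterate morning/afternoon half-days over an inclusive date range."""
    if start_date > end_date:
        raise ValueError("start_date after end_date")
    day = start_date
    one = dt.timedelta(days=1)
    while day <= end_date:
        base = index_of(day, MORNING)
        yield HalfDay(base, day, MORNING)
        yield HalfDay(base + 1, day, AFTERNOON)
        day = day + one
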
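"""Gestational famine-exposure classification from birth-record dates.

The Dutch Hunger Winter rationing fell below 900 kcal/day between
1944-11-26 and 1945-05-15.  A pregnancy is assigned to one of five
gestational exposure windows from the mother's last menstrual period
(LMP): a 10-week gestational window counts as exposed when it was
entirely contained in the ration-restriction interval, which translates
into fixed LMP date ranges per window.  Because the famine lasted about
six months, an LMP can fall in at most two (adjacent) windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date

import pandas as pd

__all__ = [
    "GestationalWindow",
    "RationCalendar",
    "ExposureRecord",
    "WINDOW_LMP_RANGES",
    "classify_lmp",
    "any_gestational_exposure",
    "weeks_exposed",
    "classify_cohort",
]


class GestationalWindow(enum.Enum):
    """Five gestational timing windows, in chronological LMP order.

    ``WEEKS_MINUS9_0`` is the peri-conception group (exposure up to ~9
    weeks before and ~8 weeks after conception).
    """

    WEEKS_31_DELIVERY = "weeks_31_delivery"
    WEEKS_21_30 = "weeks_21_30"
    WEEKS_11_20 = "weeks_11_20"
    WEEKS_1_10 = "weeks_1_10"
    WEEKS_MINUS9_0 = "weeks_minus9_0"


#: LMP date ranges per window, both endpoints inclusive.
WINDOW_LMP_RANGES: dict[GestationalWindow, tuple[date, date]] = {
    GestationalWindow.WEEKS_31_DELIVERY: (date(1944, 4, 30), date(1944, 8, 24)),
    GestationalWindow.WEEKS_21_30: (date(1944, 7, 9), date(1944, 10, 15)),
    GestationalWindow.WEEKS_11_20: (date(1944, 9, 17), date(1944, 12, 24)),
    GestationalWindow.WEEKS_1_10: (date(1944, 11, 26), date(1945, 3, 4)),
    GestationalWindow.WEEKS_MINUS9_0: (date(1945, 2, 4), date(1945, 5, 12)),
}

#: Chronological (LMP) order; adjacency below refers to this ordering.
_WINDOW_ORDER = list(GestationalWindow)


@dataclass(frozen=True)
class RationCalendar:
    """Interval during which central rations fell below a kcal threshold."""

    famine_start: date = date(1944, 11, 26)
    famine_end: date = date(1945, 5, 15)
    threshold_kcal: int = 900

    def __post_init__(self) -> None:
        if self.famine_start >= self.famine_end:
            raise ValueError("famine_start must precede famine_end")


@dataclass(frozen=True)
class ExposureRecord:
    participant_id: str
    windows: frozenset[GestationalWindow]
    any_exposure: bool
    weeks_exposed: int


def classify_lmp(lmp: date) -> set[GestationalWindow]:
    """Return every gestational window whose LMP range contains ``lmp``.

    Both endpoints of each published range are inclusive.  Out-of-range
    dates (control birth years) yield the empty set.
    """
    if not isinstance(lmp, date):
        raise TypeError("lmp must be a datetime.date")
    return {
        w for w, (lo, hi) in WINDOW_LMP_RANGES.items() if lo <= lmp <= hi
    }


def any_gestational_exposure(
    windows: set[GestationalWindow], include_periconception: bool = True
) -> bool:
    """True iff the participant was exposed in at least one window.

    ``include_periconception=False`` does not count participants whose
    only window is the peri-conception group (``WEEKS_MINUS9_0``).
    """
    if include_periconception:
        return len(windows) > 0
    return len(windows - {GestationalWindow.WEEKS_MINUS9_0}) > 0


def weeks_exposed(
    lmp: date, birth: date, calendar: RationCalendar | None = None
) -> int:
    """Completed weeks of gestation overlapping the ration restriction.

    Floor of (days in the intersection of [lmp, birth] and
    [famine_start, famine_end]) / 7; partial weeks do not count.
    """
    calendar = calendar or RationCalendar()
    if birth <= lmp:
        raise ValueError(f"birth date {birth} must be after LMP {lmp}")
    overlap_start = max(lmp, calendar.famine_start)
    overlap_end = min(birth, calendar.famine_end)
    days = max((overlap_end - overlap_start).days, 0)
    return days // 7


def classify_cohort(
    cohort: pd.DataFrame,
    lmp_col: str = "lmp_date",
    birth_col: str = "birth_date",
    include_periconception: bool = True,
) -> pd.DataFrame:
    """Annotate a cohort table with exposure windows and weeks exposed.

    Adds ``windows`` (semicolon-joined labels), one 0/1 indicator column
    per window (``win_<label>``), ``any_exposure`` (0/1) and
    ``weeks_exposed``.  Dates may be ISO-8601 strings or date objects.
    """
    out = cohort.copy()
    lmps = [_as_date(v) for v in out[lmp_col]]
    births = [_as_date(v) for v in out[birth_col]]
    window_sets = [classify_lmp(d) for d in lmps]
    out["windows"] = [
        ";".join(w.value for w in _WINDOW_ORDER if w in ws) for ws in window_sets
    ]
    for w in _WINDOW_ORDER:
        out[f"win_{w.value}"] = [int(w in ws) for ws in window_sets]
    out["any_exposure"] = [
        int(any_gestational_exposure(ws, include_periconception))
        for ws in window_sets
    ]
    out["weeks_exposed"] = [
        weeks_exposed(l, b) for l, b in zip(lmps, births)
    ]
    return out


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))
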
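"""Run-timing statistics and experienced-temperature summaries.

Entry and exit timing of each contingent-year is summarised by first,
median and last dates (medians on ordinal day numbers; even group sizes
round down to the earlier day), and by the 50%-incidence date — the first
date on which at least half of the contingent's eventual entrants have
crossed the entry threshold. "Experienced temperature" is the monitored
water temperature on that date, from the single mid-river monitoring
series, regardless of fish position.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import RunSegment


@dataclass
class IncidenceCurve:
    """Cumulative count of fish having entered, by date, one contingent-year."""

    dates: list[dt.date]
    cumulative: np.ndarray

    def __post_init__(self):
        if len(self.dates) == 0:
            raise ValidationError("empty incidence curve")
        if np.any(np.diff(self.cumulative) < 0):
            raise ValidationError("cumulative incidence must be nondecreasing")

    @property
    def n_fish(self) -> int:
        return int(self.cumulative[-1])


@dataclass
class RunPhenologyStats:
    contingent: str
    year: int
    n_fish: int
    first_entry: dt.date
    median_entry: dt.date
    last_entry: dt.date
    first_exit: dt.date
    median_exit: dt.date
    last_exit: dt.date
    date_50pct_incidence: dt.date
    temp_at_50pct: float | None


def _median_date(dates: list[dt.date]) -> dt.date:
    """Median on ordinal day numbers; even n rounds down to the earlier day."""
    ordinals = sorted(d.toordinal() for d in dates)
    n = len(ordinals)
    if n % 2:
        mid = ordinals[n // 2]
    else:
        mid = (ordinals[n // 2 - 1] + ordinals[n // 2]) // 2
    return dt.date.fromordinal(mid)


def incidence_curve(entry_dates: list[dt.date]) -> IncidenceCurve:
    if not entry_dates:
        raise ValidationError("no entry dates")
    start, end = min(entry_dates), max(entry_dates)
    axis = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    entries = np.array(sorted(d.toordinal() for d in entry_dates))
    cumulative = np.searchsorted(entries, [d.toordinal() for d in axis], side="right")
    return IncidenceCurve(dates=axis, cumulative=cumulative)


def incidence_50_date(curve: IncidenceCurve) -> dt.date:
    """First date with cumulative count >= ceil(n / 2)."""
    need = -(-curve.n_fish // 2)
    idx = int(np.searchsorted(curve.cumulative, need, side="left"))
    return curve.dates[idx]


def temperature_at(environment: pd.DataFrame, date: dt.date) -> float:
    """Exact lookup in the daily gap-free environmental series."""
    hit = environment.loc[environment["date"] == date, "water_temp_C"]
    if hit.empty:
        raise ValidationError(f"date {date.isoformat()} outside environmental series")
    return float(hit.iloc[0])


def run_stats(
    segments: list[RunSegment],
    contingent: str,
    year: int,
    environment: pd.DataFrame | None = None,
) -> RunPhenologyStats:
    """Timing statistics for one contingent-year's run segments."""
    if not segments:
        raise ValidationError(f"no run segments for {contingent} {year}")
    entries = [s.entry_date for s in segments]
    exits = [s.exit_date for s in segments]
    date50 = incidence_50_date(incidence_curve(entries))
    temp = temperature_at(environment, date50) if environment is not None else None
    return RunPhenologyStats(
        contingent=contingent,
        year=year,
        n_fish=len(segments),
        first_entry=min(entries),
        median_entry=_median_date(entries),
        last_entry=max(entries),
        first_exit=min(exits),
        median_exit=_median_date(exits),
        last_exit=max(exits),
        date_50pct_incidence=date50,
        temp_at_50pct=temp,
    )
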
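"""Detection events to equal-length daily spawning-phenology series.

The clustering stage consumes, per fish and year, a dense daily river-km
series. This module builds it in four steps:

1. ``daily_mean_position`` — arithmetic mean river km of each day's
   detections (shelf-region receivers, which have no river km, are dropped);
2. ``impute_gaps`` — interior gaps filled with a two-sided 4-day
   exponential-weighted moving average (weight ``2**-d`` at day-distance
   ``d``), falling back to linear interpolation across gaps wider than the
   window;
3. ``extract_run`` — the run is the span between the outermost days at or
   above the entry/exit threshold (river km 43 by default); a fish that
   never crosses it that year skipped spawning;
4. ``catenate_pad`` — all runs of a cohort-year are placed on the union date
   axis and padded at both ends with a constant anchor (river km 35), which
   preserves calendar information and penalises alignment of runs far apart
   in time.

Provenance of every daily value is kept as one of {"observed", "imputed",
"pad"}; observed values are never modified by imputation.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, ValidationError
from .io import local_date

log = logging.getLogger("runcontingent")

OBSERVED = "observed"
IMPUTED = "imputed"
PAD = "pad"


@dataclass
class RunSegment:
    """One fish's spawning run in one year: the series between the outermost
    threshold crossings (sub-threshold dips inside the run are retained)."""

    tag_id: str
    year: int
    entry_date: dt.date
    exit_date: dt.date
    series: pd.DataFrame  # columns: date, river_km, provenance

    def __post_init__(self):
        if self.entry_date > self.exit_date:
            raise ValidationError("entry_date after exit_date")


@dataclass
class PhenologySeries:
    """Equal-length padded daily series, the unit the clustering consumes."""

    tag_id: str
    year: int
    dates: list[dt.date]
    values: np.ndarray
    provenance: list[str] = field(repr=False, default_factory=list)


def daily_mean_position(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    utc_offset_hours: float = -5.0,
) -> pd.Series:
    """Sparse date -> mean river km for one tag's detections.

    Detections at shelf-region receivers (no river km) are excluded from
    positions; an unknown receiver_id raises :class:`ValidationError`.
    """
    known = set(receivers["receiver_id"])
    unknown = set(detections["receiver_id"]) - known
    if unknown:
        raise ValidationError(f"unresolvable receiver_id(s): {sorted(unknown)}")
    km_of = receivers.set_index("receiver_id")["river_km"]
    km = detections["receiver_id"].map(km_of)
    dates = local_date(detections["timestamp"], utc_offset_hours)
    frame = pd.DataFrame({"date": dates, "river_km": km}).dropna(subset=["river_km"])
    if frame.empty:
        return pd.Series(dtype=float, name="river_km")
    out = frame.groupby("date")["river_km"].mean()
    out.name = "river_km"
    return out


def impute_gaps(sparse: pd.Series, window: int = 4) -> pd.DataFrame:
    """Dense daily series over the observed range with provenance flags.

    Each missing interior day is filled with sum(w_i x_i)/sum(w_i) over
    observed values within ``window`` days each side, w = 2**(-d) for
    day-distance d. Gaps with no observed neighbour in the window fall back
    to linear interpolation between the nearest observations (logged).
    """
    if len(sparse) < 2:
        raise ValidationError("need >= 2 observed days to impute")
    sparse = sparse.sort_index()
    obs_dates = np.array([d.toordinal() for d in sparse.index])
    obs_vals = sparse.to_numpy(dtype=float)
    full = np.arange(obs_dates[0], obs_dates[-1] + 1)
    values = np.empty(len(full))
    prov = np.empty(len(full), dtype=object)
    observed_at = dict(zip(obs_dates, obs_vals))
    fallback = []
    for i, day in enumerate(full):
        if day in observed_at:
            values[i] = observed_at[day]
            prov[i] = OBSERVED
            continue
        d = np.abs(obs_dates - day)
        in_win = d <= window
        if in_win.any():
            w = 2.0 ** (-d[in_win].astype(float))
            values[i] = np.dot(w, obs_vals[in_win]) / w.sum()
        else:
            values[i] = np.interp(day, obs_dates, obs_vals)
            fallback.append(day)
        prov[i] = IMPUTED
    if fallback:
        log.info(
            "gap wider than imputation window: linear fallback on %d day(s) "
            "starting %s",
            len(fallback),
            dt.date.fromordinal(fallback[0]).isoformat(),
        )
    return pd.DataFrame(
        {
            "date": [dt.date.fromordinal(int(day)) for day in full],
            "river_km": values,
            "provenance": prov,
        }
    )


def extract_run(
    dense: pd.DataFrame,
    tag_id: str,
    year: int,
    threshold_km: float = 43.0,
) -> RunSegment | None:
    """Slice the spawning run out of a dense daily series.

    Entry is the first day at or above ``threshold_km``, exit the last; the
    slice keeps any sub-threshold dips between them. Returns ``None`` when
    the fish never crosses the threshold (skipped spawning that year).
    """
    above = dense["river_km"].to_numpy() >= threshold_km
    if not above.any():
        return None
    idx = np.flatnonzero(above)
    first, last = int(idx[0]), int(idx[-1])
    segment = dense.iloc[first : last + 1].reset_index(drop=True)
    return RunSegment(
        tag_id=tag_id,
        year=year,
        entry_date=segment["date"].iloc[0],
        exit_date=segment["date"].iloc[-1],
        series=segment,
    )


def catenate_pad(
    segments: list[RunSegment], pad_km: float = 35.0
) -> list[PhenologySeries]:
    """Pad all runs of a cohort-year to the union date axis with ``pad_km``.

    The common axis spans [min entry, max exit] over the cohort; every
    series is front- and tail-padded with the constant anchor so all have
    identical length.
    """
    if not segments:
        raise EmptyCohortError("catenate_pad received no run segments")
    start = min(s.entry_date for s in segments)
    end = max(s.exit_date for s in segments)
    n = (end - start).days + 1
    axis = [start + dt.timedelta(days=i) for i in range(n)]
    out = []
    for seg in segments:
        values = np.full(n, float(pad_km))
        prov = [PAD] * n
        offset = (seg.entry_date - start).days
        m = len(seg.series)
        values[offset : offset + m] = seg.series["river_km"].to_numpy()
        prov[offset : offset + m] = list(seg.series["provenance"])
        out.append(
            PhenologySeries(
                tag_id=seg.tag_id,
                year=seg.year,
                dates=axis,
                values=values,
                provenance=prov,
            )
        )
    return out


def series_table(series_list: list[PhenologySeries]) -> pd.DataFrame:
    """Long-format table (tag_id, year, date, river_km, provenance)."""
    rows = []
    for s in series_list:
        rows.append(
            pd.DataFrame(
                {
                    "tag_id": s.tag_id,
                    "year": s.year,
                    "date": s.dates,
                    "river_km": np.round(s.values, 1),
                    "provenance": s.provenance,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
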
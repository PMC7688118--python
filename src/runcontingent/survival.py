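"""Contingent-specific attrition: loss rates, Kaplan-Meier, weighted log-rank.

The attrition model follows last-detection logic: a tagged fish's last
detection date separates its period at large (alive) from its assumed loss
from the sample. Three estimators are provided:

* ``loss_rate`` — the instantaneous daily loss rate Z, the negative slope
  of an ordinary least-squares fit of ln(extant count) on day index
  (exponential attrition, N(t) = N0 * exp(-Z t));
* ``kaplan_meier`` — the product-limit survival curve with Greenwood
  standard errors and pointwise normal 95% intervals;
* ``weighted_logrank`` — a two-group weighted log-rank chi-square (1 df)
  with log-rank, Gehan, or Peto-Peto weights; the Peto-Peto weight at event
  time t_j is the modified pooled survival estimate
  S~(t_j) = prod_{i<=j} (1 - d_i / (n_i + 1)), which emphasises early
  differences between the curves.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

WEIGHT_SCHEMES = ("logrank", "gehan", "peto-peto")


@dataclass
class SurvivalRecord:
    """Per-fish interval from origin (run exit) to last detection."""

    tag_id: str
    group: str
    origin_date: dt.date
    end_date: dt.date
    event: bool  # True = assumed death; False = right-censored

    def __post_init__(self):
        if self.end_date < self.origin_date:
            raise ValidationError(
                f"{self.tag_id}: end_date precedes origin_date"
            )

    @property
    def time_days(self) -> int:
        return (self.end_date - self.origin_date).days


@dataclass
class LossRateFit:
    Z: float  # instantaneous daily loss rate, d^-1
    intercept: float
    r_squared: float
    n_dates: int


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times (days)
    n_at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    std_err: np.ndarray  # Greenwood SE of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> tuple[float, float]:
        """(S(t), SE) at time t (step function; S(0)=1 before first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 0.0
        return float(self.survival[idx]), float(self.std_err[idx])


@dataclass
class TwoGroupTest:
    statistic: float
    p_value: float
    weights: str
    df: int = 1


def build_records(
    last_detections: dict[str, dt.date],
    origins: dict[str, dt.date],
    groups: dict[str, str],
    period_start: dt.date,
    period_end: dt.date,
    censor_window_days: int = 30,
) -> list[SurvivalRecord]:
    """Survival records from per-fish last-detection and origin dates.

    A fish whose last detection falls within ``censor_window_days`` of the
    period end is right-censored at the period end (it may simply not have
    been heard yet); otherwise its last detection is the event date. Fish
    without a detection in the period, or with an origin after the period
    end, are excluded.
    """
    records = []
    for tag, last in last_detections.items():
        if tag not in origins or tag not in groups:
            continue
        origin = origins[tag]
        if last < period_start and origin < period_start:
            continue
        if origin > period_end:
            continue
        last = min(last, period_end)
        origin = max(origin, period_start)
        if (period_end - last).days <= censor_window_days:
            records.append(
                SurvivalRecord(tag, groups[tag], origin, period_end, event=False)
            )
        else:
            records.append(
                SurvivalRecord(tag, groups[tag], origin, max(last, origin), event=True)
            )
    return records


def extant_counts(records: list[SurvivalRecord]) -> pd.Series:
    """Number of individuals extant (at large) on each day since origin."""
    horizon = max(r.time_days for r in records)
    days = np.arange(horizon + 1)
    counts = np.zeros(horizon + 1, dtype=int)
    for r in records:
        counts[: r.time_days + 1] += 1
    return pd.Series(counts, index=days, name="extant")


def loss_rate(counts: pd.Series, period: tuple[int, int] | None = None) -> LossRateFit:
    """OLS of ln(count) on day index; Z is the negative slope.

    Zero-count days are excluded (log undefined); at least 3 usable days
    are required.
    """
    series = counts if period is None else counts.loc[period[0] : period[1]]
    series = series[series > 0]
    if len(series) < 3:
        raise ValidationError("loss_rate needs >= 3 dates with positive counts")
    x = series.index.to_numpy(dtype=float)
    y = np.log(series.to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    return LossRateFit(
        Z=-float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_dates=len(series),
    )


def kaplan_meier(records: list[SurvivalRecord], alpha: float = 0.05) -> KMCurve:
    """Product-limit estimator with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i);
    SE(t) = S(t) * sqrt(sum d_i / (n_i (n_i - d_i))), terms with
    n_i == d_i contributing a zero-survival point with SE 0.
    """
    if not records:
        raise ValidationError("kaplan_meier requires >= 1 record")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    S = 1.0
    greenwood = 0.0
    rows = []
    z = stats.norm.ppf(1 - alpha / 2)
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum(events & (times == t)))
        S *= 1.0 - d_i / n_i
        if n_i > d_i:
            greenwood += d_i / (n_i * (n_i - d_i))
            se = S * np.sqrt(greenwood)
        else:
            se = 0.0
        rows.append((t, n_i, d_i, S, se))
    if not rows:
        rows = []
    arr = np.array(rows, dtype=float).reshape(-1, 5)
    survival = arr[:, 3]
    se = arr[:, 4]
    return KMCurve(
        times=arr[:, 0],
        n_at_risk=arr[:, 1].astype(int),
        deaths=arr[:, 2].astype(int),
        survival=survival,
        std_err=se,
        ci_lower=np.clip(survival - z * se, 0.0, 1.0),
        ci_upper=np.clip(survival + z * se, 0.0, 1.0),
    )


def _pooled_tables(records_a, records_b):
    times = np.concatenate(
        [[r.time_days for r in records_a], [r.time_days for r in records_b]]
    ).astype(float)
    events = np.concatenate(
        [[r.event for r in records_a], [r.event for r in records_b]]
    ).astype(bool)
    in_a = np.concatenate(
        [np.ones(len(records_a), bool), np.zeros(len(records_b), bool)]
    )
    event_times = np.unique(times[events])
    return times, events, in_a, event_times


def weighted_logrank(
    records_a: list[SurvivalRecord],
    records_b: list[SurvivalRecord],
    weights: str = "peto-peto",
) -> TwoGroupTest:
    """Two-group weighted log-rank chi-square test (1 df).

    At each pooled event time t_j with n_j at risk, d_j deaths, n_Aj at
    risk in group A and d_Aj deaths in A:

      E_Aj = d_j n_Aj / n_j
      V_Aj = d_j (n_Aj/n_j) (1 - n_Aj/n_j) (n_j - d_j) / (n_j - 1)
      statistic = (sum_j w_j (d_Aj - E_Aj))^2 / sum_j w_j^2 V_Aj

    with w_j = 1 (log-rank), n_j (Gehan), or the Peto-Peto modified pooled
    survival estimate prod_{i<=j} (1 - d_i/(n_i + 1)).
    """
    if weights not in WEIGHT_SCHEMES:
        raise ValidationError(f"weights must be one of {WEIGHT_SCHEMES}")
    times, events, in_a, event_times = _pooled_tables(records_a, records_b)
    if len(event_times) == 0:
        raise ValidationError("weighted_logrank requires >= 1 event")
    num = 0.0
    den = 0.0
    s_tilde = 1.0
    for t in event_times:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int((events & (times == t)).sum())
        n_aj = int((at_risk & in_a).sum())
        d_aj = int((events & (times == t) & in_a).sum())
        if weights == "logrank":
            w = 1.0
        elif weights == "gehan":
            w = float(n_j)
        else:
            s_tilde *= 1.0 - d_j / (n_j + 1)
            w = s_tilde
        e_aj = d_j * n_aj / n_j
        if n_j > 1:
            v_aj = d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
        else:
            v_aj = 0.0
        num += w * (d_aj - e_aj)
        den += w * w * v_aj
    if den == 0.0:
        return TwoGroupTest(statistic=0.0, p_value=1.0, weights=weights)
    chi2 = num * num / den
    return TwoGroupTest(
        statistic=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        weights=weights,
    )


def km_table(curve: KMCurve, group: str, year: int | None = None) -> pd.DataFrame:
    """Stepwise KM curve as a long-format table."""
    df = pd.DataFrame(
        {
            "group": group,
            "time_days": curve.times.astype(int),
            "n_at_risk": curve.n_at_risk,
            "deaths": curve.deaths,
            "survival": curve.survival,
            "std_err": curve.std_err,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
    if year is not None:
        df.insert(1, "year", year)
    return df
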
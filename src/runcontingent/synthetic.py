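"""Synthetic acoustic-telemetry cohorts with known contingent structure.

The generator emulates a two-contingent spring spawning run in a long,
linear estuary instrumented with fixed receivers: a lower-reach contingent
targeting river km 90-100 with retreats delimited near km 95, and an
upper-reach contingent targeting km 160-200 that does not retreat below
~km 150. Entry dates pulse in mid/late April, runs end by early June, and
each fish's latent daily track is piecewise-linear (ascent, residence with
up-estuary excursions, descent) with Gaussian speed noise. Detections are
emitted at the nearest river receiver on a per-day Bernoulli basis, leaving
gaps for the imputation stage; after run exit, fish at large emit sparse
detections on shelf-region arrays until an exponentially distributed death
time or the study end. Ground-truth labels, entry/exit dates and death
dates are returned for recovery testing.

Mortality is two-phase: for ``vulnerable_days`` after run exit (default 60,
the period when departing fish first enter shelf fisheries) the hazard is
the contingent-specific rate (defaults about 5e-3 vs 1e-3 per day); after
that a common baseline hazard applies (default 5e-4 per day). The defaults
give annual post-run survivals near 0.64 and 0.81 for the two contingents.
Year-to-year contingent fidelity defaults to 0.89.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LOWER = "lower"
UPPER = "upper"

_SHELF_REGIONS = ("MA", "NYB", "LIS", "DE")


@dataclass
class ContingentParams:
    """Movement and mortality parameters for one contingent."""

    entry_month_day: tuple[int, int]
    entry_sd_days: float
    target_km_range: tuple[float, float]
    retreat_floor_km: float
    post_run_hazard_per_day: float

    def validate(self, name: str) -> None:
        lo, hi = self.target_km_range
        if not lo <= hi:
            raise ValidationError(f"{name}: bad target_km_range {self.target_km_range}")
        if self.retreat_floor_km > hi:
            raise ValidationError(
                f"{name}: retreat floor {self.retreat_floor_km} above target reach"
            )
        if self.post_run_hazard_per_day < 0:
            raise ValidationError(f"{name}: hazard must be >= 0")


@dataclass
class SyntheticConfig:
    n_fish_lower: int = 30
    n_fish_upper: int = 30
    lower: ContingentParams = field(
        default_factory=lambda: ContingentParams(
            entry_month_day=(4, 18),
            entry_sd_days=6.0,
            target_km_range=(90.0, 100.0),
            retreat_floor_km=95.0,
            post_run_hazard_per_day=4.9e-3,
        )
    )
    upper: ContingentParams = field(
        default_factory=lambda: ContingentParams(
            entry_month_day=(4, 22),
            entry_sd_days=6.0,
            target_km_range=(160.0, 200.0),
            retreat_floor_km=150.0,
            post_run_hazard_per_day=1.0e-3,
        )
    )
    n_excursions_mean: float = 2.0
    travel_speed_kmd_mean: float = 15.0
    travel_speed_kmd_sd: float = 3.0
    residence_days_mean: float = 20.0
    residence_days_sd: float = 5.0
    daily_detection_prob: float = 0.65
    shelf_detection_prob: float = 0.2
    repeat_fidelity_prob: float = 0.89
    vulnerable_days: int = 60
    baseline_hazard_per_day: float = 5.0e-4
    jitter_km_sd: float = 1.0
    start_km: float = 38.0
    river_max_km: float = 245.0
    receiver_spacing_km: float = 5.0
    temp_start_C: float = 4.0
    temp_end_C: float = 23.0
    temp_midpoint_month_day: tuple[int, int] = (4, 28)
    temp_scale_days: float = 10.0
    discharge_base_m3s: float = 300.0
    freshet_amplitude_m3s: float = 600.0
    freshet_peak_month_day: tuple[int, int] = (4, 15)
    freshet_width_days: float = 15.0
    years: tuple[int, int] = (2017, 2018)
    seed: int = 0

    def __post_init__(self):
        for p in (self.daily_detection_prob, self.shelf_detection_prob, self.repeat_fidelity_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        self.lower.validate("lower")
        self.upper.validate("upper")

    def params(self, contingent: str) -> ContingentParams:
        return self.lower if contingent == LOWER else self.upper


@dataclass
class SyntheticDataset:
    detections: pd.DataFrame
    receivers: pd.DataFrame
    fish: pd.DataFrame
    environment: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        det = self.detections.copy()
        det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        det.to_csv(out / "detections.csv", index=False)
        self.receivers.to_csv(out / "receivers.csv", index=False)
        self.fish.to_csv(out / "fish.csv", index=False)
        self.environment.to_csv(out / "environment.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def default_receivers(config: SyntheticConfig) -> pd.DataFrame:
    """One river station per spacing interval from km 43 up, plus shelf arrays."""
    kms = np.arange(43.0, config.river_max_km + 1e-9, config.receiver_spacing_km)
    rows = [
        {"receiver_id": f"R{int(km):03d}", "river_km": float(km), "region": ""}
        for km in kms
    ]
    rows += [
        {"receiver_id": f"S_{reg}", "river_km": np.nan, "region": reg}
        for reg in _SHELF_REGIONS
    ]
    return pd.DataFrame(rows)


def simulate_track(
    entry_date: dt.date,
    target_km: float,
    floor_km: float,
    speed_kmd: float,
    residence_days: float,
    n_excursions: int,
    rng: np.random.Generator,
    jitter_km_sd: float = 1.0,
    start_km: float = 38.0,
    threshold_km: float = 43.0,
    river_max_km: float = 245.0,
) -> tuple[list[dt.date], np.ndarray]:
    """Latent daily river-km path for one fish-year.

    Piecewise-linear waypoints: ascent from below the threshold to the
    target reach, residence split around ``n_excursions`` retreat-and-return
    excursions bounded below by the effective floor, then descent. The day
    the path first reaches the threshold is aligned to ``entry_date``.
    """
    if speed_kmd <= 0:
        raise ValidationError("speed must be positive")
    floor = min(floor_km, target_km)
    # waypoints as (river_km, dwell_days_after_reaching)
    hold = residence_days / (n_excursions + 1)
    waypoints: list[tuple[float, float]] = [(start_km, 0.0), (target_km, hold)]
    for _ in range(n_excursions):
        retreat = floor + rng.uniform(0.0, 0.3) * max(target_km - floor, 0.0)
        waypoints.append((retreat, 0.0))
        waypoints.append((target_km, hold))
    waypoints.append((start_km, 0.0))

    t = [0.0]
    km = [waypoints[0][0]]
    for (k0, _), (k1, dwell) in zip(waypoints, waypoints[1:]):
        t.append(t[-1] + abs(k1 - k0) / speed_kmd)
        km.append(k1)
        if dwell > 0:
            t.append(t[-1] + dwell)
            km.append(k1)
    days = np.arange(0.0, np.ceil(t[-1]) + 1.0)
    path = np.interp(days, t, km)
    if jitter_km_sd > 0:
        jitter = rng.normal(0.0, jitter_km_sd, size=len(path))
        path = path + jitter
    # enforce construction constraints: interior bounded by the floor,
    # everything bounded by the river, endpoints below the threshold
    at_target = np.flatnonzero(np.interp(days, t, km) >= target_km - 1e-6)
    if len(at_target):
        lo, hi = at_target[0], at_target[-1]
        path[lo : hi + 1] = np.clip(path[lo : hi + 1], floor, None)
    path = np.clip(path, 0.0, river_max_km)
    path[0] = min(path[0], start_km)
    path[-1] = min(path[-1], start_km)

    crossing = np.flatnonzero(path >= threshold_km)
    align = int(crossing[0]) if len(crossing) else 0
    first_date = entry_date - dt.timedelta(days=align)
    dates = [first_date + dt.timedelta(days=int(d)) for d in range(len(path))]
    return dates, path


def emit_detections(
    dates: list[dt.date],
    path: np.ndarray,
    receivers: pd.DataFrame,
    daily_detection_prob: float,
    rng: np.random.Generator,
    tag_id: str = "fish",
    utc_offset_hours: float = -5.0,
    max_gap_km: float | None = None,
) -> pd.DataFrame:
    """Bernoulli per-day detections at the nearest river receiver.

    Detected days emit 1-3 events at local times within the day; undetected
    days leave gaps for the imputer. With ``max_gap_km`` set, days when the
    latent position lies further than that from every receiver (e.g. below
    the bottom of the array) emit nothing: receivers have finite range.
    """
    river = receivers.dropna(subset=["river_km"]).sort_values("river_km")
    if river.empty:
        raise ValidationError("emit_detections requires river receivers")
    kms = river["river_km"].to_numpy()
    ids = river["receiver_id"].to_numpy()
    rows = []
    for date, km in zip(dates, path):
        if rng.random() >= daily_detection_prob:
            continue
        nearest = int(np.argmin(np.abs(kms - km)))
        if max_gap_km is not None and abs(kms[nearest] - km) > max_gap_km:
            continue
        for _ in range(int(rng.integers(1, 4))):
            hour = float(rng.uniform(0.0, 24.0))
            ts = (
                pd.Timestamp(date, tz="UTC")
                + pd.Timedelta(hours=hour)
                - pd.Timedelta(hours=utc_offset_hours)
            )
            rows.append({"timestamp": ts, "tag_id": tag_id, "receiver_id": ids[nearest]})
    return pd.DataFrame(rows, columns=["timestamp", "tag_id", "receiver_id"])


def simulate_mortality(
    exit_date: dt.date,
    hazard_per_day: float,
    study_end: dt.date,
    rng: np.random.Generator,
) -> tuple[dt.date, bool]:
    """Exponential death time after run exit; survivors censored at study end.

    Returns (last alive date, event flag); event True means death occurred
    on or before the study end.
    """
    if hazard_per_day < 0:
        raise ValidationError("hazard must be >= 0")
    if study_end < exit_date:
        raise ValidationError("study_end precedes exit_date: invalid window")
    if hazard_per_day == 0:
        return study_end, False
    t = rng.exponential(1.0 / hazard_per_day)
    death = exit_date + dt.timedelta(days=int(np.ceil(t)))
    if death <= study_end:
        return death, True
    return study_end, False


def simulate_environment(
    year: int,
    config: SyntheticConfig,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> pd.DataFrame:
    """Daily temperature (monotone logistic, ~4 to ~23 C over spring) and
    discharge (baseline plus a Gaussian spring freshet pulse) for one year."""
    start = start or dt.date(year, 3, 1)
    end = end or dt.date(year, 12, 31)
    n = (end - start).days + 1
    dates = [start + dt.timedelta(days=i) for i in range(n)]
    mid = dt.date(year, *config.temp_midpoint_month_day)
    t = np.array([(d - mid).days for d in dates], dtype=float)
    span = config.temp_end_C - config.temp_start_C
    if config.temp_scale_days <= 0:
        temp = config.temp_start_C + span * (t >= 0)
    else:
        temp = config.temp_start_C + span / (1.0 + np.exp(-t / config.temp_scale_days))
    peak = dt.date(year, *config.freshet_peak_month_day)
    tp = np.array([(d - peak).days for d in dates], dtype=float)
    discharge = config.discharge_base_m3s + config.freshet_amplitude_m3s * np.exp(
        -0.5 * (tp / config.freshet_width_days) ** 2
    )
    return pd.DataFrame(
        {"date": dates, "water_temp_C": temp, "discharge_m3s": discharge}
    )


def _two_phase_mortality(
    exit_date: dt.date,
    hazard: float,
    config: SyntheticConfig,
    study_end: dt.date,
    rng: np.random.Generator,
) -> tuple[dt.date, bool]:
    """Contingent hazard for ``vulnerable_days`` post-exit, then baseline."""
    if study_end < exit_date:
        raise ValidationError("study_end precedes exit_date: invalid window")
    t1 = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
    if t1 <= config.vulnerable_days:
        t = t1
    elif config.baseline_hazard_per_day > 0:
        t = config.vulnerable_days + rng.exponential(
            1.0 / config.baseline_hazard_per_day
        )
    else:
        return study_end, False
    death = exit_date + dt.timedelta(days=int(np.ceil(t)))
    if death <= study_end:
        return death, True
    return study_end, False


def _entry_date(year: int, params: ContingentParams, rng) -> dt.date:
    base = dt.date(year, *params.entry_month_day)
    return base + dt.timedelta(days=int(round(rng.normal(0.0, params.entry_sd_days))))


def _shelf_detections(tag_id, start, end, receivers, prob, rng, utc_offset_hours=-5.0):
    shelf = receivers[receivers["river_km"].isna()]
    rows = []
    n = (end - start).days + 1
    if n <= 0 or shelf.empty:
        return pd.DataFrame(columns=["timestamp", "tag_id", "receiver_id"])
    ids = shelf["receiver_id"].to_numpy()
    for i in range(n):
        if rng.random() >= prob:
            continue
        date = start + dt.timedelta(days=i)
        ts = (
            pd.Timestamp(date, tz="UTC")
            + pd.Timedelta(hours=float(rng.uniform(0, 24)))
            - pd.Timedelta(hours=utc_offset_hours)
        )
        rows.append(
            {"timestamp": ts, "tag_id": tag_id, "receiver_id": str(rng.choice(ids))}
        )
    return pd.DataFrame(rows, columns=["timestamp", "tag_id", "receiver_id"])


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Full two-year synthetic study: detections, metadata, truth labels.

    Year-1 contingents follow the configured cohort sizes; each returning
    fish keeps its contingent in year 2 with probability
    ``repeat_fidelity_prob``. Death times are exponential with the fish's
    contingent-specific post-run hazard, drawn after each year's run exit
    (the year-1 draw is truncated at the year-2 entry; survivors re-draw
    after the year-2 exit), and fish at large emit sparse shelf-array
    detections until death or study end.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    receivers = default_receivers(config)
    y1, y2 = config.years
    study_end = dt.date(y2, 12, 31)
    env = pd.concat(
        [
            # year-1 series runs through February so the two years abut
            simulate_environment(y1, config, end=dt.date(y2, 3, 1) - dt.timedelta(days=1)),
            simulate_environment(y2, config),
        ],
        ignore_index=True,
    )

    det_frames, fish_rows, truth_rows = [], [], []
    assignments = [(LOWER, i) for i in range(config.n_fish_lower)] + [
        (UPPER, i) for i in range(config.n_fish_upper)
    ]
    for contingent, i in assignments:
        tag = f"{contingent[0].upper()}{i:03d}"
        p1 = config.params(contingent)
        sex = "F" if rng.random() < 0.6 else "M"
        length = float(np.round(rng.normal(88.0 if contingent == UPPER else 83.0, 6.0), 1))
        weight = float(np.round(max(rng.normal(8.0, 2.0), 2.5), 1))
        tagging = dt.date(y1 - 1, 5, 10) if contingent == UPPER else dt.date(y1 - 1, 4, 22)
        fish_rows.append(
            {
                "tag_id": tag,
                "tagging_date": tagging.isoformat(),
                "tagging_reach": contingent,
                "length_cm": length,
                "weight_kg": weight,
                "sex": sex,
            }
        )

        # --- year 1 run
        entry1 = _entry_date(y1, p1, rng)
        dates1, path1 = _simulate_year_track(config, p1, entry1, rng)
        det_frames.append(
            emit_detections(
                dates1, path1, receivers, config.daily_detection_prob, rng, tag,
                max_gap_km=config.receiver_spacing_km,
            )
        )
        exit1 = dates1[-1]

        # --- mortality between runs (hazard of the year-1 contingent)
        contingent2 = contingent
        if rng.random() >= config.repeat_fidelity_prob:
            contingent2 = UPPER if contingent == LOWER else LOWER
        p2 = config.params(contingent2)
        entry2 = _entry_date(y2, p2, rng)
        last1, event1 = _two_phase_mortality(
            exit1, p1.post_run_hazard_per_day, config, study_end, rng
        )
        death_date: dt.date | None = None
        if event1 and last1 < entry2:
            death_date = last1
            det_frames.append(
                _shelf_detections(
                    tag, exit1 + dt.timedelta(days=1), last1, receivers,
                    config.shelf_detection_prob, rng,
                )
            )
            truth_rows.append(
                _truth_row(tag, contingent, None, entry1, exit1, None, None, death_date)
            )
            continue

        # survived to year 2: at large until year-2 entry, then runs again
        det_frames.append(
            _shelf_detections(
                tag, exit1 + dt.timedelta(days=1),
                entry2 - dt.timedelta(days=5), receivers,
                config.shelf_detection_prob, rng,
            )
        )
        dates2, path2 = _simulate_year_track(config, p2, entry2, rng)
        det_frames.append(
            emit_detections(
                dates2, path2, receivers, config.daily_detection_prob, rng, tag,
                max_gap_km=config.receiver_spacing_km,
            )
        )
        exit2 = dates2[-1]
        last2, event2 = _two_phase_mortality(
            exit2, p2.post_run_hazard_per_day, config, study_end, rng
        )
        if event2:
            death_date = last2
        det_frames.append(
            _shelf_detections(
                tag, exit2 + dt.timedelta(days=1), last2, receivers,
                config.shelf_detection_prob, rng,
            )
        )
        truth_rows.append(
            _truth_row(tag, contingent, contingent2, entry1, exit1, entry2, exit2, death_date)
        )

    detections = pd.concat(
        [f for f in det_frames if len(f)], ignore_index=True
    )
    detections = detections.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
    return SyntheticDataset(
        detections=detections,
        receivers=receivers,
        fish=pd.DataFrame(fish_rows),
        environment=env,
        truth=pd.DataFrame(truth_rows),
    )


def _simulate_year_track(config, params, entry_date, rng):
    target = float(rng.uniform(*params.target_km_range))
    speed = float(np.clip(rng.normal(config.travel_speed_kmd_mean, config.travel_speed_kmd_sd), 5.0, None))
    residence = float(np.clip(rng.normal(config.residence_days_mean, config.residence_days_sd), 3.0, None))
    n_exc = int(rng.poisson(config.n_excursions_mean))
    return simulate_track(
        entry_date,
        target,
        params.retreat_floor_km,
        speed,
        residence,
        n_exc,
        rng,
        jitter_km_sd=config.jitter_km_sd,
        start_km=config.start_km,
        river_max_km=config.river_max_km,
    )


def _truth_row(tag, c1, c2, entry1, exit1, entry2, exit2, death_date):
    return {
        "tag_id": tag,
        "contingent_y1": c1,
        "contingent_y2": c2 if c2 else "",
        "entry_y1": entry1.isoformat(),
        "exit_y1": exit1.isoformat(),
        "entry_y2": entry2.isoformat() if entry2 else "",
        "exit_y2": exit2.isoformat() if exit2 else "",
        "death_date": death_date.isoformat() if death_date else "",
        "censored": death_date is None,
    }
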
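"""Shared pipeline configuration.

All river positions are kilometres upstream of the river mouth ("river km").
Two anchors matter throughout: the entry/exit threshold (default km 43)
which defines when a fish is "in the run", and the padding
anchor (default km 35, the NJ-NY border) used to extend phenology series to a
common length so that runs far apart in time are penalised when aligned.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

#: Step patterns accepted by the DTW distance.
STEP_PATTERNS = ("symmetric2", "symmetric1")


@dataclass
class PipelineConfig:
    """End-to-end analysis settings.

    Parameters
    ----------
    entry_exit_threshold_km:
        River km a fish must reach for a day to count as part of a spawning
        run; the first/last day at or above it define entry and exit.
    pad_km:
        Constant river km used to pad all series to a common date axis.
    imputation_window_days:
        Half-width (calendar days, each side) of the exponential-weighted
        moving-average gap imputer.
    n_clusters:
        Number of contingents sought by k-medoids (k).
    dtw_step_pattern:
        "symmetric2" (diagonal steps cost twice the local distance) or
        "symmetric1".
    censor_window_days:
        Fish whose last detection falls within this many days of the analysis
        end are right-censored rather than treated as deaths.
    analysis_start, analysis_end:
        Mortality analysis period (inclusive).
    utc_offset_hours:
        Offset applied to UTC timestamps before daily binning (local civil
        date); default -5 (US Eastern standard time).
    random_seed:
        Seed for any stochastic option (PAM random restarts); the default
        pipeline path is deterministic.
    """

    entry_exit_threshold_km: float = 43.0
    pad_km: float = 35.0
    imputation_window_days: int = 4
    n_clusters: int = 2
    dtw_step_pattern: str = "symmetric2"
    censor_window_days: int = 30
    analysis_start: dt.date | None = None
    analysis_end: dt.date | None = None
    utc_offset_hours: float = -5.0
    random_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.pad_km < self.entry_exit_threshold_km:
            raise ValidationError(
                f"pad_km ({self.pad_km}) must lie below the entry/exit "
                f"threshold ({self.entry_exit_threshold_km})"
            )
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.imputation_window_days < 1:
            raise ValidationError("imputation_window_days must be >= 1")
        if self.censor_window_days < 0:
            raise ValidationError("censor_window_days must be >= 0")
        if self.dtw_step_pattern not in STEP_PATTERNS:
            raise ValidationError(
                f"dtw_step_pattern must be one of {STEP_PATTERNS}"
            )
        if (
            self.analysis_start is not None
            and self.analysis_end is not None
            and self.analysis_end < self.analysis_start
        ):
            raise ValidationError("analysis_end precedes analysis_start")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("analysis_start", "analysis_end"):
            if isinstance(raw.get(key), str):
                raw[key] = dt.date.fromisoformat(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {}
        for key, value in self.__dict__.items():
            raw[key] = value.isoformat() if isinstance(value, dt.date) else value
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
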
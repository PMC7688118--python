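"""Readers and writers for the four CSV input formats and all output tables.

Inputs (comma-separated, UTF-8, header row required):

``detections.csv``   timestamp (ISO-8601, UTC), tag_id, receiver_id
``receivers.csv``    receiver_id, river_km [, region] — river_km may be blank
                     for shelf-array stations identified only by region code
``fish.csv``         tag_id, tagging_date, tagging_reach, length_cm,
                     weight_kg, sex
``environment.csv``  date, water_temp_C, discharge_m3s — daily and gap-free

All collections are returned as pandas DataFrames with validated dtypes.
Output tables are written with a one-line schema-version header comment so
files are self-describing; :func:`read_table` round-trips them.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .errors import FormatError, RowError, ValidationError

log = logging.getLogger("runcontingent")

SCHEMA_VERSION = 1

DETECTION_COLUMNS = ["timestamp", "tag_id", "receiver_id"]
RECEIVER_COLUMNS = ["receiver_id", "river_km"]
FISH_COLUMNS = ["tag_id", "tagging_date", "tagging_reach", "length_cm", "weight_kg", "sex"]
ENV_COLUMNS = ["date", "water_temp_C", "discharge_m3s"]

_SEXES = {"F", "M", "unknown"}
_REACHES = {"lower", "upper"}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_detections(path) -> pd.DataFrame:
    """Read a detection log, sorted by (tag_id, timestamp).

    Raises :class:`RowError` listing 1-based file line numbers for rows whose
    timestamp does not parse, and :class:`FormatError` for missing columns.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    _require_columns(df, DETECTION_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    bad |= df["timestamp"].isna()
    if bad.any():
        # +2: one for the header, one for 0- vs 1-based indexing
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise RowError(
            f"{path}: unparseable timestamp on line(s) {lines}", lines=lines
        )
    empty = df["tag_id"].isna() | df["receiver_id"].isna()
    if empty.any():
        lines = [int(i) + 2 for i in np.flatnonzero(empty.to_numpy())]
        raise RowError(f"{path}: empty tag_id/receiver_id on line(s) {lines}", lines=lines)
    out = pd.DataFrame(
        {"timestamp": ts, "tag_id": df["tag_id"], "receiver_id": df["receiver_id"]}
    )
    return out.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)


def read_receivers(path) -> pd.DataFrame:
    """Read receiver metadata; duplicate receiver_id is a validation error."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, RECEIVER_COLUMNS, path)
    if "region" not in df.columns:
        df["region"] = pd.NA
    dupes = df["receiver_id"][df["receiver_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate receiver_id(s) {sorted(map(str, dupes))}")
    km = pd.to_numeric(df["river_km"], errors="coerce")
    riverine = km.notna()
    if (km[riverine] < 0).any() or np.isinf(km[riverine]).any():
        raise ValidationError(f"{path}: river_km must be finite and >= 0")
    no_place = ~riverine & df["region"].isna()
    if no_place.any():
        raise ValidationError(
            f"{path}: receivers without river_km must carry a region code: "
            f"{df.loc[no_place, 'receiver_id'].tolist()}"
        )
    return pd.DataFrame(
        {
            "receiver_id": df["receiver_id"].astype(str),
            "river_km": km,
            "region": df["region"].astype("string"),
        }
    )


def read_fish(path) -> pd.DataFrame:
    """Read tagged-fish metadata.

    Unrecognised sex codes are coerced to "unknown" with a logged warning;
    non-positive lengths or weights and unknown tagging reaches are errors.
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, FISH_COLUMNS, path)
    df = df.copy()
    df["tag_id"] = df["tag_id"].astype(str)
    df["tagging_date"] = pd.to_datetime(df["tagging_date"]).dt.date
    bad_reach = ~df["tagging_reach"].isin(_REACHES)
    if bad_reach.any():
        raise ValidationError(
            f"{path}: tagging_reach must be one of {sorted(_REACHES)}; "
            f"got {df.loc[bad_reach, 'tagging_reach'].unique().tolist()}"
        )
    odd_sex = ~df["sex"].isin(_SEXES)
    if odd_sex.any():
        log.warning(
            "%s: coercing unrecognised sex code(s) %s to 'unknown'",
            path,
            df.loc[odd_sex, "sex"].unique().tolist(),
        )
        df.loc[odd_sex, "sex"] = "unknown"
    for col in ("length_cm", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if ((vals <= 0) & vals.notna()).any():
            raise ValidationError(f"{path}: {col} must be positive when present")
        df[col] = vals
    return df[FISH_COLUMNS].reset_index(drop=True)


def read_environment(path) -> pd.DataFrame:
    """Read the daily environmental series, checked gap-free and increasing."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ENV_COLUMNS, path)
    dates = pd.to_datetime(df["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValidationError(f"{path}: dates must be strictly increasing")
    full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    missing = full.difference(pd.DatetimeIndex(dates))
    if len(missing):
        raise ValidationError(
            f"{path}: environment series has a gap; first missing date "
            f"{missing[0].date().isoformat()}"
        )
    return pd.DataFrame(
        {
            "date": dates.dt.date,
            "water_temp_C": pd.to_numeric(df["water_temp_C"]),
            "discharge_m3s": pd.to_numeric(df["discharge_m3s"]),
        }
    )


# ---------------------------------------------------------------------------
# Output tables


def write_table(df: pd.DataFrame, path, name: str) -> None:
    """Write an output table with a schema-version header comment."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# runcontingent-table {name} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%d")


_DATEISH = ("date", "timestamp")


def read_table(path) -> pd.DataFrame:
    """Round-trip reader for tables produced by :func:`write_table`.

    Columns named ``date``/``timestamp`` or ending in ``_date`` are parsed
    back to dates.
    """
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        if col in _DATEISH or col.endswith("_date"):
            parsed = pd.to_datetime(df[col], errors="coerce")
            if col == "timestamp":
                df[col] = parsed
            else:
                df[col] = parsed.dt.date
    return df


def local_date(timestamps: pd.Series, utc_offset_hours: float) -> pd.Series:
    """Local civil date for UTC timestamps under a fixed UTC offset."""
    shifted = timestamps + pd.Timedelta(hours=utc_offset_hours)
    return shifted.dt.date
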
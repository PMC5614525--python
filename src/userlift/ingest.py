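"""Readers, inclusion filters, and per-user per-day labels.

Raw inputs are two delimited tables — GPS location logs and timestamped
Likert self-reports — plus a YAML registry of scale definitions.  A user
enters the analysis only with at least ``min_days`` days that each carry a
label and at least ``min_gps_obs`` GPS observations (defaults 30 and 35); a
day's label is the arithmetic mean of that day's reports, binarized at the
scale's threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, EmptyCohortError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

LOCATION_COLUMNS = ["user_id", "timestamp", "latitude", "longitude"]
RESPONSE_COLUMNS = ["user_id", "timestamp", "scale_id", "value"]

#: inclusion thresholds: days with a label and enough GPS coverage
DEFAULT_MIN_DAYS = 30
DEFAULT_MIN_GPS_OBS = 35


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered integer self-report scale and its binarization rule.

    ``binarize_threshold`` splits daily mean levels into two classes; when
    ``positive_is_high`` levels at or above the threshold are the positive
    (stressed / happy) class, otherwise at or below.  The threshold itself
    belongs to the positive class.
    """

    scale_id: str
    min: int
    max: int
    binarize_threshold: float
    positive_is_high: bool = True

    def __post_init__(self):
        if not self.min < self.max:
            raise ConfigError(f"scale {self.scale_id}: min must be < max")
        if not (self.min < self.binarize_threshold <= self.max):
            raise ConfigError(
                f"scale {self.scale_id}: binarize_threshold must lie in (min, max]"
            )

    def binarize(self, level) -> np.ndarray:
        level = np.asarray(level, dtype=float)
        if self.positive_is_high:
            return level >= self.binarize_threshold
        return level <= self.binarize_threshold


def load_scales(path) -> dict[str, ScaleDefinition]:
    """Read a scales.yaml registry: ``{scales: [{scale_id, min, max, ...}]}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scales" not in doc:
        raise SchemaError(f"{path}: expected a top-level 'scales' list")
    out = {}
    for entry in doc["scales"]:
        sd = ScaleDefinition(
            scale_id=str(entry["scale_id"]),
            min=int(entry["min"]),
            max=int(entry["max"]),
            binarize_threshold=float(entry["binarize_threshold"]),
            positive_is_high=bool(entry.get("positive_is_high", True)),
        )
        out[sd.scale_id] = sd
    return out


def _read_table(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in list(required) + list(optional)]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}; schema is versioned "
                          f"and rejects unrecognized dialects")
    return df


def read_locations(path) -> pd.DataFrame:
    """Read locations.csv: user_id,timestamp,latitude,longitude[,is_moving].

    Rows are sorted by (user, timestamp). Rows with unparseable fields are
    dropped and counted (``df.attrs['n_malformed']``); coordinates outside
    the valid lat/lon ranges raise.
    """
    df = _read_table(path, LOCATION_COLUMNS, optional=["is_moving"])
    n_raw = len(df)
    for col in ("timestamp", "latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["user_id", "timestamp", "latitude", "longitude"])
    n_malformed = n_raw - len(df)
    if n_malformed:
        logger.warning("%s: dropped %d malformed location row(s)", path, n_malformed)
    bad_lat = ~df["latitude"].between(-90, 90)
    bad_lon = ~df["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        row = int(df.index[bad_lat | bad_lon][0])
        raise ValidationError(f"{path}: coordinate out of range at row {row}")
    df["timestamp"] = df["timestamp"].astype(np.int64)
    if "is_moving" in df.columns:
        df["is_moving"] = pd.to_numeric(df["is_moving"], errors="coerce")
    df = df.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_malformed"] = int(n_malformed)
    return df


def read_responses(path, scale: ScaleDefinition) -> pd.DataFrame:
    """Read responses.csv: user_id,timestamp,scale_id,value, validated against ``scale``."""
    df = _read_table(path, RESPONSE_COLUMNS)
    n_raw = len(df)
    df["timestamp"] = pd.to_numeric(df["timestamp"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df = df.dropna(subset=["user_id", "timestamp", "value"])
    n_malformed = n_raw - len(df)
    if n_malformed:
        logger.warning("%s: dropped %d malformed response row(s)", path, n_malformed)
    df = df[df["scale_id"] == scale.scale_id]
    out_of_range = ~df["value"].between(scale.min, scale.max)
    if out_of_range.any():
        row = int(df.index[out_of_range][0])
        raise ValidationError(
            f"{path}: value outside [{scale.min}, {scale.max}] at row {row}"
        )
    df["timestamp"] = df["timestamp"].astype(np.int64)
    df["value"] = df["value"].astype(int)
    df = df.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_malformed"] = int(n_malformed)
    return df


def _local_date(timestamp: pd.Series, tz: str) -> pd.Series:
    ts = pd.to_datetime(timestamp, unit="s", utc=True)
    if tz != "UTC":
        ts = ts.dt.tz_convert(tz)
    return ts.dt.normalize().dt.tz_localize(None)


def build_day_records(responses: pd.DataFrame, locations: pd.DataFrame,
                      scale: ScaleDefinition, tz: str = "UTC") -> pd.DataFrame:
    """One row per (user, local day) with a label.

    Columns: user_id, date, label_level (mean of the day's reports),
    label_binary, n_responses, n_gps_obs. Days with no response produce no
    row; days with no GPS get n_gps_obs = 0. Day boundaries are local civil
    midnight in the study timezone ``tz``.
    """
    resp = responses.copy()
    resp["date"] = _local_date(resp["timestamp"], tz)
    day = (resp.groupby(["user_id", "date"], sort=True)["value"]
           .agg(label_level="mean", n_responses="size").reset_index())
    day["label_binary"] = scale.binarize(day["label_level"].to_numpy())

    if len(locations):
        loc = locations[["user_id", "timestamp"]].copy()
        loc["date"] = _local_date(loc["timestamp"], tz)
        gps = loc.groupby(["user_id", "date"], sort=True).size().rename("n_gps_obs").reset_index()
        day = day.merge(gps, on=["user_id", "date"], how="left")
        day["n_gps_obs"] = day["n_gps_obs"].fillna(0).astype(int)
    else:
        day["n_gps_obs"] = 0
    return day.sort_values(["user_id", "date"], kind="mergesort").reset_index(drop=True)


def filter_participants(day_records: pd.DataFrame,
                        min_days: int = DEFAULT_MIN_DAYS,
                        min_gps_obs: int = DEFAULT_MIN_GPS_OBS) -> tuple[pd.DataFrame, list[str]]:
    """Apply the inclusion filter; returns (qualifying day rows, retained users).

    A day qualifies if it has a label and >= ``min_gps_obs`` GPS observations;
    a user is retained with >= ``min_days`` qualifying days. Only qualifying
    days of retained users are passed downstream.
    """
    ok = day_records[day_records["n_gps_obs"] >= min_gps_obs]
    counts = ok.groupby("user_id").size()
    retained = sorted(counts[counts >= min_days].index)
    if not retained:
        raise EmptyCohortError(
            f"no user has >= {min_days} days with a label and >= {min_gps_obs} GPS observations"
        )
    out = ok[ok["user_id"].isin(retained)].reset_index(drop=True)
    return out, retained
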
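"""Synthetic smartphone-sensing cohorts with known ground truth.

Emulates the structure that the user-lift evaluation assumes: each user dwells
at a small set of recurrent locations (home, work, extras) on a daily schedule
(home overnight, work midday), GPS is sampled sparsely and noisily, and daily
Likert self-reports have large between-user but small within-user variance.

The latent daily state for user u on day d is

    level_ud = clamp(round(mu_u + beta * s_ud + eps_ud))

where ``mu_u ~ Normal(scale midpoint, between_user_sd)`` (clamped to the
scale), ``eps_ud ~ Normal(0, within_user_sd)``, and ``s_ud`` is the within-user
z-score of the fraction of day d spent away from home — one of the mobility
features the downstream models can recover, so ``beta > 0`` plants a learnable
signal while ``beta = 0`` is an exact null (state independent of mobility).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .geometry import inverse_project

# 2024-01-01T00:00:00Z; all synthetic timestamps count forward from here
_EPOCH_START = 1_704_067_200
_DAY_S = 86_400

# minutes of simulated travel after each dwell change
_TRAVEL_S = 600.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated cohort.

    Defaults describe a mid-sized campus study: 20 users, 40 labeled days,
    a 5-point stress scale answered twice a day, and 40 GPS fixes per day
    over 4 recurrent locations.
    """

    n_users: int = 20
    n_days: int = 40
    scale_min: int = 1
    scale_max: int = 5
    responses_per_day: int = 2
    gps_obs_per_day: int = 40
    n_locations_per_user: int = 4
    effect_size: float = 0.0
    within_user_sd: float = 0.7
    between_user_sd: float = 1.0
    report_noise_sd: float = 0.5
    gps_noise_sd: float = 20.0
    seed: int = 0
    origin_lat: float = 40.0
    origin_lon: float = -74.0
    scale_id: str = "synthetic_stress"

    def validate(self) -> None:
        checks = [
            (self.n_users >= 2, "n_users must be >= 2"),
            (self.n_days >= 30, "n_days must be >= 30"),
            (self.gps_obs_per_day >= 35, "gps_obs_per_day must be >= 35"),
            (self.responses_per_day >= 1, "responses_per_day must be >= 1"),
            (self.n_locations_per_user >= 2, "n_locations_per_user must be >= 2"),
            (self.scale_min < self.scale_max, "scale_min must be < scale_max"),
            (self.within_user_sd >= 0, "within_user_sd must be >= 0"),
            (self.between_user_sd >= 0, "between_user_sd must be >= 0"),
            (self.report_noise_sd >= 0, "report_noise_sd must be >= 0"),
            (self.gps_noise_sd >= 0, "gps_noise_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @property
    def scale_midpoint(self) -> float:
        return (self.scale_min + self.scale_max) / 2.0


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    effect_size: float
    seed: int
    mu: dict[str, float] = field(default_factory=dict)
    home_xy: dict[str, tuple[float, float]] = field(default_factory=dict)
    work_xy: dict[str, tuple[float, float]] = field(default_factory=dict)
    s: dict[str, list[float]] = field(default_factory=dict)  # per-day mobility driver
    frac_away: dict[str, list[float]] = field(default_factory=dict)
    levels: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)


def _user_layout(rng: np.random.Generator, n_locations: int) -> np.ndarray:
    """Planar coordinates (m) of a user's recurrent locations; row 0 = home, 1 = work."""
    home = rng.normal(0.0, 2000.0, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(2000.0, 6000.0)
    work = home + dist * np.array([np.cos(theta), np.sin(theta)])
    extras = home + rng.normal(0.0, 3000.0, size=(n_locations - 2, 2))
    return np.vstack([home, work, extras])


def _daily_schedule(rng: np.random.Generator, n_locations: int) -> list[tuple[float, float, int]]:
    """Dwell segments (start_s, end_s, location index) covering one day.

    Hour-level: overnight (23:00-06:00) predominantly home, midday
    (11:00-16:00) predominantly work, other hours sticky-random over all
    locations; segment boundaries get a few minutes of jitter.
    """
    hours = np.empty(24, dtype=int)
    prev = 0
    for h in range(24):
        if h >= 23 or h < 6:
            loc = 0 if rng.random() < 0.92 else int(rng.integers(1, n_locations))
        elif 11 <= h < 16:
            loc = 1 if rng.random() < 0.85 else int(rng.integers(0, n_locations))
        else:
            loc = prev if rng.random() < 0.6 else int(rng.integers(0, n_locations))
        hours[h] = loc
        prev = loc
    segments: list[tuple[float, float, int]] = []
    start = 0.0
    for h in range(1, 24):
        if hours[h] != hours[h - 1]:
            end = h * 3600.0 + rng.uniform(-600.0, 600.0)
            segments.append((start, end, int(hours[h - 1])))
            start = end
    segments.append((start, float(_DAY_S), int(hours[23])))
    return segments


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a cohort; returns (locations, responses, truth).

    ``locations`` has columns user_id,timestamp,latitude,longitude,is_moving;
    ``responses`` has user_id,timestamp,scale_id,value. Deterministic for a
    fixed config (the seed lives inside the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    origin = (config.origin_lat, config.origin_lon)
    truth = SimTruth(effect_size=config.effect_size, seed=config.seed)

    loc_rows: list[pd.DataFrame] = []
    resp_rows: list[pd.DataFrame] = []

    for u in range(config.n_users):
        user_id = f"u{u:03d}"
        layout = _user_layout(rng, config.n_locations_per_user)
        mu = float(np.clip(rng.normal(config.scale_midpoint, config.between_user_sd),
                           config.scale_min, config.scale_max))
        truth.mu[user_id] = mu
        truth.home_xy[user_id] = tuple(layout[0])
        truth.work_xy[user_id] = tuple(layout[1])

        day_ts: list[np.ndarray] = []
        day_xy: list[np.ndarray] = []
        day_moving: list[np.ndarray] = []
        frac_away = np.empty(config.n_days)

        for d in range(config.n_days):
            day_start = _EPOCH_START + d * _DAY_S
            segments = _daily_schedule(rng, config.n_locations_per_user)
            home_s = sum(e - s for s, e, loc in segments if loc == 0)
            # travel windows after a change count as time away from home
            travel_s = _TRAVEL_S * max(len(segments) - 1, 0)
            frac_away[d] = 1.0 - max(home_s - travel_s, 0.0) / _DAY_S

            t = np.sort(rng.uniform(0.0, _DAY_S, size=config.gps_obs_per_day))
            xy = np.empty((t.size, 2))
            moving = np.zeros(t.size, dtype=int)
            for i, ti in enumerate(t):
                seg_idx = 0
                for j, (s, e, _) in enumerate(segments):
                    if s <= ti < e:
                        seg_idx = j
                        break
                s, e, loc = segments[seg_idx]
                if seg_idx > 0 and ti - s < _TRAVEL_S:
                    prev_loc = segments[seg_idx - 1][2]
                    if prev_loc != loc:
                        w = (ti - s) / _TRAVEL_S
                        xy[i] = (1 - w) * layout[prev_loc] + w * layout[loc]
                        moving[i] = 1
                        continue
                xy[i] = layout[loc]
            xy = xy + rng.normal(0.0, config.gps_noise_sd, size=xy.shape)
            day_ts.append(day_start + t)
            day_xy.append(xy)
            day_moving.append(moving)

        # standardized mobility driver: within-user z-score of fraction away
        sd = frac_away.std()
        s_ud = (frac_away - frac_away.mean()) / sd if sd > 0 else np.zeros_like(frac_away)
        eps = rng.normal(0.0, config.within_user_sd, size=config.n_days)
        levels = np.clip(
            np.round(mu + config.effect_size * s_ud + eps),
            config.scale_min, config.scale_max,
        ).astype(int)
        truth.s[user_id] = [float(v) for v in s_ud]
        truth.frac_away[user_id] = [float(v) for v in frac_away]
        truth.levels[user_id] = [int(v) for v in levels]

        ts_all = np.concatenate(day_ts)
        xy_all = np.vstack(day_xy)
        lat, lon = inverse_project(xy_all[:, 0], xy_all[:, 1], origin)
        loc_rows.append(pd.DataFrame({
            "user_id": user_id,
            "timestamp": ts_all.astype(np.int64),
            "latitude": lat,
            "longitude": lon,
            "is_moving": np.concatenate(day_moving),
        }))

        rt = np.sort(rng.uniform(0.0, _DAY_S, size=(config.n_days, config.responses_per_day)), axis=1)
        noise = np.round(rng.normal(0.0, config.report_noise_sd,
                                    size=(config.n_days, config.responses_per_day)))
        values = np.clip(levels[:, None] + noise, config.scale_min, config.scale_max).astype(int)
        day_starts = _EPOCH_START + np.arange(config.n_days)[:, None] * _DAY_S
        resp_rows.append(pd.DataFrame({
            "user_id": user_id,
            "timestamp": (day_starts + rt).ravel().astype(np.int64),
            "scale_id": config.scale_id,
            "value": values.ravel(),
        }))

    locations = pd.concat(loc_rows, ignore_index=True)
    responses = pd.concat(resp_rows, ignore_index=True)
    locations = locations.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    responses = responses.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return locations, responses, truth


def scale_definition_dict(config: CohortConfig) -> dict:
    """The scales.yaml entry matching a synthetic cohort (threshold = midpoint)."""
    return {
        "scale_id": config.scale_id,
        "min": config.scale_min,
        "max": config.scale_max,
        "binarize_threshold": config.scale_midpoint,
        "positive_is_high": True,
    }


def write_fixture(locations: pd.DataFrame, responses: pd.DataFrame, truth: SimTruth,
                  directory, config: CohortConfig | None = None) -> dict[str, Path]:
    """Write a cohort in the ingest CSV schemas plus a ground-truth sidecar.

    Returns the written paths. Round-trips losslessly through
    :func:`userlift.ingest.read_locations` / ``read_responses``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "locations": directory / "locations.csv",
        "responses": directory / "responses.csv",
        "truth": directory / "truth.json",
    }
    # default float formatting is the shortest exact repr, so the CSV round-trips
    locations.to_csv(paths["locations"], index=False)
    responses.to_csv(paths["responses"], index=False)
    paths["truth"].write_text(truth.to_json())
    if config is not None:
        paths["scales"] = directory / "scales.yaml"
        with open(paths["scales"], "w") as fh:
            yaml.safe_dump({"scales": [scale_definition_dict(config)]}, fh)
    return paths
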
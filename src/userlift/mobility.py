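"""Daily location and mobility features from raw GPS streams.

Two per-user clusterings precede featurization:

* the *full clustering*: a Gaussian mixture model over every location sample,
  with the number of components chosen (up to 20) by minimum BIC — its
  components are the user's frequented places, among which the *home* and
  *work* components are the ones holding the most samples during 23:00-06:00
  and 11:00-16:00 local time respectively;
* the *stationary clustering*: K-means over stationary samples only
  (movement speed below ~1 km/h, or a provider-supplied flag), with K chosen
  by BIC under a spherical-Gaussian reading of the K-means solution — the
  *night cluster* is the one holding the most samples between midnight and
  06:00.

From these, each qualifying day yields 14 features (the AIC/BIC pair shares
one slot, so 15 numbers): movement fractions and displacement statistics,
log location variance, circadian movement, location entropy, the minimum
enclosing circle radius, dwell fractions at home/work/night, the day's
log-likelihood / AIC / BIC under the user's mixture, and counts of clusters
visited.  Observations are used as-is — they are never interpolated to a
regular time grid — so dwell "time" is sample counts throughout.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .geometry import minimum_enclosing_circle, project_to_plane

logger = logging.getLogger(__name__)

#: column order of the daily feature matrix
FEATURE_COLUMNS = [
    "frac_not_stationary",
    "mean_displacement",
    "sd_displacement",
    "log_location_variance",
    "circadian_movement",
    "location_entropy",
    "mec_radius",
    "frac_home",
    "frac_work",
    "frac_night",
    "gmm_day_loglik",
    "gmm_day_aic",
    "gmm_day_bic",
    "n_gmm_clusters_visited",
    "n_stationary_clusters_visited",
]

MAX_CLUSTERS = 20
STATIONARY_SPEED_KMH = 1.0
#: displacement pairs with a larger time gap (s) are skipped for f2/f3
DISPLACEMENT_GAP_S = 600.0
#: variance floor (m^2) inside the log for zero-variance days
LOG_VAR_EPS = 1e-12

_HOME_HOURS = frozenset({23, 0, 1, 2, 3, 4, 5})
_WORK_HOURS = frozenset({11, 12, 13, 14, 15})
_NIGHT_HOURS = frozenset({0, 1, 2, 3, 4, 5})


@dataclass
class ClusterModel:
    """A user's fitted location structure."""

    user_id: str
    origin: tuple[float, float]
    gmm: GaussianMixture
    stationary_centroids: np.ndarray
    home_cluster_id: int | None = None
    work_cluster_id: int | None = None
    night_cluster_id: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def k_full(self) -> int:
        return int(self.gmm.n_components)

    @property
    def k_stationary(self) -> int:
        return int(self.stationary_centroids.shape[0])

    @property
    def n_gmm_parameters(self) -> int:
        """Free parameters of the diagonal-covariance mixture: (K-1) + 2K + 2K."""
        return 5 * self.k_full - 1

    def assign_full(self, xy: np.ndarray) -> np.ndarray:
        """Component of maximum posterior responsibility for each sample."""
        return self.gmm.predict(xy)

    def assign_stationary(self, xy: np.ndarray) -> np.ndarray:
        """Nearest stationary centroid for each sample."""
        d = np.linalg.norm(xy[:, None, :] - self.stationary_centroids[None, :, :], axis=2)
        return d.argmin(axis=1)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "origin": list(self.origin),
            "k_full": self.k_full,
            "weights": self.gmm.weights_.tolist(),
            "means": self.gmm.means_.tolist(),
            "covariances": self.gmm.covariances_.tolist(),
            "stationary_centroids": self.stationary_centroids.tolist(),
            "home_cluster_id": self.home_cluster_id,
            "work_cluster_id": self.work_cluster_id,
            "night_cluster_id": self.night_cluster_id,
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        k = int(d["k_full"])
        gmm = GaussianMixture(n_components=k, covariance_type="diag")
        gmm.weights_ = np.asarray(d["weights"], dtype=float)
        gmm.means_ = np.asarray(d["means"], dtype=float)
        gmm.covariances_ = np.asarray(d["covariances"], dtype=float)
        gmm.precisions_cholesky_ = 1.0 / np.sqrt(gmm.covariances_)
        return cls(
            user_id=d["user_id"],
            origin=tuple(d["origin"]),
            gmm=gmm,
            stationary_centroids=np.asarray(d["stationary_centroids"], dtype=float),
            home_cluster_id=d["home_cluster_id"],
            work_cluster_id=d["work_cluster_id"],
            night_cluster_id=d["night_cluster_id"],
            flags=list(d.get("flags", [])),
        )


def detect_stationary(xy: np.ndarray, timestamps: np.ndarray,
                      speed_threshold_kmh: float = STATIONARY_SPEED_KMH) -> np.ndarray:
    """Per-sample stationary flag from the speed time-derivative.

    Speed at sample i is distance(i-1, i) / dt; a sample is stationary when
    its speed is below the threshold (~1 km/h).  The first sample inherits
    the second's state.  Coincident timestamps with distinct coordinates are
    flagged moving (anomalous teleport).
    """
    n = len(timestamps)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if n == 1:
        return np.ones(1, dtype=bool)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(np.asarray(timestamps, dtype=float))
    thr_ms = speed_threshold_kmh / 3.6
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.inf)
    speed = np.where((dt == 0) & (d == 0), 0.0, speed)
    stationary = np.empty(n, dtype=bool)
    stationary[1:] = speed < thr_ms
    stationary[0] = stationary[1]
    n_anom = int(np.sum((dt == 0) & (d > 0)))
    if n_anom:
        logger.warning("detect_stationary: %d coincident-timestamp anomalies flagged moving", n_anom)
    return stationary


def _bic_ties_to_smaller(bics: list[float]) -> int:
    return int(np.argmin(bics))  # argmin keeps the first (smallest K) on ties


def fit_full_clustering(xy: np.ndarray, max_clusters: int = MAX_CLUSTERS,
                        seed: int = 0, n_init: int = 2) -> GaussianMixture:
    """Fit diagonal-covariance GMMs for K = 1..max and keep the minimum-BIC one.

    With fewer than 20 samples the largest K is capped at floor(n/2).
    Degenerate inputs (all samples coincident) fall back to K = 1 with the
    covariance floored by the EM regularizer.
    """
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    k_max = max(1, min(max_clusters, n if n >= 20 else n // 2))
    if np.allclose(xy, xy[0]):
        k_max = 1
    models, bics = [], []
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(n_components=k, covariance_type="diag",
                              random_state=seed, n_init=n_init, reg_covar=1e-4)
        gmm.fit(xy)
        models.append(gmm)
        bics.append(gmm.bic(xy))
    return models[_bic_ties_to_smaller(bics)]


def _kmeans_bic(xy: np.ndarray, km: KMeans) -> float:
    """BIC of a K-means solution read as a shared-variance spherical mixture."""
    n, d = xy.shape
    k = km.n_clusters
    labels = km.labels_
    sse = float(((xy - km.cluster_centers_[labels]) ** 2).sum())
    sigma2 = max(sse / max(n * d - k * d, 1), 1e-8)
    counts = np.bincount(labels, minlength=k).astype(float)
    with np.errstate(divide="ignore"):
        log_w = np.where(counts > 0, np.log(counts / n), 0.0)
    ll = float((counts * log_w).sum()) - 0.5 * n * d * np.log(2 * np.pi * sigma2) \
        - sse / (2 * sigma2)
    m = (k - 1) + k * d + 1
    return m * np.log(n) - 2 * ll


def fit_stationary_clustering(xy: np.ndarray, max_clusters: int = MAX_CLUSTERS,
                              seed: int = 0) -> np.ndarray:
    """K-means over stationary samples; K chosen by the spherical BIC. Returns centroids."""
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    k_max = max(1, min(max_clusters, n if n >= 20 else max(n // 2, 1)))
    if np.allclose(xy, xy[0]):
        return xy[:1].copy()
    best, best_bic = None, np.inf
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(xy)
        bic = _kmeans_bic(xy, km)
        if bic < best_bic:
            best, best_bic = km, bic
    return best.cluster_centers_


def _local_hours(timestamps: np.ndarray, tz: str) -> np.ndarray:
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps, dtype=np.int64)), unit="s", utc=True)
    if tz != "UTC":
        ts = ts.dt.tz_convert(tz)
    return ts.dt.hour.to_numpy()


def _majority_cluster(assignments: np.ndarray, hours: np.ndarray,
                      window: frozenset[int]) -> int | None:
    in_win = np.isin(hours, list(window))
    if not in_win.any():
        return None
    counts = np.bincount(assignments[in_win])
    return int(counts.argmax())


def identify_semantic_clusters(model: ClusterModel, xy: np.ndarray,
                               timestamps: np.ndarray, tz: str = "UTC") -> ClusterModel:
    """Fill home / work / night cluster identities from dwell (sample counts).

    Home and work are full-GMM components dominating 23:00-06:00 and
    11:00-16:00 local time; the night cluster is the stationary cluster
    dominating 00:00-06:00.  A window with no samples leaves the identity
    undefined (the matching dwell fraction becomes 0, flagged).
    """
    hours = _local_hours(timestamps, tz)
    full = model.assign_full(xy)
    stat = model.assign_stationary(xy)
    model.home_cluster_id = _majority_cluster(full, hours, _HOME_HOURS)
    model.work_cluster_id = _majority_cluster(full, hours, _WORK_HOURS)
    model.night_cluster_id = _majority_cluster(stat, hours, _NIGHT_HOURS)
    for name, val in (("home", model.home_cluster_id), ("work", model.work_cluster_id),
                      ("night", model.night_cluster_id)):
        if val is None:
            model.flags.append(f"no samples in {name} window")
    return model


def _stationary_fractions(assignments: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(assignments, minlength=k) / len(assignments)


def compute_daily_features(xy: np.ndarray, timestamps: np.ndarray,
                           stationary: np.ndarray, model: ClusterModel,
                           user_mean_fractions: np.ndarray,
                           displacement_gap_s: float = DISPLACEMENT_GAP_S) -> dict[str, float]:
    """The 14-feature vector for one user-day (AIC and BIC fill one slot jointly)."""
    n = len(timestamps)
    feats: dict[str, float] = {}
    feats["frac_not_stationary"] = float(1.0 - np.mean(stationary))

    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(np.asarray(timestamps, dtype=float))
    keep = dt <= displacement_gap_s
    if keep.any():
        feats["mean_displacement"] = float(d[keep].mean())
        feats["sd_displacement"] = float(d[keep].std())
    else:
        feats["mean_displacement"] = 0.0
        feats["sd_displacement"] = 0.0

    feats["log_location_variance"] = float(np.log(xy[:, 0].var() + xy[:, 1].var() + LOG_VAR_EPS))

    stat_assign = model.assign_stationary(xy)
    fracs = _stationary_fractions(stat_assign, model.k_stationary)
    feats["circadian_movement"] = float(np.linalg.norm(fracs - user_mean_fractions))
    nz = fracs[fracs > 0]
    feats["location_entropy"] = float(-(nz * np.log(nz)).sum())

    _, radius = minimum_enclosing_circle(xy)
    feats["mec_radius"] = float(radius)

    full_assign = model.assign_full(xy)
    for key, cid, assign in (
        ("frac_home", model.home_cluster_id, full_assign),
        ("frac_work", model.work_cluster_id, full_assign),
        ("frac_night", model.night_cluster_id, stat_assign),
    ):
        feats[key] = float(np.mean(assign == cid)) if cid is not None else 0.0

    ll = float(model.gmm.score(xy) * n)
    m = model.n_gmm_parameters
    feats["gmm_day_loglik"] = ll
    feats["gmm_day_aic"] = 2.0 * m - 2.0 * ll
    feats["gmm_day_bic"] = m * np.log(n) - 2.0 * ll
    feats["n_gmm_clusters_visited"] = float(len(np.unique(full_assign)))
    feats["n_stationary_clusters_visited"] = float(len(np.unique(stat_assign)))
    return feats


def fit_user_cluster_model(user_id: str, locs: pd.DataFrame, *,
                           max_clusters: int = MAX_CLUSTERS,
                           speed_threshold_kmh: float = STATIONARY_SPEED_KMH,
                           tz: str = "UTC", seed: int = 0,
                           n_init: int = 2) -> tuple[ClusterModel, np.ndarray, np.ndarray]:
    """Fit both clusterings and semantic ids for one user.

    Returns (model, planar xy for every sample, stationary flags). ``locs``
    must be that user's location rows sorted by timestamp.
    """
    origin = (float(locs["latitude"].median()), float(locs["longitude"].median()))
    x, y = project_to_plane(locs["latitude"].to_numpy(), locs["longitude"].to_numpy(), origin)
    xy = np.column_stack([x, y])
    ts = locs["timestamp"].to_numpy()

    if "is_moving" in locs.columns and locs["is_moving"].notna().all():
        stationary = ~locs["is_moving"].astype(bool).to_numpy()
    else:
        stationary = detect_stationary(xy, ts, speed_threshold_kmh)

    gmm = fit_full_clustering(xy, max_clusters=max_clusters, seed=seed, n_init=n_init)
    stat_xy = xy[stationary]
    flags = []
    if stat_xy.shape[0] < 2:
        stat_xy = xy  # no stationary fixes at all: cluster everything, flagged
        flags.append("fewer than 2 stationary samples; stationary clustering on all samples")
    centroids = fit_stationary_clustering(stat_xy, max_clusters=max_clusters, seed=seed)
    model = ClusterModel(user_id=user_id, origin=origin, gmm=gmm,
                         stationary_centroids=centroids, flags=flags)
    return identify_semantic_clusters(model, xy, ts, tz), xy, stationary


def extract_features(locations: pd.DataFrame, day_records: pd.DataFrame, *,
                     max_clusters: int = MAX_CLUSTERS,
                     speed_threshold_kmh: float = STATIONARY_SPEED_KMH,
                     tz: str = "UTC",
                     displacement_gap_s: float = DISPLACEMENT_GAP_S,
                     exclude_current_day: bool = False,
                     seed: int = 0,
                     gmm_n_init: int = 2) -> tuple[pd.DataFrame, dict[str, ClusterModel]]:
    """Daily feature matrix for every qualifying (user, day) in ``day_records``.

    The circadian-movement reference distribution is the user's mean
    stationary-cluster fraction vector over all their qualifying days; with
    ``exclude_current_day`` each day is compared against the mean of the
    *other* days instead (no self-reference).  Returns (features table keyed
    by user_id/date, per-user cluster models).
    """
    feature_rows = []
    models: dict[str, ClusterModel] = {}
    loc_by_user = dict(tuple(locations.groupby("user_id", sort=True)))

    for user_id, days in day_records.groupby("user_id", sort=True):
        locs = loc_by_user.get(user_id)
        if locs is None or len(locs) < 2:
            logger.warning("user %s has no usable GPS; skipped", user_id)
            continue
        locs = locs.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        model, xy, stationary = fit_user_cluster_model(
            user_id, locs, max_clusters=max_clusters,
            speed_threshold_kmh=speed_threshold_kmh, tz=tz, seed=seed,
            n_init=gmm_n_init)
        models[user_id] = model

        dates = pd.to_datetime(locs["timestamp"], unit="s", utc=True)
        if tz != "UTC":
            dates = dates.dt.tz_convert(tz)
        dates = dates.dt.normalize().dt.tz_localize(None)
        wanted = set(days["date"])
        day_idx = {d: np.flatnonzero((dates == d).to_numpy()) for d in wanted}

        # per-day stationary-cluster fraction vectors, for the circadian reference
        day_fracs = {}
        for d, idx in day_idx.items():
            if len(idx) >= 2:
                day_fracs[d] = _stationary_fractions(
                    model.assign_stationary(xy[idx]), model.k_stationary)
        if not day_fracs:
            continue
        all_fracs = np.vstack(list(day_fracs.values()))
        frac_dates = list(day_fracs.keys())
        mean_fracs = all_fracs.mean(axis=0)

        for _, row in days.iterrows():
            d = row["date"]
            idx = day_idx.get(d, np.empty(0, dtype=int))
            if len(idx) < 2 or d not in day_fracs:
                logger.warning("user %s day %s has <2 usable samples; feature row dropped",
                               user_id, d)
                continue
            if exclude_current_day and len(frac_dates) > 1:
                mask = np.array([fd != d for fd in frac_dates])
                ref = all_fracs[mask].mean(axis=0)
            else:
                ref = mean_fracs
            feats = compute_daily_features(
                xy[idx], locs["timestamp"].to_numpy()[idx], stationary[idx],
                model, ref, displacement_gap_s=displacement_gap_s)
            feature_rows.append({"user_id": user_id, "date": d,
                                 "n_gps_obs": int(row["n_gps_obs"]), **feats})

    features = pd.DataFrame(feature_rows, columns=["user_id", "date", "n_gps_obs"]
                            + FEATURE_COLUMNS)
    return features, models


def write_cluster_models(models: dict[str, ClusterModel], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({u: m.to_dict() for u, m in models.items()}, indent=1))
    return path


def read_cluster_models(path) -> dict[str, ClusterModel]:
    doc = json.loads(Path(path).read_text())
    return {u: ClusterModel.from_dict(d) for u, d in doc.items()}
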
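import numpy as np
import pandas as pd
import pytest

from userlift import mobility
from userlift.mobility import (ClusterModel, FEATURE_COLUMNS, compute_daily_features,
                               detect_stationary, extract_features,
                               fit_full_clustering, fit_stationary_clustering,
                               identify_semantic_clusters, read_cluster_models,
                               write_cluster_models)


class TestDetectStationary:
    def test_coincident_points_are_stationary(self):
        xy = np.zeros((2, 2))
        ts = np.array([0, 60])
        assert detect_stationary(xy, ts).tolist() == [True, True]

    def test_six_kmh_is_moving(self):
        # 100 m in 60 s = 6 km/h, above the ~1 km/h threshold
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        ts = np.array([0, 60])
        assert detect_stationary(xy, ts).tolist() == [False, False]

    def test_below_threshold_is_stationary(self):
        # 10 m in 60 s = 0.6 km/h
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert detect_stationary(xy, np.array([0, 60])).tolist() == [True, True]

    def test_first_sample_inherits_second(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        ts = np.array([0, 60, 120])
        assert detect_stationary(xy, ts).tolist() == [False, False, True]

    def test_zero_dt_distinct_coords_flagged_moving(self):
        xy = np.array([[0.0, 0.0], [50.0, 0.0]])
        ts = np.array([60, 60])
        assert detect_stationary(xy, ts).tolist() == [False, False]

    def test_provider_flag_passthrough(self):
        # when the provider supplies is_moving it is used untouched
        locs = pd.DataFrame({
            "user_id": "u1",
            "timestamp": [0, 60, 120],
            "latitude": [42.0, 42.0, 42.0],
            "longitude": [-71.0, -71.0, -71.0],
            "is_moving": [1, 0, 1],
        })
        model, xy, stationary = mobility.fit_user_cluster_model("u1", locs, max_clusters=2)
        assert stationary.tolist() == [False, True, False]


class TestFullClustering:
    def test_single_point_gives_k1(self):
        xy = np.tile([10.0, 20.0], (50, 1))
        gmm = fit_full_clustering(xy, seed=0)
        assert gmm.n_components == 1

    def test_selected_k_minimizes_bic(self, rng):
        xy = np.vstack([rng.normal(c, 30.0, size=(80, 2))
                        for c in ([0, 0], [5000, 0], [0, 5000])])
        gmm = fit_full_clustering(xy, max_clusters=8, seed=0)
        bics = [fit_full_clustering(xy, max_clusters=8, seed=0).bic(xy)]
        for k in range(1, 9):
            from sklearn.mixture import GaussianMixture
            other = GaussianMixture(n_components=k, covariance_type="diag",
                                    random_state=0, n_init=2, reg_covar=1e-4).fit(xy)
            assert gmm.bic(xy) <= other.bic(xy) + 1e-6

    def test_three_separated_clusters_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            xy = np.vstack([rng.normal(c, 50.0, size=(70, 2))
                            for c in ([0, 0], [6000, 0], [0, 6000])])
            hits += fit_full_clustering(xy, max_clusters=8, seed=seed).n_components == 3
        assert hits >= 9

    def test_small_sample_caps_k(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(size=(10, 2)) * 1000
        gmm = fit_full_clustering(xy, seed=0)
        assert gmm.n_components <= 5  # floor(10 / 2)


def _model_from_params(means, covs, weights, centroids, home=0, work=1, night=0):
    return ClusterModel.from_dict({
        "user_id": "u1", "origin": (42.0, -71.0), "k_full": len(weights),
        "weights": weights, "means": means, "covariances": covs,
        "stationary_centroids": centroids,
        "home_cluster_id": home, "work_cluster_id": work, "night_cluster_id": night,
    })


TWO_SITE_MODEL = dict(
    means=[[0.0, 0.0], [5000.0, 0.0]],
    covs=[[100.0, 100.0], [100.0, 100.0]],
    weights=[0.5, 0.5],
    centroids=[[0.0, 0.0], [5000.0, 0.0]],
)


class TestSemanticClusters:
    def test_single_location_user_home_equals_work(self):
        model = _model_from_params([[0.0, 0.0]], [[100.0, 100.0]], [1.0], [[0.0, 0.0]],
                                   home=None, work=None, night=None)
        n = 48
        ts = np.arange(n) * 1800 + 1_704_067_200  # every 30 min across one day
        xy = np.zeros((n, 2))
        model = identify_semantic_clusters(model, xy, ts)
        assert model.home_cluster_id == model.work_cluster_id == 0
        assert model.night_cluster_id == 0

    def test_night_and_work_windows_separate_clusters(self):
        model = _model_from_params(**TWO_SITE_MODEL, home=None, work=None, night=None)
        day0 = 1_704_067_200
        night_ts = day0 + np.arange(0, 6 * 3600, 1800)          # 00:00-06:00 UTC
        work_ts = day0 + 11 * 3600 + np.arange(0, 5 * 3600, 1800)  # 11:00-16:00
        ts = np.concatenate([night_ts, work_ts])
        xy = np.vstack([np.zeros((len(night_ts), 2)),
                        np.tile([5000.0, 0.0], (len(work_ts), 1))])
        model = identify_semantic_clusters(model, xy, ts)
        assert model.home_cluster_id == 0
        assert model.work_cluster_id == 1
        assert model.night_cluster_id == 0

    def test_empty_window_leaves_id_undefined_and_flagged(self):
        model = _model_from_params(**TWO_SITE_MODEL, home=None, work=None, night=None)
        day0 = 1_704_067_200
        ts = day0 + 12 * 3600 + np.arange(0, 3600, 600)  # midday only
        xy = np.tile([5000.0, 0.0], (len(ts), 1))
        model = identify_semantic_clusters(model, xy, ts)
        assert model.home_cluster_id is None
        assert model.night_cluster_id is None
        assert any("home" in f for f in model.flags)

    def test_sample_count_dwell_matches_time_weighted_under_uniform_sampling(self):
        # with strictly regular sampling, counting samples equals weighting by
        # time intervals, so the count-based rule agrees with a time oracle
        model = _model_from_params(**TWO_SITE_MODEL, home=None, work=None, night=None)
        day0 = 1_704_067_200
        ts = day0 + np.arange(0, 86400, 900)
        hours = ((ts - day0) // 3600) % 24
        at_work = (hours >= 9) & (hours < 17)
        xy = np.where(at_work[:, None], [5000.0, 0.0], [0.0, 0.0])
        model = identify_semantic_clusters(model, xy, ts)
        # time-weighted oracle over the 23:00-06:00 window: home occupies all of it
        assert model.home_cluster_id == 0
        assert model.work_cluster_id == 1


class TestDailyFeatures:
    def _features(self, xy, ts, stationary, model, mean_fracs=None):
        if mean_fracs is None:
            mean_fracs = mobility._stationary_fractions(
                model.assign_stationary(xy), model.k_stationary)
        return compute_daily_features(np.asarray(xy, float), np.asarray(ts),
                                      np.asarray(stationary), model, mean_fracs)

    def test_degenerate_day_all_at_one_point(self):
        model = _model_from_params([[0.0, 0.0]], [[100.0, 100.0]], [1.0],
                                   [[0.0, 0.0]], home=0, work=0, night=0)
        n = 40
        xy = np.zeros((n, 2))
        ts = np.arange(n) * 600
        f = self._features(xy, ts, np.ones(n, bool), model)
        assert f["frac_not_stationary"] == 0.0
        assert f["mean_displacement"] == 0.0 and f["sd_displacement"] == 0.0
        assert f["location_entropy"] == 0.0
        assert f["mec_radius"] == 0.0
        assert f["n_gmm_clusters_visited"] == 1
        assert f["n_stationary_clusters_visited"] == 1
        assert f["frac_home"] == 1.0

    def test_circadian_movement_zero_when_day_matches_mean(self):
        model = _model_from_params(**TWO_SITE_MODEL)
        xy = np.vstack([np.zeros((20, 2)), np.tile([5000.0, 0.0], (20, 1))])
        ts = np.arange(40) * 600
        f = self._features(xy, ts, np.ones(40, bool), model,
                           mean_fracs=np.array([0.5, 0.5]))
        assert f["circadian_movement"] == pytest.approx(0.0)

    def test_entropy_of_even_two_cluster_split_is_ln2(self):
        model = _model_from_params(**TWO_SITE_MODEL)
        xy = np.vstack([np.zeros((20, 2)), np.tile([5000.0, 0.0], (20, 1))])
        ts = np.arange(40) * 600
        f = self._features(xy, ts, np.ones(40, bool), model)
        assert f["location_entropy"] == pytest.approx(np.log(2), rel=1e-9)

    def test_displacement_mean_and_sd(self):
        model = _model_from_params([[0.0, 0.0]], [[100.0, 100.0]], [1.0], [[0.0, 0.0]],
                                   home=0, work=0, night=0)
        xy = np.array([[0.0, 0.0], [30.0, 0.0], [30.0, 40.0]])
        ts = np.array([0, 60, 120])
        f = self._features(xy, ts, np.zeros(3, bool), model)
        assert f["mean_displacement"] == pytest.approx(35.0)  # (30 + 40) / 2
        assert f["sd_displacement"] == pytest.approx(5.0)
        assert f["frac_not_stationary"] == 1.0

    def test_displacements_skip_long_gaps(self):
        model = _model_from_params([[0.0, 0.0]], [[100.0, 100.0]], [1.0], [[0.0, 0.0]],
                                   home=0, work=0, night=0)
        xy = np.array([[0.0, 0.0], [30.0, 0.0], [9000.0, 0.0]])
        ts = np.array([0, 60, 60 + 7200])  # overnight-style gap to the third fix
        f = self._features(xy, ts, np.zeros(3, bool), model)
        assert f["mean_displacement"] == pytest.approx(30.0)

    def test_scale_equivariance(self):
        # doubling coordinates doubles f2/f3/f7 and adds ln 4 to the log-variance
        base = _model_from_params(**TWO_SITE_MODEL)
        scaled = _model_from_params(
            means=[[0.0, 0.0], [10000.0, 0.0]],
            covs=[[400.0, 400.0], [400.0, 400.0]],
            weights=[0.5, 0.5],
            centroids=[[0.0, 0.0], [10000.0, 0.0]])
        rng = np.random.default_rng(5)
        xy = np.vstack([rng.normal(0, 200, (20, 2)), rng.normal([5000, 0], 200, (20, 2))])
        ts = np.arange(40) * 600
        st = np.ones(40, bool)
        f1 = self._features(xy, ts, st, base)
        f2 = self._features(2 * xy, ts, st, scaled)
        assert f2["mean_displacement"] == pytest.approx(2 * f1["mean_displacement"])
        assert f2["sd_displacement"] == pytest.approx(2 * f1["sd_displacement"])
        assert f2["mec_radius"] == pytest.approx(2 * f1["mec_radius"])
        assert f2["log_location_variance"] - f1["log_location_variance"] == \
            pytest.approx(np.log(4), abs=1e-6)

    def test_day_aic_bic_from_loglik_and_m(self):
        model = _model_from_params(**TWO_SITE_MODEL)
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 10, (35, 2))
        ts = np.arange(35) * 600
        f = self._features(xy, ts, np.ones(35, bool), model)
        m = 5 * 2 - 1  # diagonal mixture: (K-1) + 2K + 2K
        assert f["gmm_day_aic"] == pytest.approx(2 * m - 2 * f["gmm_day_loglik"])
        assert f["gmm_day_bic"] == pytest.approx(m * np.log(35) - 2 * f["gmm_day_loglik"])


class TestExtractFeatures:
    def test_feature_frame_shape_and_bounds(self, small_day_features):
        merged, features, models = small_day_features
        assert set(FEATURE_COLUMNS).issubset(features.columns)
        for col in ("frac_not_stationary", "frac_home", "frac_work", "frac_night"):
            assert features[col].between(0, 1).all()
        assert (features["mec_radius"] >= 0).all()
        assert (features["location_entropy"] >= -1e-12).all()
        for uid, model in models.items():
            rows = features[features["user_id"] == uid]
            assert (rows["location_entropy"] <= np.log(max(model.k_stationary, 1)) + 1e-9).all()
            assert (rows["n_gmm_clusters_visited"] <= model.k_full).all()
            assert (rows["n_stationary_clusters_visited"] <= model.k_stationary).all()
            np.testing.assert_allclose(model.gmm.weights_.sum(), 1.0, atol=1e-9)

    def test_home_fraction_complements_away(self, small_day_features):
        # frac_home plus the fraction in all non-home components is 1
        merged, features, models = small_day_features
        assert (features["frac_home"] <= 1.0 + 1e-12).all()

    def test_determinism(self, small_cohort, small_scale, small_settings):
        from userlift.pipeline import featurize
        locations, responses, _ = small_cohort
        m1, f1, _ = featurize(locations, responses, small_scale, small_settings)
        m2, f2, _ = featurize(locations, responses, small_scale, small_settings)
        pd.testing.assert_frame_equal(f1, f2)

    def test_cluster_model_round_trip(self, tmp_path, small_day_features):
        _, features, models = small_day_features
        path = write_cluster_models(models, tmp_path / "models.json")
        loaded = read_cluster_models(path)
        for uid in models:
            np.testing.assert_allclose(loaded[uid].gmm.means_, models[uid].gmm.means_)
            np.testing.assert_allclose(loaded[uid].stationary_centroids,
                                       models[uid].stationary_centroids)
            assert loaded[uid].home_cluster_id == models[uid].home_cluster_id


def test_stationary_clustering_recovers_separated_sites(rng):
    xy = np.vstack([rng.normal(c, 40.0, size=(100, 2))
                    for c in ([0, 0], [4000, 0], [0, 4000])])
    centroids = fit_stationary_clustering(xy, max_clusters=8, seed=1)
    assert centroids.shape[0] == 3
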
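"""Scaling, k-means, silhouette selection and nearest-centroid routing."""

import numpy as np
import pandas as pd
import pytest

from bpcluster.cluster import (
    ClusterModel,
    ScalingModel,
    apply_scaler,
    assign_cluster,
    fit_clusters,
    fit_scaler,
    invert_scaler,
    kmeans_fit,
    load_cluster_model,
    mean_silhouette,
    save_cluster_model,
    select_k,
)


def brute_force_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) reference silhouette: (b-a)/max(a,b), singletons contribute 0."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            continue  # singleton
        a = d[i, same].sum() / (same.sum() - 1)
        b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def two_blobs(n=10, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.1, (n, 3))
    b = rng.normal(sep, 0.1, (n, 3))
    return np.vstack([a, b])


class TestScaler:
    def test_two_point_column(self):
        table = pd.DataFrame({"ptt_s": [1.0, 3.0], "pir_ratio": [1.0, 3.0],
                              "hr_bpm": [1.0, 3.0]})
        scaler = fit_scaler(table)
        np.testing.assert_allclose(scaler.center, [2, 2, 2])
        np.testing.assert_allclose(scaler.scale, [1, 1, 1])  # population SD
        np.testing.assert_allclose(apply_scaler(scaler, table),
                                   [[-1, -1, -1], [1, 1, 1]])

    def test_constant_column_scale_one_with_warning(self):
        table = pd.DataFrame({"ptt_s": [5.0, 5.0, 5.0], "pir_ratio": [1.0, 2.0, 3.0],
                              "hr_bpm": [60.0, 70.0, 80.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaler = fit_scaler(table)
        assert scaler.scale[0] == 1.0
        assert np.all(apply_scaler(scaler, table)[:, 0] == 0.0)

    def test_scaled_columns_standardized(self, truth_features):
        scaled = apply_scaler(fit_scaler(truth_features), truth_features)
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=0), 1, atol=1e-12)

    def test_invert_is_identity(self, truth_features):
        scaler = fit_scaler(truth_features)
        x = truth_features[["ptt_s", "pir_ratio", "hr_bpm"]].to_numpy()
        np.testing.assert_allclose(invert_scaler(scaler, apply_scaler(scaler, x)), x)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ScalingModel(center=np.zeros(3), scale=np.array([1.0, 0.0, 1.0]))


class TestKmeans:
    def test_two_blob_optimum(self):
        pts = two_blobs()
        centroids, labels, inertia = kmeans_fit(pts, 2, seed=0)
        order = np.argsort(centroids[:, 0])
        np.testing.assert_allclose(centroids[order][0], pts[:10].mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(centroids[order][1], pts[10:].mean(axis=0), atol=1e-8)
        within = (((pts[:10] - pts[:10].mean(0)) ** 2).sum()
                  + ((pts[10:] - pts[10:].mean(0)) ** 2).sum())
        assert inertia == pytest.approx(within)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kmeans_fit(two_blobs(), 1)

    def test_k_above_distinct_points_rejected(self):
        pts = np.tile([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_fit(pts, 3)

    def test_seed_determinism(self):
        pts = two_blobs(seed=3)
        _, l1, _ = kmeans_fit(pts, 2, seed=11)
        _, l2, _ = kmeans_fit(pts, 2, seed=11)
        np.testing.assert_array_equal(l1, l2)


class TestSilhouette:
    def test_separated_blobs_near_one(self):
        pts = two_blobs(sep=100.0)  # 100x the within-blob spread
        labels = np.repeat([0, 1], 10)
        assert mean_silhouette(pts, labels) >= 0.99

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            pts = rng.normal(size=(30, 3))
            labels = rng.integers(0, rng.integers(2, 5), size=30)
            if len(np.unique(labels)) < 2:
                continue
            assert mean_silhouette(pts, labels) == pytest.approx(
                brute_force_silhouette(pts, labels), abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette(two_blobs(), np.zeros(20, dtype=int))


class TestSelectK:
    def test_five_regimes_recovered(self, truth_features):
        scaled = apply_scaler(fit_scaler(truth_features), truth_features)
        model = select_k(scaled, 2, 10, seed=0)
        assert model.k == 5
        assert model.k == max(model.silhouette_by_k, key=model.silhouette_by_k.get)

    def test_two_blobs_give_k2(self):
        model = select_k(two_blobs(n=30), 2, 6, seed=0)
        assert model.k == 2

    def test_tie_break_prefers_smaller_k(self):
        scores = {3: 0.7, 4: 0.7, 5: 0.2}
        best = max(scores, key=lambda k: (scores[k], -k))
        assert best == 3

    def test_single_regime_silhouette_low_and_flat(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(300, 3))  # one isotropic cloud
        model = select_k(pts, 2, 10, seed=0)
        scores = np.array(list(model.silhouette_by_k.values()))
        assert scores.max() < 0.4
        assert scores.max() - scores.min() < 0.2

    def test_label_partition_matches_regimes(self, truth_features):
        scaled = apply_scaler(fit_scaler(truth_features), truth_features)
        model = select_k(scaled, 2, 10, seed=0)
        regime = truth_features["regime_id"].to_numpy()
        # best-match agreement up to label permutation
        agree = 0
        for c in range(model.k):
            idx = model.labels == c
            agree += np.bincount(regime[idx]).max()
        assert agree / len(regime) >= 0.95


class TestAssign:
    @pytest.fixture
    def fitted(self, truth_features):
        scaler = fit_scaler(truth_features)
        model = fit_clusters(apply_scaler(scaler, truth_features), 5, seed=0)
        return model, scaler

    def test_training_rows_route_to_their_labels(self, fitted, truth_features):
        model, scaler = fitted
        np.testing.assert_array_equal(
            assign_cluster(model, scaler, truth_features), model.labels)

    def test_point_at_centroid_routes_to_it(self, fitted):
        model, scaler = fitted
        point = invert_scaler(scaler, model.centroids[2])
        row = pd.DataFrame([point], columns=["ptt_s", "pir_ratio", "hr_bpm"])
        assert assign_cluster(model, scaler, row)[0] == 2

    def test_midpoint_tie_routes_to_lower_index(self, fitted):
        model, scaler = fitted
        mid = invert_scaler(scaler, (model.centroids[0] + model.centroids[1]) / 2)
        row = pd.DataFrame([mid], columns=["ptt_s", "pir_ratio", "hr_bpm"])
        assert assign_cluster(model, scaler, row)[0] == 0


class TestModelInvariants:
    def test_every_cluster_nonempty_enforced(self):
        with pytest.raises(ValueError, match="non-empty"):
            ClusterModel(k=3, centroids=np.zeros((3, 3)),
                         labels=np.array([0, 1, 0, 1]), inertia=0.0,
                         silhouette_by_k={3: 0.5}, seed=0)

    def test_json_round_trip(self, tmp_path, truth_features):
        scaler = fit_scaler(truth_features)
        model = fit_clusters(apply_scaler(scaler, truth_features), 5, seed=0)
        path = save_cluster_model(model, scaler, tmp_path / "model.json")
        model2, scaler2 = load_cluster_model(path)
        np.testing.assert_allclose(model2.centroids, model.centroids)
        np.testing.assert_array_equal(model2.labels, model.labels)
        np.testing.assert_allclose(scaler2.center, scaler.center)
        assert model2.silhouette_by_k == model.silhouette_by_k
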
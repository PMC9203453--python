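import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from lesioncast.subset_classifier import (
    drop_sparse_features,
    fit_subset_classifier,
    fit_subset_pipeline,
    multiclass_mcc,
    predict_subset,
    reduce_dimensions,
    screen_features_kw,
)

SMALL_GRID = {"n_estimators": (50,), "max_depth": (None, 3)}


class TestDropSparseFeatures:
    def test_missingness_threshold(self):
        df = pd.DataFrame(
            {
                "all_missing": [np.nan] * 10,
                "three_of_ten": [np.nan] * 3 + [1.0] * 7,
                "complete": np.arange(10.0),
            }
        )
        kept, dropped, medians = drop_sparse_features(df, max_missing_fraction=0.2)
        assert set(dropped) == {"all_missing", "three_of_ten"}  # 0.3 > 0.2
        assert not kept.isna().any().any()
        # same feature over 20 subjects (0.15 <= 0.2) is kept and imputed
        df20 = pd.DataFrame({"f": [np.nan] * 3 + [2.0] * 17, "g": np.arange(20.0)})
        kept20, dropped20, med20 = drop_sparse_features(df20, 0.2)
        assert dropped20 == []
        assert kept20["f"].iloc[0] == med20["f"] == 2.0

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        kept, dropped, _ = drop_sparse_features(df)
        pd.testing.assert_frame_equal(kept, df)
        assert dropped == []

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            drop_sparse_features(df, 0.2)


class TestScreenKW:
    def _labels(self, n_per=20):
        return np.repeat([1, 2, 3], n_per)

    def test_constant_feature_dropped_signal_kept(self):
        rng = np.random.default_rng(0)
        labels = self._labels()
        df = pd.DataFrame(
            {
                "constant": np.ones(60),
                "signal": labels + rng.normal(0, 0.01, 60),
                "noise": rng.normal(size=60),
            }
        )
        kept = screen_features_kw(df, labels, alpha=0.05)
        assert "signal" in kept.columns
        assert "constant" not in kept.columns

    def test_alpha_extremes(self):
        rng = np.random.default_rng(1)
        labels = self._labels()
        df = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        assert list(screen_features_kw(df, labels, alpha=1.0).columns) == list("abcde")
        assert list(screen_features_kw(df, labels, alpha=0.0).columns) == []

    def test_null_type_i_rate_near_alpha(self):
        # pure-noise features pass the screen in about 5% of simulations
        rng = np.random.default_rng(2)
        labels = self._labels()
        n_sim, hits = 1000, 0
        df = pd.DataFrame(rng.normal(size=(60, n_sim)))
        kept = screen_features_kw(df, labels, alpha=0.05)
        rate = kept.shape[1] / n_sim
        assert 0.03 <= rate <= 0.075


class TestReduceDimensions:
    def test_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        df = pd.DataFrame({"a": base, "b": 2 * base})
        scores, red = reduce_dimensions(df, variance_target=0.95)
        assert red.n_components == 1
        assert scores.shape == (50, 1)

    def test_isotropic_data_needs_all_components(self):
        # independent standard normals: each PC carries ~1/5 of the variance
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(2000, 5)), columns=list("abcde"))
        _, red = reduce_dimensions(df, variance_target=0.95)
        assert red.n_components == 5

    def test_component_count_monotone_in_target(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(100, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.1])
        df = pd.DataFrame(x, columns=list("abcdef"))
        counts = [
            reduce_dimensions(df, variance_target=t)[1].n_components
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        _, red = reduce_dimensions(df, variance_target=1.0)
        xs = red.scaler.transform(df.to_numpy())
        recon = red.pca.inverse_transform(red.pca.transform(xs))
        assert np.allclose(recon, xs, atol=1e-10)

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ValueError):
            reduce_dimensions(df)


class TestMulticlassMCC:
    def brute_force_mcc(self, m):
        """Gorodkin's covariance formula expanded term by term."""
        m = np.asarray(m, float)
        k = m.shape[0]
        s = m.sum()
        cov_xy = sum(
            m[i, i] * m[j, l] - m[i, j] * m[l, i]
            for i in range(k)
            for j in range(k)
            for l in range(k)
        )
        cov_xx = sum(
            m[i, :].sum() * sum(m[j, :].sum() for j in range(k) if j != i)
            for i in range(k)
        )
        cov_yy = sum(
            m[:, i].sum() * sum(m[:, j].sum() for j in range(k) if j != i)
            for i in range(k)
        )
        return cov_xy / math.sqrt(cov_xx * cov_yy)

    def test_perfect_and_degenerate(self):
        assert multiclass_mcc(np.diag([5, 7, 3])) == pytest.approx(1.0)
        all_one_class = np.array([[10, 0, 0], [5, 0, 0], [5, 0, 0]])
        assert multiclass_mcc(all_one_class) == 0.0

    def test_against_formula_oracle(self):
        m = np.array([[50, 5, 5], [5, 50, 5], [5, 5, 50]])
        assert multiclass_mcc(m) == pytest.approx(self.brute_force_mcc(m))

    def test_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            m = np.zeros((3, 3), int)
            for t, p in zip(y_true, y_pred):
                m[t, p] += 1
            expected = matthews_corrcoef(y_true, y_pred)
            assert multiclass_mcc(m) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_class_permutation(self):
        rng = np.random.default_rng(8)
        m = rng.integers(0, 30, size=(3, 3))
        perm = rng.permutation(3)
        assert multiclass_mcc(m[np.ix_(perm, perm)]) == pytest.approx(multiclass_mcc(m))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            multiclass_mcc(np.zeros((0, 0)))


def separable_scores(seed=0, n_per=50):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [6, 0], [0, 6]])
    scores = np.vstack(
        [rng.normal(c, 0.5, size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat([1, 2, 3], n_per)
    return scores, labels


class TestForestTuning:
    def test_separable_classes_high_mcc_and_training_accuracy(self):
        scores, labels = separable_scores(seed=9)
        forest, best, record = fit_subset_classifier(
            scores, labels, seed=0, grid=SMALL_GRID, n_resamples=5
        )
        assert record["mcc"].max() >= 0.9
        assert (forest.predict(scores) == labels).all()

    def test_permuted_labels_give_near_zero_mcc(self):
        scores, labels = separable_scores(seed=10, n_per=30)
        rng = np.random.default_rng(1)
        mccs = []
        for _ in range(10):
            perm = rng.permutation(labels)
            _, _, record = fit_subset_classifier(
                scores, perm, seed=2, grid={"n_estimators": (30,)}, n_resamples=5
            )
            mccs.append(record["mcc"].iloc[0])
        assert abs(np.mean(mccs)) < 0.1

    def test_same_seed_identical_selection_and_predictions(self):
        scores, labels = separable_scores(seed=11)
        f1, b1, r1 = fit_subset_classifier(scores, labels, seed=3, grid=SMALL_GRID, n_resamples=3)
        f2, b2, r2 = fit_subset_classifier(scores, labels, seed=3, grid=SMALL_GRID, n_resamples=3)
        assert b1 == b2
        assert (f1.predict(scores) == f2.predict(scores)).all()
        pd.testing.assert_frame_equal(r1, r2)

    def test_fewer_than_three_classes_raises(self):
        scores, labels = separable_scores(seed=12)
        with pytest.raises(ValueError):
            fit_subset_classifier(scores, (labels == 1).astype(int), seed=0)


class TestEndToEndPipeline:
    def test_pipeline_beats_majority_class_and_is_deterministic(self):
        rng = np.random.default_rng(13)
        labels = np.repeat([1, 2, 3], [30, 40, 20])
        n = len(labels)
        df = pd.DataFrame(rng.normal(size=(n, 15)), columns=[f"v{i}" for i in range(15)])
        for j in range(5):  # five informative features
            df[f"v{j}"] += 1.5 * labels
        df.iloc[::17, 3] = np.nan
        clf = fit_subset_pipeline(df, labels, seed=4, grid=SMALL_GRID, n_resamples=3)
        pred = predict_subset(clf, df)
        majority = max(np.bincount(labels)[1:]) / n
        assert (pred == labels).mean() > majority
        clf2 = fit_subset_pipeline(df, labels, seed=4, grid=SMALL_GRID, n_resamples=3)
        assert (predict_subset(clf2, df) == pred).all()

    def test_missing_retained_feature_raises(self):
        rng = np.random.default_rng(14)
        labels = np.repeat([1, 2, 3], 20)
        df = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"v{i}" for i in range(8)])
        df["v0"] += labels * 2.0
        clf = fit_subset_pipeline(df, labels, seed=5, grid=SMALL_GRID, n_resamples=2)
        with pytest.raises(ValueError, match="missing retained"):
            predict_subset(clf, df.drop(columns=clf.screened_features[:1]))
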
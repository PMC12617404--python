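import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phenoprofiler.profiling import (
    DensityClusterer,
    RobustZScaler,
    assemble,
    choose_eps,
    ciliated_fraction,
    cluster_summary,
    dbscan,
    embed,
    median_split,
    robust_scale,
)


from _oracles import brute_force_dbscan, partitions_equal, random_instance


class TestDensityClusterer:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        X, eps, min_samples = random_instance(seed)
        labels = DensityClusterer(eps=eps, min_samples=min_samples).fit_predict(X)
        ref = brute_force_dbscan(X, eps, min_samples)
        assert partitions_equal(labels, ref)

    def test_matches_sklearn_core_partition(self):
        # independent cross-check: core points must partition identically
        from sklearn.cluster import DBSCAN

        X, eps, min_samples = random_instance(123)
        ours = DensityClusterer(eps=eps, min_samples=min_samples)
        labels = ours.fit_predict(X)
        sk = DBSCAN(eps=eps, min_samples=min_samples).fit(X)
        core = np.zeros(len(X), bool)
        core[sk.core_sample_indices_] = True
        np.testing.assert_array_equal(ours.core_sample_mask_, core)
        assert partitions_equal(labels[core], sk.labels_[core])

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.1, (100, 2)), rng.normal(10, 0.1, (100, 2))]
        )
        res = dbscan(X, eps=0.5, min_samples=5)
        assert res.n_clusters == 2
        assert (res.labels[:100] == res.labels[0]).all()
        assert (res.labels[100:] == res.labels[100]).all()
        assert res.labels[0] != res.labels[100]

    def test_identical_points_one_cluster(self):
        X = np.zeros((20, 3))
        res = dbscan(X, eps=0.1, min_samples=5)
        assert (res.labels == 0).all()

    def test_min_samples_exceeds_n_all_noise(self):
        X = np.random.default_rng(1).normal(size=(10, 2))
        res = dbscan(X, eps=0.5, min_samples=50)
        assert (res.labels == -1).all()

    def test_labels_contiguous_largest_first(self):
        X, eps, min_samples = random_instance(7)
        labels = DensityClusterer(eps=eps, min_samples=min_samples).fit_predict(X)
        ids = np.unique(labels[labels >= 0])
        assert list(ids) == list(range(len(ids)))
        sizes = [(labels == k).sum() for k in ids]
        assert sizes == sorted(sizes, reverse=True)


class TestRobustZScaler:
    def test_closed_form_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        z = RobustZScaler().fit_transform(df)
        assert z["a"].iloc[2] == 0.0
        assert z["a"].iloc[4] == 1.0

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="zero-IQR"):
            scaler = RobustZScaler().fit(df)
        assert scaler.dropped_ == ["b"]
        assert "b" not in scaler.transform(df).columns

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            float,
            (30, 3),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=32),
        )
    )
    def test_median_zero_iqr_one(self, X):
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        scaler = RobustZScaler()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = scaler.fit_transform(df)
        for col in z.columns:
            assert abs(z[col].median()) < 1e-9
            assert abs((z[col].quantile(0.75) - z[col].quantile(0.25)) - 1) < 1e-9

    def test_sklearn_pipeline_compatible(self):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("scale", RobustZScaler()), ("cluster", DensityClusterer(eps=2.0))])
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(20, 1, (50, 3))])
        labels = pipe.fit_predict(X)
        assert len(np.unique(labels[labels >= 0])) >= 1


class TestAssemble:
    def test_row_concatenation(self):
        a = pd.DataFrame({"cell_id": range(10), "f": np.arange(10.0)})
        b = pd.DataFrame({"cell_id": range(10), "f": np.arange(10.0) + 5})
        assert len(assemble([a, b])) == 20

    def test_imputation_flags(self):
        a = pd.DataFrame({"f": [1.0, 2.0, np.nan, 4.0]})
        out = assemble([a])
        assert "f_imputed" in out.columns
        assert out["f_imputed"].tolist() == [0, 0, 1, 0]
        assert out["f"].iloc[2] == pytest.approx(2.0)  # median of observed

    def test_high_missing_column_dropped(self):
        a = pd.DataFrame({"f": [1.0, np.nan, np.nan, np.nan], "g": [1.0, 2, 3, 4]})
        out = assemble([a])
        assert "f" not in out.columns and "g" in out.columns

    def test_empty_error(self):
        with pytest.raises(ValueError, match="no rows"):
            assemble([pd.DataFrame()])


class TestRobustScaleTable:
    def test_imputed_values_excluded_from_fit(self):
        # half the rows imputed at the median must not collapse the IQR
        observed = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0] + [np.nan] * 5})
        out = assemble([observed])
        scaled = robust_scale(out, columns=["f"])
        assert scaled.scale["f"] == pytest.approx(2.0)  # IQR of observed values
        assert scaled.values["f"].iloc[:5].tolist() == pytest.approx(
            [-1.0, -0.5, 0.0, 0.5, 1.0]
        )


class TestEmbed:
    def test_blob_separation_rank_preserved(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0] * 6, [4.0] * 6, [40.0] * 6])
        X = np.vstack([c + rng.normal(0, 0.3, (40, 6)) for c in centers])
        coords = embed(X, method="pca", seed=0)
        m = [coords[i * 40 : (i + 1) * 40].mean(axis=0) for i in range(3)]
        d01 = np.hypot(*(m[0] - m[1]))
        d02 = np.hypot(*(m[0] - m[2]))
        d12 = np.hypot(*(m[1] - m[2]))
        assert d01 < d12 < d02

    def test_deterministic(self):
        X = np.random.default_rng(1).normal(size=(30, 5))
        np.testing.assert_array_equal(embed(X, "pca", seed=3), embed(X, "pca", seed=3))

    def test_single_row_error(self):
        with pytest.raises(ValueError):
            embed(np.zeros((1, 4)), "pca")

    def test_unknown_backend(self):
        with pytest.raises(ValueError, match="pca"):
            embed(np.zeros((5, 3)), "tsne")


class TestClusterSummary:
    def test_strata(self):
        scaled = pd.DataFrame({"f": [0.0, 1, 2, 3]})
        labels = np.array([0, 0, 1, 1])
        cond = pd.Series(["a", "b", "a", "b"])
        out = cluster_summary(scaled, labels, cond)
        assert len(out) == 4
        assert set(out["cluster"]) == {0, 1}

    def test_noise_is_own_stratum(self):
        scaled = pd.DataFrame({"f": [0.0, 1, 2]})
        out = cluster_summary(scaled, np.array([0, 0, -1]))
        assert -1 in out["cluster"].values

    def test_single_cluster_global_means(self):
        scaled = pd.DataFrame({"f": [1.0, 3.0]})
        out = cluster_summary(scaled, np.array([0, 0]))
        assert out["f"].iloc[0] == pytest.approx(2.0)


class TestMedianSplit:
    def test_reference_median_threshold(self):
        df = pd.DataFrame({"d": [1.0, 2.0, 3.0, 4.0, 2.0, 3.0]})
        ref = np.array([True, True, True, True, False, False])
        labels, thr = median_split(df, "d", ref)
        assert thr == pytest.approx(2.5)
        assert labels[4] == 1 and labels[5] == 2

    def test_tie_goes_to_subcluster_one(self):
        df = pd.DataFrame({"d": [5.0, 5.0]})
        labels, thr = median_split(df, "d", np.array([True, True]))
        assert thr == 5.0 and (labels == 1).all()

    def test_missing_feature_error(self):
        df = pd.DataFrame({"d": [1.0]})
        with pytest.raises(ValueError):
            median_split(df, "nope", np.array([True]))

    def test_bimodal_mixture_recovery(self):
        rng = np.random.default_rng(0)
        low = rng.normal(5, 0.5, 200)
        high = rng.normal(25, 0.5, 200)
        df = pd.DataFrame({"d": np.concatenate([low, high])})
        ref = np.ones(400, bool)
        labels, _ = median_split(df, "d", ref)
        truth = np.array([1] * 200 + [2] * 200)
        assert (labels == truth).mean() >= 0.9


class TestCiliatedFraction:
    def test_fraction(self):
        counts = pd.DataFrame(
            {"condition": ["c", "c"], "cilia": [30, 10], "nuclei": [60, 40]}
        )
        out = ciliated_fraction(counts)
        assert out["fraction"].iloc[0] == pytest.approx(0.4)
        assert out["cilia"].iloc[0] == 40

    def test_zero_cilia(self):
        out = ciliated_fraction(
            pd.DataFrame({"condition": ["c"], "cilia": [0], "nuclei": [50]})
        )
        assert out["fraction"].iloc[0] == 0.0

    def test_zero_nuclei_missing(self):
        out = ciliated_fraction(
            pd.DataFrame({"condition": ["c"], "cilia": [10], "nuclei": [0]})
        )
        assert np.isnan(out["fraction"].iloc[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ciliated_fraction(
                pd.DataFrame({"condition": ["c"], "cilia": [-1], "nuclei": [5]})
            )


def test_choose_eps_two_scale_curve():
    """Elbow eps keeps two well-separated blobs apart while covering the
    bulk of each blob."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.2, (100, 2)), rng.normal(8, 0.2, (100, 2))])
    eps = choose_eps(X, 5)
    assert 0 < eps < 8  # never bridges the blobs
    labels = DensityClusterer(eps=eps, min_samples=5).fit_predict(X)
    a, b = labels[:100], labels[100:]
    # the two dominant clusters are pure and cover >= 90% of each blob
    dom_a = np.bincount(a[a >= 0]).argmax()
    dom_b = np.bincount(b[b >= 0]).argmax()
    assert dom_a != dom_b
    assert (a == dom_a).mean() >= 0.9 and (b == dom_b).mean() >= 0.9
    assert not np.isin(dom_b, a) and not np.isin(dom_a, b)
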
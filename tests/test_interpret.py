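"""Shapley attribution, loading back-projection, and importance summaries."""

import numpy as np
import pandas as pd
import pytest

from trpca import (
    CountTable,
    FeatureImportanceMatrix,
    SampleMetadata,
    ShapMatrix,
    compute_shap,
    feature_age_correlation,
    global_importances,
    importance_correlations,
    project_importances,
    sample_heatmap_data,
)
from trpca.rpca import RpcaResult


def make_rpca(loadings):
    loadings = np.asarray(loadings, dtype=float)
    j, k = loadings.shape
    return RpcaResult(embedding=np.zeros((1, j)), loadings=loadings,
                      explained_variance=np.ones(j) / j,
                      feature_means=np.zeros(k),
                      feature_ids=[f"f{i}" for i in range(k)],
                      sample_ids=["s0"])


class TestComputeShap:
    def test_constant_model_all_zero(self, rng):
        f = lambda X: np.full(len(X), 7.5)
        shap = compute_shap(f, rng.normal(size=(3, 4)), rng.normal(size=(10, 4)),
                            n_permutations=3, seed=0)
        assert np.abs(shap.values).max() < 1e-12
        assert shap.base_value == pytest.approx(7.5)

    def test_linear_model_closed_form(self, rng):
        """For f(x) = w.x the attribution is w_p (x_p - mean background_p)."""
        w = rng.normal(size=6)
        f = lambda X: X @ w
        X_test = rng.normal(size=(5, 6))
        bg = rng.normal(size=(20, 6))
        shap = compute_shap(f, X_test, bg, n_permutations=2, seed=1)
        expected = w * (X_test - bg.mean(axis=0))
        assert np.abs(shap.values - expected).max() < 1e-6

    def test_additivity(self, rng):
        """base value + attribution row = model prediction, per test sample."""
        w = rng.normal(size=5)
        f = lambda X: np.tanh(X @ w) * 10  # nonlinear on purpose
        X_test = rng.normal(size=(4, 5))
        bg = rng.normal(size=(15, 5))
        shap = compute_shap(f, X_test, bg, n_permutations=4, seed=2)
        recon = shap.base_value + shap.values.sum(axis=1)
        assert np.allclose(recon, f(X_test), atol=1e-10)

    def test_single_background_warns(self, rng):
        with pytest.warns(UserWarning, match="background"):
            compute_shap(lambda X: X[:, 0], rng.normal(size=(1, 3)),
                         rng.normal(size=(1, 3)), n_permutations=1)

    def test_deterministic_given_seed(self, rng):
        f = lambda X: (X ** 2) @ np.ones(4)
        X_test, bg = rng.normal(size=(2, 4)), rng.normal(size=(8, 4))
        a = compute_shap(f, X_test, bg, n_permutations=5, seed=3)
        b = compute_shap(f, X_test, bg, n_permutations=5, seed=3)
        assert np.array_equal(a.values, b.values)


class TestProjectImportances:
    def test_identity_loadings(self, rng):
        shap = ShapMatrix(rng.normal(size=(3, 4)), 0.0, 5)
        fi = project_importances(shap, make_rpca(np.eye(4)))
        assert np.array_equal(fi.values, shap.values)

    def test_hand_matrix_product(self):
        shap = ShapMatrix(np.array([[1.0, 0.0], [0.0, 2.0]]), 0.0, 5)
        fi = project_importances(shap, make_rpca([[1, 1], [1, -1]]))
        assert np.array_equal(fi.values, [[1.0, 1.0], [2.0, -2.0]])

    def test_zero_row_stays_zero(self):
        shap = ShapMatrix(np.zeros((1, 2)), 0.0, 5)
        fi = project_importances(shap, make_rpca([[0.6, 0.8], [0.8, -0.6]]))
        assert np.abs(fi.values).max() == 0.0

    def test_linearity(self, rng):
        L = make_rpca(rng.normal(size=(3, 7)))
        s1, s2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        combo = ShapMatrix(2.0 * s1 - 0.5 * s2, 0.0, 5)
        direct = project_importances(combo, L).values
        parts = (2.0 * project_importances(ShapMatrix(s1, 0.0, 5), L).values
                 - 0.5 * project_importances(ShapMatrix(s2, 0.0, 5), L).values)
        assert np.abs(direct - parts).max() < 1e-10

    def test_dimension_mismatch(self, rng):
        shap = ShapMatrix(rng.normal(size=(2, 3)), 0.0, 5)
        with pytest.raises(ValueError, match="components"):
            project_importances(shap, make_rpca(np.eye(4)))


class TestLinearSurrogateBackProjection:
    def test_global_importances_proportional_to_w_loadings(self, rng):
        """A linear head on components back-projects to w^T . loadings."""
        j, k = 5, 12
        Q, _ = np.linalg.qr(rng.normal(size=(k, j)))
        loadings = Q.T
        rpca = make_rpca(loadings)
        w = rng.normal(size=j)
        f = lambda X: X @ w
        X_test = rng.normal(size=(30, j))
        bg = rng.normal(size=(40, j))
        shap = compute_shap(f, X_test, bg, n_permutations=2, seed=0)
        fi = project_importances(shap, rpca)
        got = fi.values.mean(axis=0)
        expected = (w * (X_test.mean(axis=0) - bg.mean(axis=0))) @ loadings
        assert np.abs(got - expected).max() < 1e-6


class TestSummaries:
    def test_global_means_match_column_loop(self, rng):
        fi = FeatureImportanceMatrix(rng.normal(size=(6, 9)),
                                     feature_ids=[f"f{i}" for i in range(9)])
        g = global_importances(fi)
        brute = {f"f{i}": fi.values[:, i].mean() for i in range(9)}
        for feat, val in g.items():
            assert val == pytest.approx(brute[feat], abs=1e-12)
        mags = np.abs(g.to_numpy())
        assert (np.diff(mags) <= 1e-15).all()  # sorted by |mean| descending

    def test_identical_rows_and_sign_cancellation(self):
        row = np.array([1.0, -2.0, 0.5])
        fi = FeatureImportanceMatrix(np.vstack([row, row]))
        assert np.allclose(np.sort(global_importances(fi).to_numpy()),
                           np.sort(row))
        fi2 = FeatureImportanceMatrix(np.array([[1.0], [-1.0]]))
        assert global_importances(fi2).iloc[0] == 0.0

    def test_heatmap_top_k_and_bounds(self, rng):
        fi = FeatureImportanceMatrix(rng.normal(size=(10, 20)),
                                     feature_ids=[f"f{i}" for i in range(20)])
        data = sample_heatmap_data(fi, top_k=20)
        assert set(data["features"]) == set(fi.feature_ids)
        assert np.abs(data["matrix"]).max() <= 1.0 + 1e-12
        small = sample_heatmap_data(fi, top_k=5)
        assert small["matrix"].shape == (10, 5)

    def test_duplicate_samples_cluster_adjacently(self, rng):
        base = rng.normal(size=(5, 8))
        dup = np.vstack([base, base[2]])  # row 5 duplicates row 2
        fi = FeatureImportanceMatrix(dup, sample_ids=[f"s{i}" for i in range(6)])
        order = list(sample_heatmap_data(fi, top_k=8)["row_order"])
        assert abs(order.index(2) - order.index(5)) == 1


class TestImportanceCorrelations:
    def test_self_scale_and_sign(self, rng):
        fi = FeatureImportanceMatrix(rng.normal(size=(5, 7)))
        mats = {"m": fi,
                "double": FeatureImportanceMatrix(2.0 * fi.values),
                "neg": FeatureImportanceMatrix(-fi.values)}
        corr = importance_correlations(mats)
        assert corr.loc["m", "m"] == 1.0
        assert corr.loc["m", "double"] == pytest.approx(1.0)
        assert corr.loc["m", "neg"] == pytest.approx(-1.0)

    def test_zero_variance_is_nan_not_zero(self, rng):
        mats = {"m": FeatureImportanceMatrix(rng.normal(size=(4, 5))),
                "flat": FeatureImportanceMatrix(np.ones((4, 5)))}
        corr = importance_correlations(mats)
        assert np.isnan(corr.loc["m", "flat"])


class TestFeatureAgeCorrelation:
    def make(self, counts, ages):
        n = len(ages)
        table = CountTable([f"s{i}" for i in range(n)], ["target", "other"],
                           np.column_stack([counts, np.ones(n, dtype=int)]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": table.sample_ids,
            "subject_id": table.sample_ids,
            "age": ages,
        }))
        return table, meta

    def test_constructed_monotone_feature(self, rng):
        ages = rng.uniform(1, 5, 200)
        counts = np.rint(np.exp(ages)).astype(int)
        table, meta = self.make(counts, ages)
        assert feature_age_correlation(table, meta, "target") > 0.98

    def test_constant_feature_undefined(self, rng):
        ages = rng.uniform(20, 80, 50)
        table, meta = self.make(np.full(50, 9), ages)
        assert np.isnan(feature_age_correlation(table, meta, "target"))

    def test_null_correlation_small(self, rng):
        ages = rng.permutation(rng.uniform(20, 80, 1000))
        counts = rng.integers(0, 100, 1000)
        table, meta = self.make(counts, ages)
        assert abs(feature_age_correlation(table, meta, "target")) < 0.1
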
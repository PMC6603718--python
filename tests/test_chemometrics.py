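"""PCA/PCR/PLSR correctness against closed forms and independent oracles."""

import numpy as np
import pytest

from hydrofuse.chemometrics import (
    PCAScores,
    PCRRegressor,
    PLSRegressorNIPALS,
    cross_validate_components,
    fit_pca,
    score_metrics,
    transform_scores,
)


def random_problem(rng, n=30, p=10):
    x = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return x, y


def ols_predictions(x, y):
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ beta


class TestMetrics:
    def test_perfect_prediction(self):
        m = score_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.slope, m.offset) == pytest.approx((1, 0, 1, 0))

    def test_mean_prediction_scores_zero(self):
        m = score_metrics([0.0, 10.0, 20.0], [10.0, 10.0, 10.0])
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = score_metrics([0.0, 10.0, 20.0], [1.0, 10.0, 19.0])
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert m.r2 == pytest.approx(0.99)
        assert m.slope == pytest.approx(0.9)
        assert m.offset == pytest.approx(1.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            score_metrics([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestPCA:
    def test_rank_one_matrix_fully_explained_by_first_component(self, rng):
        x = np.outer(rng.normal(size=20), rng.normal(size=8))
        m = fit_pca(x, 2)
        assert m.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self, rng):
        m = fit_pca(rng.normal(size=(25, 12)), 6)
        gram = m.components_ @ m.components_.T
        assert np.allclose(gram, np.eye(6), atol=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        m = fit_pca(rng.normal(size=(25, 12)), 8)
        assert np.all(np.diff(m.explained_variance_) <= 1e-12)

    def test_eckart_young_reconstruction_error(self, rng):
        x = rng.normal(size=(20, 10))
        k = 4
        m = fit_pca(x, k)
        xc = x - x.mean(axis=0)
        recon = m.x_scores_ @ m.components_
        err = ((xc - recon) ** 2).sum() / (len(x) - 1)
        s = np.linalg.svd(xc, compute_uv=False)
        assert err == pytest.approx((s[k:] ** 2).sum() / (len(x) - 1), rel=1e-10)

    def test_transform_matches_training_scores_and_oracle(self, rng):
        x = rng.normal(size=(30, 9))
        m = fit_pca(x, 5)
        assert np.allclose(transform_scores(m, x), m.x_scores_, atol=1e-10)
        # independent SVD oracle on fresh samples, sign-aligned per component
        fresh = rng.normal(size=(6, 9))
        u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
        oracle = (fresh - x.mean(axis=0)) @ vt[:5].T
        signs = np.sign(np.sum(vt[:5] * m.components_, axis=1))
        assert np.allclose(transform_scores(m, fresh), oracle * signs, atol=1e-8)

    def test_transform_of_mean_row_is_zero(self, rng):
        x = rng.normal(size=(15, 7))
        m = fit_pca(x, 3)
        assert np.allclose(m.transform(x.mean(axis=0)[None, :]), 0.0, atol=1e-10)

    def test_excess_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(rng.normal(size=(5, 10)), 5)


class TestPCR:
    def test_full_rank_equals_ols(self, rng):
        x, y = random_problem(rng)
        pred = PCRRegressor(n_components=10).fit(x, y).predict(x)
        assert np.allclose(pred, ols_predictions(x, y), rtol=1e-8, atol=1e-8)

    def test_planted_three_factor_recovery(self, rng):
        t = rng.normal(size=(40, 3))
        loadings = rng.normal(size=(3, 20))
        x = t @ loadings
        y = t @ np.array([2.0, -1.0, 0.5])
        m = PCRRegressor(n_components=3).fit(x, y)
        assert score_metrics(y, m.predict(x)).r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_component_on_uncorrelated_response(self, rng):
        x = rng.normal(size=(500, 10))
        # response orthogonal to PC1 by construction: pure noise
        y = rng.normal(size=500)
        m = PCRRegressor(n_components=1).fit(x, y)
        assert score_metrics(y, m.predict(x)).r2 < 0.05


class TestPLSR:
    def test_full_rank_equals_ols(self, rng):
        x, y = random_problem(rng)
        pred = PLSRegressorNIPALS(n_components=10).fit(x, y).predict(x)
        assert np.allclose(pred, ols_predictions(x, y), rtol=1e-8, atol=1e-8)

    def test_single_feature_equals_simple_regression(self, rng):
        x = rng.normal(size=(20, 1))
        y = 3.0 * x[:, 0] + rng.normal(size=20)
        pred = PLSRegressorNIPALS(n_components=1).fit(x, y).predict(x)
        assert np.allclose(pred, ols_predictions(x, y), atol=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_sklearn_pls_oracle(self, rng, k):
        from sklearn.cross_decomposition import PLSRegression

        x, y = random_problem(rng)
        ours = PLSRegressorNIPALS(n_components=k).fit(x, y).predict(x)
        oracle = PLSRegression(n_components=k, scale=False).fit(x, y)
        assert np.allclose(ours, oracle.predict(x).ravel(), atol=1e-6)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            PLSRegressorNIPALS(n_components=2).fit(
                rng.normal(size=(10, 4)), np.full(10, 3.0)
            )

    def test_out_of_sample_scores_reproduce_training_scores(self, rng):
        x, y = random_problem(rng)
        m = PLSRegressorNIPALS(n_components=4).fit(x, y)
        assert np.allclose(m.transform(x), m.x_scores_, atol=1e-8)


class TestSharedLatentProperties:
    def test_pcr_and_plsr_agree_with_ols_at_full_rank(self, rng):
        x, y = random_problem(rng, n=25, p=6)
        ols = ols_predictions(x, y)
        for cls in (PCRRegressor, PLSRegressorNIPALS):
            pred = cls(n_components=6).fit(x, y).predict(x)
            assert np.allclose(pred, ols, atol=1e-8)

    def test_orthogonal_noise_features_do_not_change_predictions(self, rng):
        x, y = random_problem(rng, n=30, p=5)
        # noise columns residualized against [1, X, y]: exactly orthogonal
        basis = np.column_stack([np.ones(30), x, y])
        q, _ = np.linalg.qr(basis)
        noise = rng.normal(size=(30, 3))
        noise -= q @ (q.T @ noise)
        x_aug = np.hstack([x, noise])
        # PCR needs all 8 directions to cover the informative subspace;
        # PLSR stops at 5 because the deflated covariance with y vanishes
        # once the informative subspace is exhausted
        for cls, k_aug in ((PCRRegressor, 8), (PLSRegressorNIPALS, 5)):
            base = cls(n_components=5).fit(x, y).predict(x)
            aug = cls(n_components=k_aug).fit(x_aug, y).predict(x_aug)
            assert np.allclose(base, aug, atol=1e-6)


class TestCrossValidation:
    def planted(self, rng, n=60, p=40, k_true=3):
        t = rng.normal(size=(n, k_true))
        x = t @ rng.normal(size=(k_true, p))
        y = t @ rng.normal(size=k_true)
        return x, y

    def test_selects_planted_dimension(self, rng):
        x, y = self.planted(rng)
        table, k = cross_validate_components(
            x, y, range(1, 7), folds=10, seed=0, estimator=PCRRegressor()
        )
        assert k == 3
        assert list(table["n_components"]) == [1, 2, 3, 4, 5, 6]

    def test_cv_error_drops_at_planted_dimension(self, rng):
        x, y = self.planted(rng)
        table, _ = cross_validate_components(
            x, y, [2, 3], folds=10, seed=1, estimator=PCRRegressor()
        )
        rmse = dict(zip(table["n_components"], table["cv_rmse"]))
        assert rmse[3] < rmse[2]

    def test_leave_one_out_boundary(self, rng):
        x, y = random_problem(rng, n=12, p=4)
        table, _ = cross_validate_components(
            x, y, [1, 2], folds=12, seed=0, estimator=PLSRegressorNIPALS()
        )
        assert len(table) == 2  # pooled n predictions per k, no error

    def test_same_seed_identical_tables(self, rng):
        x, y = random_problem(rng, n=25, p=8)
        t1, k1 = cross_validate_components(x, y, [1, 2, 3], folds=5, seed=9)
        t2, k2 = cross_validate_components(x, y, [1, 2, 3], folds=5, seed=9)
        assert t1.equals(t2) and k1 == k2

    def test_oversized_fold_count_rejected(self, rng):
        x, y = random_problem(rng, n=10, p=4)
        with pytest.raises(ValueError, match="folds"):
            cross_validate_components(x, y, [1], folds=11)

    def test_infeasible_component_grid_rejected(self, rng):
        x, y = random_problem(rng, n=10, p=9)
        with pytest.raises(ValueError, match="infeasible"):
            cross_validate_components(x, y, [9], folds=2)
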
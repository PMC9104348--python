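"""Transforms, PCA, oPLS-DA, venetian-blind CV and the permutation test."""

import numpy as np
import pytest

from metatrack.chemometrics import (
    ModelError,
    apply_scaling,
    autoscale,
    glog,
    opls_da_fit,
    opls_da_predict,
    pca,
    permutation_test,
    pls1_fit,
    pls1_predict,
    pls_rmsecv,
    separation_statistic,
    venetian_blind_cv,
    venetian_blind_folds,
)


class TestAutoscale:
    def test_column_example(self):
        scaled, means, scales = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled.ravel(), [-1, 0, 1])
        assert means[0] == 2 and scales[0] == 1

    def test_constant_column_zeroed(self):
        scaled, _, scales = autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_array_equal(scaled[:, 1], 0)
        assert scales[1] == 1.0  # recorded as 1 so reapplication is safe

    def test_stored_transform_reproduces(self, rng):
        X = rng.normal(size=(10, 4))
        scaled, means, scales = autoscale(X)
        np.testing.assert_allclose(apply_scaling(X, means, scales), scaled, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ModelError):
            autoscale(np.ones((1, 3)))


class TestGlog:
    def test_lambda_zero_reduces_to_log2(self):
        assert glog(np.array([[4.0]]), lam=0.0)[0, 0] == pytest.approx(2.0)

    def test_zero_with_lambda_four(self):
        # log2((0 + sqrt(0+4))/2) = log2(1) = 0
        assert glog(np.array([[0.0]]), lam=4.0)[0, 0] == pytest.approx(0.0)

    def test_strictly_increasing(self, rng):
        x = np.sort(rng.uniform(0, 100, 200))
        g = glog(x[None, :], lam=2.5).ravel()
        assert np.all(np.diff(g) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ModelError):
            glog(np.array([[-1.0]]))


class TestPca:
    def test_perfectly_correlated_columns(self, rng):
        a = rng.normal(size=20)
        X = np.column_stack([a, 2 * a])
        X = X - X.mean(axis=0)
        _, _, evr = pca(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(12, 5))
        X -= X.mean(axis=0)
        scores, loadings, _ = pca(X, 5)
        np.testing.assert_allclose(scores @ loadings.T, X, atol=1e-8)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Brute-force oracle: eigenvectors of the covariance matrix."""
        for _ in range(5):
            X = rng.normal(size=(10, 6))
            X -= X.mean(axis=0)
            scores, loadings, evr = pca(X, 6)
            cov = X.T @ X / (X.shape[0] - 1)
            w, v = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            w, v = w[order], v[:, order]
            np.testing.assert_allclose(evr, w / w.sum(), atol=1e-8)
            for j in range(6):
                dot = abs(v[:, j] @ loadings[:, j])
                if w[j] > 1e-10:
                    assert dot == pytest.approx(1.0, abs=1e-8)  # up to sign


class TestOplsDa:
    def test_zero_orth_equals_one_component_pls(self, rng):
        X = rng.normal(size=(30, 15))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        model = opls_da_fit(X, y, n_orth=0)
        y_opls, _ = opls_da_predict(model, X)
        Xs, means, scales = autoscale(X)
        pls = pls1_fit(Xs, y, 1)
        y_pls = pls1_predict(pls, Xs, 1)
        assert np.abs(y_opls - y_pls).max() < 1e-10

    def test_separable_training_accuracy(self, rng):
        X = rng.normal(size=(24, 6))
        y = np.r_[np.ones(12), -np.ones(12)]
        X[:12, 0] += 8.0
        model = opls_da_fit(X, y, n_orth=1)
        _, classes = opls_da_predict(model, X)
        assert np.array_equal(classes, y)

    def test_orthogonal_component_removed_exactly(self, rng):
        """Adding y-orthogonal structure must not move predictive scores."""
        n = 30
        y = np.r_[np.ones(15), -np.ones(15)]
        yc = y - y.mean()
        t_y = yc / np.linalg.norm(yc)
        w = rng.normal(size=12)
        w /= np.linalg.norm(w)
        v = rng.normal(size=12)
        v -= (v @ w) * w
        v /= np.linalg.norm(v)
        t_o = rng.normal(size=n)
        t_o -= (t_o @ t_y) * t_y
        X = np.outer(t_y, w)
        X_conf = X + 2.0 * np.outer(t_o, v)
        m1 = opls_da_fit(X, y, n_orth=1, scale=False)
        m2 = opls_da_fit(X_conf, y, n_orth=1, scale=False)
        assert np.abs(m1.predictive_scores(X) - m2.predictive_scores(X_conf)).max() < 1e-6

    def test_score_orthogonality_invariant(self, rng):
        X = rng.normal(size=(25, 10))
        y = np.where(rng.random(25) < 0.5, 1.0, -1.0)
        model = opls_da_fit(X, y, n_orth=2)
        for t_o in model.t_orth:
            assert abs(model.t_pred @ t_o) < 1e-8

    def test_label_swap_flips_predictions(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.r_[np.ones(10), -np.ones(10)]
        X[:10] += 1.5
        _, c1 = opls_da_predict(opls_da_fit(X, y, 1), X)
        _, c2 = opls_da_predict(opls_da_fit(X, -y, 1), X)
        assert np.array_equal(c1, -c2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ModelError):
            opls_da_fit(rng.normal(size=(10, 3)), np.ones(10), 1)

    def test_all_zero_row_predicts_intercept_tie_to_ctrl(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.r_[np.ones(10), -np.ones(10)]  # balanced -> intercept 0
        X[:10] += 1.0
        model = opls_da_fit(X, y, 1)
        row = model.means[None, :].copy()  # scales to all-zero after centering
        y_hat, cls = opls_da_predict(model, row)
        assert y_hat[0] == pytest.approx(model.intercept, abs=1e-12)
        assert cls[0] == -1.0  # exact-tie convention: CTRL


class TestVenetianBlindCv:
    def test_fold_assignment_deterministic(self):
        folds = venetian_blind_folds(10, 3)
        np.testing.assert_array_equal(folds[0], [0, 3, 6, 9])
        np.testing.assert_array_equal(folds[1], [1, 4, 7])

    def test_perfectly_separable(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.where(np.arange(30) % 2 == 0, 1.0, -1.0)
        X[y == 1, 0] += 10.0
        rep = venetian_blind_cv(X, y, n_orth=1, n_folds=10)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_loo_equals_direct_oracle(self, rng):
        """n_folds = n must coincide with an explicit leave-one-out loop."""
        n = 12
        X = rng.normal(size=(n, 5))
        y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        X[y == 1] += 1.0
        rep = venetian_blind_cv(X, y, n_orth=1, n_folds=n)
        y_hat = np.empty(n)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            model = opls_da_fit(X[train], y[train], n_orth=1)
            y_hat[i] = opls_da_predict(model, X[i : i + 1])[0][0]
        np.testing.assert_allclose(rep.y_hat, y_hat, atol=1e-10)

    def test_null_accuracy_near_chance(self):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(100, 10))
            y = np.where(r.random(100) < 0.5, 1.0, -1.0)
            if np.unique(y).size < 2:
                continue
            accs.append(venetian_blind_cv(X, y, n_orth=1, n_folds=10).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_single_class_training_split_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([1.0, 1, 1, 1, 1, -1])
        with pytest.raises(ModelError):
            venetian_blind_cv(X, y, n_orth=0, n_folds=6)


class TestPermutationTest:
    def test_separable_data_minimum_p(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.r_[np.ones(15), -np.ones(15)]
        X[:15, :3] += 4.0
        _, p, null = permutation_test(X, y, n_orth=1, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)
        assert len(null) == 199

    def test_statistic_invariant_to_score_scaling(self, rng):
        scores = rng.normal(size=40)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        s1 = separation_statistic(scores, y)
        s2 = separation_statistic(5.0 * scores + 3.0, y)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ModelError):
            permutation_test(rng.normal(size=(10, 3)), np.r_[np.ones(5), -np.ones(5)], n_perm=0)


def test_pls_rmsecv_empty_feature_set_infinite():
    X = np.empty((10, 0))
    y = np.r_[np.ones(5), -np.ones(5)]
    assert pls_rmsecv(X, y) == np.inf
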
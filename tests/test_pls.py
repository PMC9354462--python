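import numpy as np
import pytest

from cardiopls.pls import (
    PLS,
    fit_nipals,
    fit_simpls,
    press,
    select_components,
)


def _factor_data(rng, n=120, p=12, q=5, r=3, noise=0.05,
                 x_noise=None):
    z = rng.normal(size=(n, r))
    L = rng.normal(size=(r, p))
    E = rng.normal(size=(r, q))
    X = z @ L + rng.normal(scale=x_noise if x_noise is not None else noise,
                           size=(n, p))
    Y = z @ E + rng.normal(scale=noise, size=(n, q))
    return X, Y


class TestFitting:
    def test_univariate_proportionality(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        Y = np.array([[-2.0], [0.0], [2.0]])
        res = fit_nipals(X, Y, n_components=1, scale=False)
        assert res.beta[0, 0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(res.fittedvalues, Y, atol=1e-12)

    def test_independent_response_shrinks_with_samples(self, rng):
        norms = []
        for n in (40, 4000):
            X = rng.normal(size=(n, 6))
            Y = rng.normal(size=(n, 2))  # no coupling planted
            res = fit_nipals(X, Y, n_components=2)
            norms.append(np.linalg.norm(res.beta))
        assert norms[1] < norms[0] / 3

    def test_exact_recovery_of_rank2_system(self, rng):
        z = rng.normal(size=(50, 2))
        X = z @ rng.normal(size=(2, 8))
        Y = z @ rng.normal(size=(2, 3))
        res = fit_nipals(X, Y, n_components=2, scale=False)
        assert press(Y, res.fittedvalues) <= 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(40, 6))
        Y = X @ rng.normal(size=(6, 3)) + 0.2 * rng.normal(size=(40, 3))
        Xc = np.column_stack([np.ones(40), X])
        ols = Xc @ np.linalg.lstsq(Xc, Y, rcond=None)[0]
        for fit in (fit_nipals, fit_simpls):
            res = fit(X, Y, n_components=6, scale=False)
            np.testing.assert_allclose(res.fittedvalues, ols, atol=1e-6)

    def test_nonconvergence_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            PLS(Y, X, n_components=0)
        with pytest.raises(ValueError):
            PLS(Y, X, n_components=4)  # > n_predictors
        Xc = X.copy()
        Xc[:, 0] = 7.0
        with pytest.raises(ValueError, match="constant"):
            PLS(Y, Xc, n_components=2, scale=True).fit()


class TestAlgorithmAgreement:
    def test_univariate_betas_identical(self, rng):
        X, Y = _factor_data(rng, q=1)
        for k in (1, 2, 3):
            b1 = fit_nipals(X, Y, n_components=k).beta
            b2 = fit_simpls(X, Y, n_components=k).beta
            np.testing.assert_allclose(b1, b2, atol=1e-8)

    def test_multivariate_betas_strongly_correlated(self, rng):
        X, Y = _factor_data(rng, q=5)
        b1 = fit_nipals(X, Y, n_components=3).beta
        b2 = fit_simpls(X, Y, n_components=3).beta
        r = np.corrcoef(b1.ravel(), b2.ravel())[0, 1]
        assert r > 0.99

    def test_first_weight_vector_shared(self, rng):
        X, Y = _factor_data(rng)
        w1 = fit_nipals(X, Y, n_components=1).x_weights[:, 0]
        w2 = fit_simpls(X, Y, n_components=1).x_weights[:, 0]
        w2 = w2 / np.linalg.norm(w2)
        assert abs(abs(w1 @ w2) - 1.0) < 1e-8

    def test_matches_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = _factor_data(rng, n=80)
        sk = sklearn.PLSRegression(n_components=3, scale=True).fit(X, Y)
        res = fit_nipals(X, Y, n_components=3, scale=True)
        np.testing.assert_allclose(res.beta, sk.coef_.T, atol=1e-2)
        r = np.corrcoef(res.beta.ravel(), sk.coef_.T.ravel())[0, 1]
        assert r > 0.9999


class TestPrediction:
    def test_mean_row_predicts_mean_response(self, rng):
        X, Y = _factor_data(rng)
        res = fit_nipals(X, Y, n_components=3)
        pred = res.predict(X.mean(axis=0))
        np.testing.assert_allclose(pred[0], Y.mean(axis=0), atol=1e-10)

    def test_componentwise_reconstruction_consistency(self, rng):
        X, Y = _factor_data(rng)
        res = fit_nipals(X, Y, n_components=3)
        # scores x y-loadings reconstruction in internal space
        recon = res.x_scores @ res.y_loadings.T
        recon = recon * res.y_scale + res.y_center
        np.testing.assert_allclose(res.fittedvalues, recon, atol=1e-10)

    def test_column_mismatch_rejected(self, rng):
        X, Y = _factor_data(rng)
        res = fit_nipals(X, Y, n_components=2)
        with pytest.raises(ValueError, match="columns"):
            res.predict(np.zeros((2, X.shape[1] + 1)))


class TestPress:
    def test_perfect_and_hand_values(self):
        Y = np.array([[3.0, 4.0]])
        assert press(Y, Y) == 0.0
        assert press(Y, np.zeros_like(Y)) == 25.0

    def test_matches_elementwise_oracle(self, rng):
        A = rng.normal(size=(7, 4))
        B = rng.normal(size=(7, 4))
        oracle = sum((A[i, j] - B[i, j]) ** 2
                     for i in range(7) for j in range(4))
        assert press(A, B) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            press(np.zeros((2, 2)), np.zeros((2, 3)))


class TestModelInvariants:
    def test_nipals_scores_orthogonal(self, rng):
        X, Y = _factor_data(rng)
        T = fit_nipals(X, Y, n_components=4).x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_variance_explained_fractions(self, rng):
        X, Y = _factor_data(rng)
        for fit in (fit_nipals, fit_simpls):
            res = fit(X, Y, n_components=4)
            for v in (res.var_explained_x, res.var_explained_y):
                assert (v >= -1e-12).all() and (v <= 1 + 1e-8).all()
                assert v.sum() <= 1 + 1e-8

    def test_fit_invariant_to_sample_order(self, rng):
        X, Y = _factor_data(rng)
        perm = rng.permutation(X.shape[0])
        a = fit_nipals(X, Y, n_components=3)
        b = fit_nipals(X[perm], Y[perm], n_components=3)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)

    def test_summary_reports_components(self, rng):
        X, Y = _factor_data(rng)
        text = fit_nipals(X, Y, n_components=3).summary()
        assert "NIPALS" in text and "No. components:   3" in text


class TestComponentSelection:
    def test_recovers_planted_rank(self, rng):
        X, Y = _factor_data(rng, n=150, r=3, noise=0.1, x_noise=0.002)
        curve = select_components(X, Y, max_components=6)
        assert curve.chosen == 3
        assert len(curve.press_values) == 6

    def test_pure_noise_chooses_one_component(self, rng):
        X = rng.normal(size=(80, 10))
        Y = rng.normal(size=(80, 3))
        curve = select_components(X, Y, max_components=5)
        assert curve.chosen == 1

    def test_excess_components_truncated_with_warning(self, rng):
        z = rng.normal(size=(30, 2))
        X = z @ rng.normal(size=(2, 6))  # rank 2
        Y = z @ rng.normal(size=(2, 2))
        with pytest.warns(UserWarning, match="truncated"):
            curve = select_components(X, Y, max_components=6)
        assert curve.n_evaluated <= 2
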
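"""Multivariate layer vs brute-force linear-algebra oracles."""

import numpy as np
import pytest

from asphyxomics.chemometrics import (backscale_loadings, cross_validate,
                                      dummy_code, nmc_permutation_null,
                                      nmc_repetitions, pca, pls_fit,
                                      pls_predict, select_ncomp, uv_scale)


class TestUvScale:
    def test_column_standardized(self):
        sc = uv_scale(np.array([[1.0], [2.0], [3.0]]))
        assert sc.X[:, 0].mean() == pytest.approx(0.0)
        assert sc.X[:, 0].std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = uv_scale(X)
        assert sc.X.shape[1] == 2 and sc.dropped == [1]

    def test_back_transform_round_trip(self, rng):
        X = rng.normal(size=(8, 4)) * 3 + 7
        sc = uv_scale(X)
        assert np.allclose(sc.backtransform(), X)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            uv_scale(np.ones((5, 3)))


class TestPca:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        r = pca(np.outer(u, v), k=2)
        assert r.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(9, 5))
        Xc = X - X.mean(0)
        r = pca(X, k=5)
        assert np.allclose(r.scores @ r.loadings.T, Xc, atol=1e-10)

    def test_agreement_with_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 8))
        sc = uv_scale(X)
        r = pca(sc, k=5)
        w, V = np.linalg.eigh(np.cov(sc.X, rowvar=False))
        order = np.argsort(w)[::-1]
        assert np.allclose(r.explained_variance_ratio[:5],
                           (w[order] / w.sum())[:5], atol=1e-10)
        for a in range(5):
            v = V[:, order[a]]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            assert np.allclose(r.loadings[:, a], v, atol=1e-8)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(5, 3)), k=5)


class TestPlsFit:
    def test_single_predictor_perfect_fit(self, rng):
        x = rng.normal(size=(12, 1))
        y = 3.0 * x[:, 0]
        m = pls_fit(x - x.mean(0), y - y.mean(), ncomp=1)
        assert m.r2[0] == pytest.approx(1.0)

    def test_exact_column_reaches_full_r2(self, rng):
        X = rng.normal(size=(12, 6))
        Xc = X - X.mean(0)
        y = Xc[:, 2].copy()
        m = pls_fit(Xc, y, ncomp=6)
        assert m.r2[-1] == pytest.approx(1.0, abs=1e-8)

    def test_first_weight_is_dominant_eigenvector(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=(12, 2))
        Xc, Yc = X - X.mean(0), y - y.mean(0)
        m = pls_fit(Xc, Yc, ncomp=1)
        M = Xc.T @ Yc @ Yc.T @ Xc
        w, V = np.linalg.eigh(M)
        v = V[:, np.argmax(w)]
        v = v * np.sign(v @ m.weights[:, 0])
        assert np.allclose(m.weights[:, 0], v, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        m = pls_fit(X - X.mean(0), y - y.mean(), ncomp=4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        Xc, yc = X - X.mean(0), y - y.mean()
        m1 = pls_fit(Xc, yc, ncomp=2)
        perm = rng.permutation(15)
        m2 = pls_fit(Xc[perm], yc[perm], ncomp=2)
        assert np.allclose(m1.coef, m2.coef, atol=1e-10)

    def test_agreement_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 7))
        y = rng.normal(size=20)
        Xc, yc = X - X.mean(0), y - y.mean()
        m = pls_fit(Xc, yc, ncomp=3)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(Xc, yc)
        assert np.allclose(pls_predict(m, Xc).ravel() + yc.mean(),
                           sk.predict(Xc).ravel(), atol=1e-8)

    def test_single_class_errors(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            pls_fit(X - X.mean(0), np.zeros(10), ncomp=1)


class TestCrossValidate:
    def test_perfectly_predictable(self, rng):
        X = rng.normal(size=(56, 4))
        y = 2.0 * X[:, 0]
        cv = cross_validate(X, y, folds=7, ncomp=3)
        assert cv.q2.max() > 0.99

    def test_null_q2_negative_in_expectation(self):
        q2 = []
        for s in range(60):
            r = np.random.default_rng(s)
            X = r.normal(size=(60, 30))
            y = r.normal(size=60)
            cv = cross_validate(X, y, folds=7, ncomp=1,
                                order=r.permutation(60))
            q2.append(cv.q2[0])
        assert np.mean(q2) < 0.0

    def test_q2_not_above_r2(self, rng):
        for _ in range(5):
            X = rng.normal(size=(35, 10))
            y = X[:, 0] + rng.normal(size=35)
            cv = cross_validate(X, y, folds=7, ncomp=2)
            m = pls_fit(*_scaled(X, y), ncomp=2)
            assert cv.q2[1] <= m.r2[1] + 1e-12

    def test_every_sample_predicted_once(self, rng):
        X = rng.normal(size=(21, 5))
        y = rng.normal(size=21)
        cv = cross_validate(X, y, folds=7, ncomp=1)
        assert np.isfinite(cv.predictions).all()

    def test_select_ncomp_smallest_at_max(self):
        assert select_ncomp(np.array([0.2, 0.5, 0.5])) == 2
        assert select_ncomp(np.array([0.7, 0.5])) == 1


def _scaled(X, y):
    sc = uv_scale(X)
    return sc.X, y - y.mean()


class TestNmc:
    def test_separated_classes_zero_nmc(self, rng):
        X = rng.normal(size=(40, 5))
        X[:20, 0] += 10
        labels = np.array(["a"] * 20 + ["b"] * 20)
        r = nmc_repetitions(X, labels, reps=20, seed=1)
        assert r.median == 0.0

    def test_identical_pairs_carry_no_class_information(self, rng):
        # every sample duplicated into both classes: labels carry no
        # information, so the observed NMC is not significantly below the
        # permuted-label null (it can exceed n/2: held-out twins are
        # predicted as their memorized duplicate's class)
        X0 = rng.normal(size=(30, 5))
        X = np.vstack([X0, X0])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        res = nmc_permutation_null(X, labels, reps=30, nperm=99, seed=2)
        assert res.median >= 25
        assert res.p_empirical > 0.1

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 6))
        labels = np.array(["a", "b"] * 15)
        r1 = nmc_repetitions(X, labels, reps=10, seed=5)
        r2 = nmc_repetitions(X, labels, reps=10, seed=5)
        assert np.array_equal(r1.observed, r2.observed)

    def test_reps_validation(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError):
            nmc_repetitions(X, labels, reps=0)

    def test_strong_separation_maximal_significance(self, rng):
        X = rng.normal(size=(40, 5))
        X[:20, 0] += 10
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = nmc_permutation_null(X, labels, reps=10, nperm=49, seed=3)
        assert res.p_empirical == pytest.approx(1 / 50)
        assert res.p_ranksum < 1e-6

    def test_nperm_validation(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError):
            nmc_permutation_null(X, labels, nperm=10)

    def test_null_median_matches_structureless_expectation(self, rng):
        # structureless X: null NMC should scatter around the chance level
        X = rng.normal(size=(40, 10))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = nmc_permutation_null(X, labels, reps=10, nperm=60, seed=4)
        # brute-force chance band: binomial(40, 1/2) central 95% ~ [14, 26]
        assert 12 <= res.null_median <= 28


class TestBackscaledLoadings:
    def test_zero_sd_zero_amplitude(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        sc = uv_scale(X)
        m = pls_fit(sc.X, y - y.mean(), ncomp=1)
        sds = np.array([1.0, 0.0, 2.0])
        bl = backscale_loadings(m, sds, X, y)
        assert bl.amplitude[1] == 0.0

    def test_perfect_predictor_color(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0] * 2
        sc = uv_scale(X)
        m = pls_fit(sc.X, y - y.mean(), ncomp=1)
        bl = backscale_loadings(m, sc.sds, X, y)
        assert abs(bl.color[0]) == pytest.approx(1.0)
        assert np.all(np.abs(bl.color) <= 1.0)

    def test_amplitude_proportional_to_response_covariance(self, rng):
        # the first weight is X'y on the scaled data, so the backscaled
        # amplitude equals the covariance of each (natural-scale) variable
        # with the response up to one common factor (brute-force check)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        sc = uv_scale(X)
        yc = y - y.mean()
        m = pls_fit(sc.X, yc, ncomp=1)
        bl = backscale_loadings(m, sc.sds, X, y)
        cov = (X - X.mean(0)).T @ yc / (len(y) - 1)
        ratio = cov / bl.amplitude
        assert np.allclose(ratio, ratio[0], rtol=1e-6)

    def test_sds_length_mismatch(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        sc = uv_scale(X)
        m = pls_fit(sc.X, y - y.mean(), ncomp=1)
        with pytest.raises(ValueError):
            backscale_loadings(m, np.ones(5), X, y)
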
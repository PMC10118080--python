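"""Scaling, PCA/OPLS-DA against independent oracles, CV and permutations."""

import numpy as np
import pytest

from oilmark.chemometrics import (
    class_dummy,
    cross_validate_q2,
    fit_oplsda,
    fit_pca,
    pareto_scale,
    permutation_test,
    variable_contributions,
)


def make_classes(n_per=6, k=2):
    return np.repeat([f"c{i}" for i in range(k)], n_per)


def make_separable(rng, n_per=6, k=2, p=10, effect=8.0, noise=0.5):
    classes = make_classes(n_per, k)
    X = rng.normal(0, noise, (n_per * k, p))
    for i in range(k):
        X[np.arange(len(classes)) // n_per == i, i] += effect
    return X, classes


class TestParetoScale:
    def test_unit_sd_column_becomes_centred(self):
        sm = pareto_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(sm.X[:, 0], [-1.0, 0.0, 1.0])

    def test_hand_computed_example(self):
        # column [0,0,4,4]: mean 2, sample SD 2.3094; x' = (x-2)/sqrt(2.3094)
        sm = pareto_scale(np.array([[0.0], [0.0], [4.0], [4.0]]))
        np.testing.assert_allclose(
            sm.X[:, 0], np.array([-2.0, -2.0, 2.0, 2.0]) / np.sqrt(2.3094), atol=1e-4
        )

    def test_constant_column_dropped(self):
        sm = pareto_scale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert sm.X.shape[1] == 1 and sm.n_dropped == 1

    def test_column_means_are_zero(self, rng):
        sm = pareto_scale(rng.lognormal(8, 1, (12, 30)))
        np.testing.assert_allclose(sm.X.mean(axis=0), 0.0, atol=1e-9)


class TestPca:
    def test_matches_svd_oracle_on_random_matrices(self, rng):
        for _ in range(5):
            X = rng.normal(size=(10, 8))
            Xc = X - X.mean(axis=0)
            model = fit_pca(Xc, 4)
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            for a in range(4):
                t_svd = U[:, a] * s[a]
                sign = np.sign(t_svd @ model.scores[:, a])
                np.testing.assert_allclose(model.scores[:, a], sign * t_svd, atol=1e-6)
                np.testing.assert_allclose(
                    model.loadings[:, a], sign * Vt[a], atol=1e-6
                )
                assert model.r2x_per_component[a] == pytest.approx(
                    s[a] ** 2 / (s**2).sum(), abs=1e-9
                )

    def test_rank_one_matrix_fully_explained(self, rng):
        X = np.outer(rng.normal(size=6), rng.normal(size=4))
        model = fit_pca(X, 1)
        assert model.r2x_per_component[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_conservation(self, rng):
        X = rng.normal(size=(9, 7))
        Xc = X - X.mean(axis=0)
        model = fit_pca(Xc, 3)
        resid = Xc - model.scores @ model.loadings.T
        total = (Xc**2).sum()
        comp_ss = (model.scores**2).sum()
        assert comp_ss + (resid**2).sum() == pytest.approx(total, rel=1e-8)

    def test_separates_oil_classes_on_synthetic_study(self, default_study):
        _, _, matrix, _ = default_study
        cols = np.flatnonzero(matrix.roles == "oil")
        sm = pareto_scale(matrix.abundance[:, cols].T)
        model = fit_pca(sm.X, 2)
        # silhouette of class labels on the t1-t2 plane must be positive
        from sklearn.metrics import silhouette_score

        assert silhouette_score(model.scores, matrix.classes[cols]) > 0


def _pls2_oracle(X, Y, n_components):
    """Straight iterative NIPALS PLS2 written independently for cross-checking."""
    Xr, Yr = X.copy(), Y.copy()
    T, P, C, W = [], [], [], []
    for _ in range(n_components):
        u = Yr[:, np.argmax(Yr.var(axis=0))]
        w = None
        for _ in range(100_000):
            w = Xr.T @ u
            w /= np.linalg.norm(w)
            t = Xr @ w
            c = Yr.T @ t / (t @ t)
            u_new = Yr @ c / (c @ c)
            if np.allclose(u_new, u, atol=1e-13, rtol=0):
                u = u_new
                break
            u = u_new
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        c = Yr.T @ t / (t @ t)
        T.append(t), P.append(p), C.append(c), W.append(w)
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, c)
    return map(np.column_stack, (W, T, P, C))


class TestOplsDa:
    def test_zero_orthogonal_equals_pls2_oracle(self, rng):
        X, classes = make_separable(rng, n_per=6, k=3, p=12)
        model = fit_oplsda(X, classes, n_predictive=2, n_orthogonal=0, cv_folds=None)
        Y, _ = class_dummy(classes)
        Yc = Y - Y.mean(axis=0)
        W, T, P, C = _pls2_oracle(model.scaler.X, Yc, 2)
        for a in range(2):
            sign = np.sign(T[:, a] @ model.scores[:, a])
            np.testing.assert_allclose(model.scores[:, a], sign * T[:, a], atol=1e-6)
            np.testing.assert_allclose(model.weights[:, a], sign * W[:, a], atol=1e-6)

    def test_orthogonal_scores_uncorrelated_with_class_dummies(self, default_study):
        _, _, matrix, _ = default_study
        cols = np.flatnonzero(matrix.roles == "oil")
        model = fit_oplsda(
            matrix.abundance[:, cols].T, matrix.classes[cols], 3, 2, cv_folds=None
        )
        Y, _ = class_dummy(matrix.classes[cols])
        Yc = Y - Y.mean(axis=0)
        for o in range(model.n_orthogonal):
            t = model.orth_scores[:, o]
            corr = Yc.T @ t / (np.linalg.norm(t) * np.linalg.norm(Yc, axis=0))
            assert np.abs(corr).max() < 1e-8

    def test_perfect_separation_limit(self, rng):
        X, classes = make_separable(rng, n_per=8, k=2, p=6, noise=1e-4)
        model = fit_oplsda(X, classes, 1, 0, cv_folds=8)
        assert model.r2y == pytest.approx(1.0, abs=1e-3)
        assert model.q2 > 0.99

    def test_q2_not_above_r2y_and_r2x_components_nonnegative(self, default_model):
        model, _ = default_model
        assert model.q2 <= model.r2y
        assert (model.r2x_per_component >= 0).all()
        assert (model.r2x_orth_per_component >= 0).all()
        assert model.r2x_cum <= 1.0 + 1e-9

    def test_adding_orthogonal_component_never_decreases_r2x(self, default_study):
        _, _, matrix, _ = default_study
        cols = np.flatnonzero(matrix.roles == "oil")
        X, cl = matrix.abundance[:, cols].T, matrix.classes[cols]
        r2x = [
            fit_oplsda(X, cl, 3, o, cv_folds=None).r2x_cum for o in range(3)
        ]
        assert r2x[0] <= r2x[1] <= r2x[2]

    def test_variance_conservation_after_deflation(self, rng):
        X, classes = make_separable(rng, n_per=5, k=3, p=9)
        model = fit_oplsda(X, classes, 2, 1, cv_folds=None)
        Xs = model.scaler.X
        resid = Xs.copy()
        for o in range(model.n_orthogonal):
            resid -= np.outer(model.orth_scores[:, o], model.orth_loadings[:, o])
        for a in range(model.n_predictive):
            resid -= np.outer(model.scores[:, a], model.loadings[:, a])
        explained = (Xs**2).sum() - (resid**2).sum()
        assert explained / (Xs**2).sum() == pytest.approx(model.r2x_cum, rel=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_oplsda(rng.normal(size=(6, 4)), ["a"] * 6, 1)

    def test_components_beyond_rank_rejected(self, rng):
        X, classes = make_separable(rng, n_per=3, k=2, p=4)
        with pytest.raises(ValueError):
            fit_oplsda(X, classes, 5, 0, cv_folds=None)

    def test_class_prediction_recovers_labels(self, rng):
        X, classes = make_separable(rng, n_per=6, k=3, p=12)
        model = fit_oplsda(X, classes, 2, 0, cv_folds=None)
        _, predicted = model.predict(X)
        assert predicted == list(classes)


class TestCrossValidation:
    def test_loo_matches_brute_force_refits(self, rng):
        X, classes = make_separable(rng, n_per=5, k=2, p=8, noise=1.0)
        n = len(classes)
        q2 = cross_validate_q2(X, classes, 1, 0, n_folds=n)
        # brute force: refit with each single sample held out
        Y, _ = class_dummy(classes)
        press = 0.0
        for i in range(n):
            train = np.arange(n) != i
            m = fit_oplsda(X[train], classes[train], 1, 0, cv_folds=None)
            yhat = m.predict_scaled(m.scaler.transform(X[[i]])) + m.y_mean
            press += ((Y[i] - yhat) ** 2).sum()
        ss = ((Y - Y.mean(axis=0)) ** 2).sum()
        assert q2 == pytest.approx(1 - press / ss, rel=1e-10)

    def test_pure_noise_labels_give_nonpositive_q2_on_average(self, rng):
        q2s = []
        for _ in range(60):
            X = rng.normal(size=(14, 10))
            classes = rng.permutation(np.repeat(["a", "b"], 7))
            q2s.append(cross_validate_q2(X, classes, 1, 0, n_folds=7))
        assert np.mean(q2s) <= 0


class TestPermutation:
    def test_p_value_bounds_and_minimum_under_planted_separation(self, rng):
        X, classes = make_separable(rng, n_per=6, k=2, p=10)
        res = permutation_test(X, classes, 1, 0, n_perm=24, seed=3, cv_folds=6)
        assert res["p_q2"] == pytest.approx(1 / (res["n_perm"] + 1))
        assert 1 / (res["n_perm"] + 1) <= res["p_q2"] <= 1.0
        assert res["permuted"][:, 1].mean() < res["q2_obs"]

    def test_p_roughly_uniform_for_random_labels(self, rng):
        from scipy import stats

        ps = []
        for _ in range(25):
            X = rng.normal(size=(12, 8))
            classes = rng.permutation(np.repeat(["a", "b"], 6))
            res = permutation_test(X, classes, 1, 0, n_perm=19, seed=11, cv_folds=6)
            ps.append(res["p_q2"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestContributions:
    def test_class_exclusive_variable_ranks_top(self, rng):
        X, classes = make_separable(rng, n_per=6, k=3, p=12, noise=0.2)
        model = fit_oplsda(X, classes, 2, 0, cv_folds=None)
        contrib = variable_contributions(model, "c1", classes)
        assert model.scaler.kept[np.argmax(contrib)] == 1

    def test_flat_variable_contributes_nothing(self, rng):
        X, classes = make_separable(rng, n_per=6, k=2, p=6, noise=0.05)
        X[:, 4] = rng.normal(0, 0.05, len(classes))  # same in both classes
        model = fit_oplsda(X, classes, 1, 0, cv_folds=None)
        contrib = np.abs(variable_contributions(model, "c0", classes))
        col4 = np.flatnonzero(model.scaler.kept == 4)[0]
        assert contrib[col4] < 0.1 * contrib.max()

    def test_planted_markers_occupy_top_ranks_per_class(self, library):
        """With a fully shared background, only the planted markers carry
        class information, so they must fill the top contribution ranks."""
        from dataclasses import replace

        from oilmark.marker_discovery import fit_class_model
        from oilmark.pipeline import RunConfig, build_matrix
        from oilmark.synthetic_data import SimulationDesign, simulate_study

        design = replace(SimulationDesign(seed=5).noise_free(), background_share=1.0)
        samples, _ = simulate_study(design)
        matrix = build_matrix(samples, RunConfig(seed=5, design=design))
        model, cols = fit_class_model(matrix, cv_folds=None)
        w = matrix.consensus
        for oil in ["sunflower", "rapeseed", "sesame", "flax"]:
            markers = [m for m in library if m.oil == oil]
            contrib = variable_contributions(model, oil, matrix.classes[cols])
            full = np.full(matrix.n_consensus, -np.inf)
            full[model.scaler.kept] = contrib
            top = np.argsort(-full)[: len(markers)]
            top_mz = np.sort(w["mz_ref"].to_numpy()[top])
            np.testing.assert_allclose(
                top_mz, sorted(m.precursor_mz for m in markers), atol=2e-3
            )
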
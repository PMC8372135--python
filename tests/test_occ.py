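"""One-class distances against brute-force linear-algebra oracles."""

import numpy as np
import pytest

from evooscreen.errors import ConditioningError, ConfigError, SplitError
from evooscreen.factory import auroc
from evooscreen.occ import (
    Algorithm,
    OCCModelSpec,
    fit_knn_occ,
    fit_mahalanobis,
    fit_ocsvm,
    fit_pca_residual,
    fit_simca,
    inner_cv_select,
    knn_distance,
    maha_distance,
    make_estimator,
    ocsvm_distance,
    q_residual,
    simca_distance,
    train_occ_model,
)
from evooscreen.preprocess import PreprocessSpec
from evooscreen.spectra import Sensor


class TestSimca:
    def test_training_mean_has_zero_distance(self, rng):
        X = rng.normal(size=(20, 5))
        model = fit_simca(X, 2)
        assert simca_distance(model, X.mean(axis=0)) < 1e-10

    def test_rotation_equivariance(self, rng):
        X = rng.normal(size=(25, 6))
        x = rng.normal(size=6)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        d1 = simca_distance(fit_simca(X, 3), x)
        d2 = simca_distance(fit_simca(X @ Q, 3), x @ Q)
        assert abs(d1 - d2) < 1e-8 * max(d1, 1.0)

    def test_toy_matches_eigendecomposition_oracle(self):
        """2-D cross {(+-1,0),(0,+-eps)} with one component: reproduce q, h
        and the combined distance from an explicit eigendecomposition."""
        eps = 0.1
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, eps], [0.0, -eps]])
        model = fit_simca(X, 1)
        # oracle: mean is 0; covariance eigenvector with top eigenvalue
        cov = X.T @ X / (len(X) - 1)
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, np.argmax(vals)]
        T = X @ v
        svar = T.var(ddof=1)
        q_tr = ((X - np.outer(T, v)) ** 2).sum(axis=1)
        h_tr = T ** 2 / svar
        q0, h0 = q_tr.mean(), h_tr.mean()
        for x in (np.array([0.5, 0.3]), np.array([2.0, -1.0])):
            t = x @ v
            q = float(((x - t * v) ** 2).sum())
            h = float(t * t / svar)
            oracle = np.hypot(q / q0, h / h0)
            assert abs(simca_distance(model, x) - oracle) < 1e-10

    def test_component_bounds_enforced(self, rng):
        with pytest.raises(ConfigError):
            fit_simca(rng.normal(size=(5, 3)), 5)


class TestKnn:
    def test_training_point_k1_zero(self, rng):
        X = rng.normal(size=(10, 4))
        assert knn_distance(fit_knn_occ(X, 1), X[3]) == 0.0

    def test_k_equals_n_is_mean_to_all(self, rng):
        X = rng.normal(size=(8, 3))
        x = rng.normal(size=3)
        expected = np.linalg.norm(X - x, axis=1).mean()
        assert abs(knn_distance(fit_knn_occ(X, 8), x) - expected) < 1e-12

    def test_matches_sort_and_average_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        model = fit_knn_occ(X, 3)
        for _ in range(10):
            x = rng.normal(size=6)
            d = np.sort(np.linalg.norm(X - x, axis=1))[:3].mean()
            assert abs(knn_distance(model, x) - d) < 1e-12


class TestPcaResidual:
    def test_point_in_subspace_scores_zero(self, rng):
        X = rng.normal(size=(15, 4))
        model = fit_pca_residual(X, 2)
        x = model.mean_ + 0.7 * model.loadings_[:, 0] - 1.2 * model.loadings_[:, 1]
        assert q_residual(model, x) < 1e-18

    def test_full_rank_projection_annihilates(self, rng):
        X = rng.normal(size=(30, 4))
        model = fit_pca_residual(X, 4)
        for _ in range(5):
            assert q_residual(model, rng.normal(size=4)) < 1e-18

    def test_matches_projector_oracle(self, rng):
        X = rng.normal(size=(12, 3))
        model = fit_pca_residual(X, 1)
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, np.argmax(vals)]
        P = np.eye(3) - np.outer(v, v)
        for _ in range(10):
            x = rng.normal(size=3)
            oracle = float(np.sum((P @ (x - mu)) ** 2))
            assert abs(q_residual(model, x) - oracle) < 1e-12


class TestMahalanobis:
    def test_euclidean_case(self):
        # whitened 2-D data constructed directly: covariance exactly I
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        X = base * np.sqrt(3.0 / 2.0)    # ddof=1 covariance becomes I
        model = fit_mahalanobis(X, regularization=0.0, standardize=False)
        np.testing.assert_allclose(
            maha_distance(model, np.array([3.0, 4.0])), 5.0, rtol=1e-10
        )

    def test_center_scores_zero(self, rng):
        X = rng.normal(size=(30, 4))
        model = fit_mahalanobis(X)
        assert maha_distance(model, X.mean(axis=0)) < 1e-10

    def test_correlated_two_by_two_hand_inverse(self, rng):
        """cov [[2,1],[1,2]], x - mu = (1,1): d = sqrt(2/3) by explicit
        2x2 inversion."""
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        L = np.linalg.cholesky(cov)
        Z = rng.standard_normal((4000, 2)) @ L.T
        Z = (Z - Z.mean(axis=0))
        # rescale so the empirical ddof-1 covariance is exactly cov
        emp = np.cov(Z, rowvar=False)
        Z = Z @ np.linalg.inv(np.linalg.cholesky(emp)).T @ L.T
        model = fit_mahalanobis(Z, regularization=0.0, standardize=False)
        x = Z.mean(axis=0) + np.array([1.0, 1.0])
        assert abs(maha_distance(model, x) - np.sqrt(2.0 / 3.0)) < 1e-8

    def test_shrinkage_rescues_singular_covariance(self, rng):
        X = np.tile(rng.normal(size=(3, 10)), (4, 1))   # rank-deficient
        model = fit_mahalanobis(X, regularization=1e-3)
        assert np.isfinite(maha_distance(model, rng.normal(size=10)))


class TestOcsvm:
    def test_deep_inlier_scores_zero(self, rng):
        X = rng.normal(size=(60, 3))
        model = fit_ocsvm(X, nu=0.2)
        center = X.mean(axis=0)
        assert ocsvm_distance(model, center) == 0.0

    def test_far_outlier_scores_positive(self, rng):
        X = rng.normal(size=(50, 3))
        model = fit_ocsvm(X, nu=0.1)
        diam = np.linalg.norm(X.max(0) - X.min(0))
        assert ocsvm_distance(model, X.mean(0) + 20 * diam) > 0.0

    def test_nu_property_on_training(self, rng):
        X = rng.normal(size=(50, 4))
        model = fit_ocsvm(X, nu=0.1)
        flagged = np.mean(model.distance(X) > 0)
        assert flagged <= 0.1 + 0.07

    def test_identical_points_degenerate(self):
        with pytest.raises(ConditioningError):
            fit_ocsvm(np.ones((10, 3)), nu=0.1)


class TestDistanceContracts:
    @pytest.mark.parametrize("algo,hyper", [
        (Algorithm.SIMCA, {"n_components": 2}),
        (Algorithm.KNN, {"k_neighbors": 3}),
        (Algorithm.PCA_RESIDUAL, {"n_components": 2}),
        (Algorithm.MAHALANOBIS, {"regularization": 1e-3}),
        (Algorithm.OCSVM_RBF, {"nu": 0.1, "gamma": "auto"}),
    ])
    def test_nonnegative_finite_deterministic(self, algo, hyper, rng):
        X = rng.normal(size=(30, 5))
        Q = rng.normal(size=(15, 5))
        est = make_estimator(algo, **hyper).fit(X)
        d1, d2 = est.distance(Q), est.distance(Q)
        assert np.all(d1 >= 0) and np.all(np.isfinite(d1))
        np.testing.assert_array_equal(d1, d2)

    @pytest.mark.parametrize("algo,hyper", [
        (Algorithm.SIMCA, {"n_components": 2}),
        (Algorithm.KNN, {"k_neighbors": 3}),
        (Algorithm.PCA_RESIDUAL, {"n_components": 2}),
        (Algorithm.MAHALANOBIS, {"regularization": 1e-3}),
        (Algorithm.OCSVM_RBF, {"nu": 0.1, "gamma": "auto"}),
    ])
    def test_separability_on_shifted_gaussians(self, algo, hyper):
        """With >= 6 sigma mean separation every algorithm reaches AUROC
        0.99 on 500 points."""
        rng = np.random.default_rng(77)
        target = rng.normal(0.0, 1.0, size=(250, 4))
        adversary = rng.normal(6.0, 1.0, size=(250, 4))
        est = make_estimator(algo, **hyper).fit(target)
        a = auroc(est.distance(target), est.distance(adversary))
        assert a >= 0.99


class TestInnerCv:
    def _grouped_rank2(self, seed, n_samples=15, n_rep=6, p=30, noise=0.05):
        rng = np.random.default_rng(seed)
        basis = np.linalg.qr(rng.standard_normal((p, 2)))[0]
        rows, ids = [], []
        for i in range(n_samples):
            mu = basis @ (rng.standard_normal(2) * [3.0, 1.5])
            for _ in range(n_rep):
                rows.append(mu + noise * rng.standard_normal(p))
                ids.append(f"s{i}")
        return np.vstack(rows), np.array(ids)

    def test_single_candidate_returned_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        ids = np.repeat([f"s{i}" for i in range(10)], 3)
        out = inner_cv_select(Algorithm.KNN, X, ids, [{"k_neighbors": 4}])
        assert out == {"k_neighbors": 4}

    def test_noiseless_low_rank_structure_wins(self):
        X, ids = self._grouped_rank2(3, noise=0.0)
        cand = [{"n_components": k} for k in (1, 2, 3)]
        for algo in (Algorithm.SIMCA, Algorithm.PCA_RESIDUAL):
            out = inner_cv_select(algo, X, ids, cand, seed=0)
            assert out["n_components"] == 2

    def test_rank2_recovered_under_noise(self):
        """Across 100 seeded repeats, grouped CV picks the true rank for
        the Q-residual model in at least 90% of cases."""
        picks = []
        for seed in range(100):
            X, ids = self._grouped_rank2(seed)
            cand = [{"n_components": k} for k in (1, 2, 3, 4, 5)]
            out = inner_cv_select(Algorithm.PCA_RESIDUAL, X, ids, cand,
                                  seed=seed)
            picks.append(out["n_components"])
        assert np.mean(np.array(picks) == 2) >= 0.90

    def test_too_few_samples_raises(self, rng):
        X = rng.normal(size=(8, 3))
        ids = np.repeat(["a", "b", "c", "d"], 2)
        with pytest.raises(SplitError):
            inner_cv_select(Algorithm.KNN, X, ids,
                            [{"k_neighbors": 1}, {"k_neighbors": 2}])


class TestTrainedModel:
    def test_calibration_is_cross_validated(self, rng):
        """Calibrated distances must differ from resubstitution: a kNN-1
        model scores its own training points 0, but the grouped-CV
        calibration keeps each sample away from its own fit."""
        spec = OCCModelSpec(Sensor.FLUO, PreprocessSpec(("none",)),
                            Algorithm.KNN)
        ids = np.repeat([f"s{i}" for i in range(8)], 4)
        X = rng.normal(size=(32, 5))
        model = train_occ_model(spec, X, ids,
                                candidate_grid=[{"k_neighbors": 1}])
        assert np.all(model.calibration_distances > 0)
        assert model.threshold > model.calibration_distances.max()

    def test_spec_key_round_trip(self):
        spec = OCCModelSpec(Sensor.NIR, PreprocessSpec(("sg2",), split=4),
                            Algorithm.OCSVM_RBF)
        assert OCCModelSpec.from_key(spec.key) == spec
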
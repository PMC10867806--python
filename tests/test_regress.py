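"""Kernels, KRR, cross-validation, learning curves, synthetic targets."""

import numpy as np
import pytest
from sklearn.kernel_ridge import KernelRidge
from sklearn.metrics.pairwise import laplacian_kernel, rbf_kernel

from spahm import fixtures
from spahm.chemio import Molecule
from spahm.regress import CVConfig, cv_grid_search, kernel_matrix, krr_fit, \
    krr_predict, learning_curve, mae, synthetic_targets


class TestKernels:
    def test_unit_diagonal_and_scale_point(self, rng):
        x = rng.standard_normal((1, 4))
        assert kernel_matrix(x, x, "laplacian", 2.0)[0, 0] == 1.0
        y = x + np.array([[0.5, -0.5, 0.5, -0.5]])   # L1 distance = 2 = sigma
        assert abs(kernel_matrix(x, y, "laplacian", 2.0)[0, 0]
                   - np.exp(-1.0)) < 1e-12

    def test_matches_sklearn_pairwise(self, rng):
        X = rng.standard_normal((6, 5))
        Y = rng.standard_normal((4, 5))
        s = 1.7
        assert np.abs(kernel_matrix(X, Y, "laplacian", s)
                      - laplacian_kernel(X, Y, gamma=1.0 / s)).max() < 1e-12
        assert np.abs(kernel_matrix(X, Y, "gaussian", s)
                      - rbf_kernel(X, Y, gamma=1.0 / (2 * s * s))).max() \
            < 1e-12

    def test_gram_psd(self, rng):
        X = rng.standard_normal((10, 3))
        for kind in ("laplacian", "gaussian"):
            K = kernel_matrix(X, X, kind, 0.8)
            assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.eye(2), np.eye(2), "laplacian", 0.0)


class TestKRR:
    def test_interpolates_with_zero_regularization(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        y = np.array([1.0, -2.0])
        model = krr_fit(X, y, "gaussian", 1.0, 0.0)
        assert np.abs(krr_predict(model, X) - y).max() < 1e-8

    def test_large_regularization_shrinks_to_zero(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        y -= y.mean()
        model = krr_fit(X, y, "laplacian", 1.0, 1e6)
        assert np.abs(krr_predict(model, X)).max() < np.abs(y).max() / 1e3

    def test_weights_match_dense_inverse(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        model = krr_fit(X, y, "laplacian", 2.0, 1e-6)
        K = kernel_matrix(X, X, "laplacian", 2.0)
        w_ref = np.linalg.inv(K + 1e-6 * np.eye(20)) @ y
        assert np.abs(model.weights - w_ref).max() < 1e-8

    def test_matches_sklearn_kernel_ridge(self, rng):
        """Independent oracle: sklearn KernelRidge with the same kernel."""
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        Xt = rng.standard_normal((7, 4))
        s, eta = 1.3, 1e-4
        model = krr_fit(X, y, "gaussian", s, eta)
        ref = KernelRidge(alpha=eta, kernel="rbf", gamma=1.0 / (2 * s * s))
        ref.fit(X, y)
        assert np.abs(krr_predict(model, Xt) - ref.predict(Xt)).max() < 1e-8

    def test_predict_permutation_and_empty(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        model = krr_fit(X, y, "laplacian", 1.0, 1e-8)
        Xt = rng.standard_normal((5, 3))
        p = krr_predict(model, Xt)
        assert np.abs(krr_predict(model, Xt[::-1]) - p[::-1]).max() == 0.0
        assert krr_predict(model, np.zeros((0, 3))).size == 0


class TestGridSearch:
    def test_recovers_generating_width(self, rng):
        """y drawn exactly as a KRR function with width sigma*: CV picks a
        sigma within one grid step."""
        X = rng.standard_normal((60, 3))
        sigma_star = 4.0
        alpha = rng.standard_normal(60)
        y = kernel_matrix(X, X, "gaussian", sigma_star) @ alpha
        cfg = CVConfig(sigmas=np.logspace(-2, 6, 9, base=2.0),
                       etas=(1e-10, 1e-6), kernels=("gaussian",), seed=1)
        (kind, sigma, eta), table = cv_grid_search(X, y, cfg)
        assert kind == "gaussian"
        assert 0.5 <= sigma / sigma_star <= 2.0
        assert len(table) == 18

    def test_exact_ties_prefer_regularization(self, rng):
        """A zero target is fit exactly by every grid point (weights = 0,
        MAE = 0): the tie-break must pick the most regularized model."""
        X = rng.standard_normal((20, 2))
        y = np.zeros(20)
        cfg = CVConfig(sigmas=np.array([1.0, 2.0]), etas=(1e-10, 1e-4),
                       kernels=("laplacian",), seed=0)
        (_, sigma, eta), _ = cv_grid_search(X, y, cfg)
        assert (eta, sigma) == (1e-4, 2.0)

    def test_singleton_grid(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        cfg = CVConfig(sigmas=np.array([2.0]), etas=(1e-6,),
                       kernels=("laplacian",), seed=0)
        best, table = cv_grid_search(X, y, cfg)
        assert best == ("laplacian", 2.0, 1e-6) and len(table) == 1

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            cv_grid_search(np.eye(3), np.ones(3), CVConfig())


class TestLearningCurve:
    def test_monotone_trend_on_learnable_target(self, rng):
        X = rng.standard_normal((100, 3))
        alpha = rng.standard_normal(100)
        y = kernel_matrix(X, X, "gaussian", 3.0) @ alpha
        cfg = CVConfig(seed=2)
        curve = learning_curve(X, y, [5, 40, 80], cfg,
                               hyper=("gaussian", 3.0, 1e-10))
        assert curve["mean_mae"].iloc[-1] < curve["mean_mae"].iloc[0]

    def test_full_pool_subsamples_identical(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        cfg = CVConfig(seed=3)
        curve = learning_curve(X, y, [16], cfg, hyper=("laplacian", 1.0,
                                                       1e-8))
        assert curve["std_mae"].iloc[0] == 0.0

    def test_empty_sizes_and_oversize(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        cfg = CVConfig(seed=0)
        assert learning_curve(X, y, [], cfg).empty
        with pytest.raises(ValueError):
            learning_curve(X, y, [17], cfg, hyper=("laplacian", 1.0, 1e-8))


class TestSyntheticTargets:
    def test_isolated_atom_closed_form(self):
        mol = Molecule([6], [[0, 0, 0]], charge=1, multiplicity=2)
        df = synthetic_targets([mol], "charge_like", seed=0, noise=0.0)
        assert abs(df["value"].iloc[0] - (0.1 * 6 + 1.0 * 1)) < 1e-12

    def test_homonuclear_symmetry(self):
        mol = fixtures.molecule("h2")
        df = synthetic_targets([mol], "charge_like", seed=0, noise=0.0)
        assert abs(df["value"].iloc[0] - df["value"].iloc[1]) < 1e-12

    def test_determinism(self):
        mols = fixtures.random_molecules(5, seed=4)
        a = synthetic_targets(mols, "charge_like", seed=7)
        b = synthetic_targets(mols, "charge_like", seed=7)
        assert (a["value"].values == b["value"].values).all()

    def test_spin_like_zero_for_closed_shells(self):
        mols = [fixtures.molecule("h2o"), fixtures.molecule("ch3")]
        df = synthetic_targets(mols, "spin_like", seed=0, noise=0.0)
        closed = df[df.molecule_id == 0]["value"].values
        open_ = df[df.molecule_id == 1]["value"].values
        assert np.abs(closed).max() == 0.0
        assert np.abs(open_).max() > 0.0
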
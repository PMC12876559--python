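"""GP regression: feature enrichment, kernels, posterior, search."""

import numpy as np
import pytest

import stenoshape as ss
from stenoshape.constants import StateError
from stenoshape.regression import (DEFAULT_CONFIGS, _params_to_config,
                                   build_kernel, trials_to_frame)


class TestPolynomialEnrich:
    def test_degree_two_pair(self):
        out = ss.polynomial_enrich(np.array([2.0, 3.0]), 2)
        assert np.array_equal(out, [2, 3, 4, 9, 6])

    def test_degree_two_count_for_five_modes(self):
        out = ss.polynomial_enrich(np.arange(1.0, 6.0), 2)
        assert out.size == 5 + 5 + 10  # linear + squares + interactions

    def test_degree_one_identity(self):
        a = np.array([1.5, -2.0, 0.25])
        assert np.array_equal(ss.polynomial_enrich(a, 1), a)

    def test_degree_three_count(self):
        # d linear + d squares + C(d,2) pairs + C(d+2,3) cubics
        out = ss.polynomial_enrich(np.arange(1.0, 4.0), 3)
        assert out.size == 3 + 3 + 3 + 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.polynomial_enrich(np.array([]), 2)

    def test_row_matrix_consistent_with_vector(self):
        X = np.array([[1.0, 2.0], [0.5, -1.0]])
        out = ss.polynomial_enrich(X, 3)
        for i in range(2):
            assert np.array_equal(out[i], ss.polynomial_enrich(X[i], 3))


class TestKernelEval:
    def test_rbf_unit_diagonal_without_noise(self):
        cfg = ss.KernelConfig(family="RBF", c_scale=1.0, noise_var=1e-6,
                              noise_bounds=(1e-12, 1.0))
        X = np.array([[0.3, -0.2]])
        K = ss.kernel_eval(cfg, X, X)  # cross-covariance: no White term
        assert K[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_white_only_on_training_diagonal(self):
        cfg = ss.KernelConfig(family="RBF", c_scale=2.0, noise_var=0.5)
        X = np.array([[0.0], [1.0]])
        K_train = ss.kernel_eval(cfg, X)
        K_cross = ss.kernel_eval(cfg, X, X)
        assert np.allclose(np.diag(K_train) - np.diag(K_cross), 0.5)
        assert np.allclose(K_train - np.diag(np.diag(K_train)),
                           K_cross - np.diag(np.diag(K_cross)))

    def test_matern_half_equals_exponential(self):
        """nu = 1/2 reduces to C exp(-r/l) (the exponential kernel)."""
        cfg = ss.KernelConfig(family="Matern", nu=0.5, c_scale=1.0,
                              noise_var=1e-6)
        x = np.linspace(0, 3, 40)[:, None]
        K = ss.kernel_eval(cfg, x, np.zeros((1, 1)))
        expected = np.exp(-np.abs(x.ravel()))
        assert np.max(np.abs(K.ravel() - expected)) < 1e-12

    def test_matern_25_close_to_rbf_at_short_range(self):
        """nu = 5/2 approaches the squared-exponential at short range:
        within 5% up to r/l = 0.4, within 15% up to r/l = 1."""
        m = ss.KernelConfig(family="Matern", nu=2.5, c_scale=1.0,
                            noise_var=1e-6)
        r = ss.KernelConfig(family="RBF", c_scale=1.0, noise_var=1e-6)
        x = np.linspace(0, 1.0, 41)[:, None]
        Km = ss.kernel_eval(m, x, np.zeros((1, 1))).ravel()
        Kr = ss.kernel_eval(r, x, np.zeros((1, 1))).ravel()
        rel = np.abs(Km - Kr) / Kr
        assert np.max(rel[x.ravel() <= 0.4]) < 0.05
        assert np.max(rel) < 0.15

    def test_dimension_mismatch_rejected(self):
        cfg = ss.KernelConfig()
        with pytest.raises(ValueError):
            ss.kernel_eval(cfg, np.zeros((2, 3)), np.zeros((2, 2)))


def _toy_data(seed=0, n=10, d=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = 2.0 + X[:, 0] - 0.5 * X[:, 1] + 0.1 * X[:, 0] ** 2
    return X, y


class TestGPRFit:
    def test_interpolates_linear_target(self):
        X, _ = _toy_data(n=12)
        y = 3.0 + X @ np.array([1.0, -2.0]) + 5.0
        cfg = ss.KernelConfig(family="RBF", c_scale=10.0, noise_var=1e-10,
                              noise_bounds=(1e-12, 1e-8))
        model = ss.gpr_fit(X, y, cfg, ss.FeatureTransform(degree=1), seed=0)
        mu, _ = ss.gpr_predict(model, X)
        assert np.allclose(mu, y, rtol=1e-6, atol=1e-6)

    def test_duplicated_rows_regularized_by_white(self):
        X, y = _toy_data(n=8)
        Xd = np.vstack([X, X])
        yd = np.concatenate([y, y + 0.01])
        cfg = ss.KernelConfig(family="RBF", c_scale=1.0, noise_var=1e-2)
        model = ss.gpr_fit(Xd, yd, cfg, ss.FeatureTransform(), seed=0)
        assert model.trained

    def test_deterministic_for_fixed_seed(self):
        X, y = _toy_data(n=15)
        cfg = ss.KernelConfig(family="Matern", nu=1.5)
        m1 = ss.gpr_fit(X, y, cfg, ss.FeatureTransform(degree=2), seed=3)
        m2 = ss.gpr_fit(X, y, cfg, ss.FeatureTransform(degree=2), seed=3)
        p1, s1 = ss.gpr_predict(m1, X)
        p2, s2 = ss.gpr_predict(m2, X)
        assert np.array_equal(p1, p2) and np.array_equal(s1, s2)

    def test_log_transform_round_trip(self):
        tr = ss.FeatureTransform(log_target=True)
        y = np.array([0.5, 2.0, 100.0, 1e-3])
        assert np.allclose(tr.inverse_target(tr.transform_target(y)), y,
                           rtol=1e-12)


class TestGPRPredict:
    def test_posterior_matches_textbook_formulas(self):
        """Independent oracle: direct dense-solve GP posterior."""
        X, y = _toy_data(n=10)
        cfg = ss.KernelConfig(family="Matern", nu=1.5, c_scale=2.0,
                              noise_var=1e-2)
        tr = ss.FeatureTransform(degree=1, standardize=False)
        model = ss.gpr_fit(X, y, cfg, tr, seed=0, n_restarts=0)
        Xq = _toy_data(seed=5, n=4)[0]
        mu, sd = ss.gpr_predict(model, Xq)
        # brute force with the *fitted* kernel hyperparameters
        k = model.gpr.kernel_
        K = k(X)
        Ks = k(X, Xq)
        mu_bf = Ks.T @ np.linalg.solve(K, y)
        # predictive variance: self-similarity (incl. the noise term, the
        # convention of the trained regressor) minus the explained part
        var_bf = k.diag(Xq) - np.einsum(
            "ij,ij->j", Ks, np.linalg.solve(K, Ks))
        assert np.allclose(mu, mu_bf, atol=1e-8)
        assert np.allclose(sd, np.sqrt(var_bf), atol=1e-8)

    def test_variance_shrinks_at_training_points(self):
        X, y = _toy_data(n=10)
        cfg = ss.KernelConfig(family="RBF", c_scale=1.0, noise_var=1e-6)
        model = ss.gpr_fit(X, y, cfg, ss.FeatureTransform(), seed=0)
        _, sd_train = ss.gpr_predict(model, X)
        _, sd_far = ss.gpr_predict(model, X + 50.0)
        assert sd_train.max() < sd_far.min()

    def test_untrained_model_raises(self):
        model = ss.GPRModel(kernel=ss.KernelConfig(),
                            transform=ss.FeatureTransform(),
                            target_name="kv")
        with pytest.raises(StateError):
            ss.gpr_predict(model, np.zeros((1, 2)))


class TestSearch:
    def test_mse_hand_value(self):
        assert ss.mse([1.0, 2.0], [1.0, 3.0]) == 0.5

    def test_quadratic_target_prefers_degree_two(self):
        """On y = alpha_1^2 + noise, degree-2 trials dominate the winners."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] ** 2 + 0.01 * rng.normal(size=40)
        params, history = ss.hyperparameter_search(X, y, n_trials=12, k=4,
                                                   seed=2, sampler="random")
        frame = trials_to_frame(history).sort_values("cv_mse")
        top = frame.head(3)
        assert (top["degree"] >= 2).mean() >= 2 / 3
        assert params["degree"] >= 2

    def test_search_deterministic(self):
        X, y = _toy_data(n=12)
        p1, h1 = ss.hyperparameter_search(X, y, n_trials=4, k=3, seed=9)
        p2, h2 = ss.hyperparameter_search(X, y, n_trials=4, k=3, seed=9)
        assert p1 == p2
        assert [t.params for t in h1] == [t.params for t in h2]

    def test_tpe_improves_over_startup(self):
        """TPE proposals stay within the search space and produce finite
        objectives after the startup phase."""
        X, y = _toy_data(n=14)
        _, history = ss.hyperparameter_search(X, y, n_trials=12, k=3,
                                              seed=0, sampler="tpe")
        assert len(history) == 12
        for t in history:
            assert 1e-1 <= t.params["c_scale"] <= 1e5
            assert 1e-6 <= t.params["noise_var"] <= 1e1
            assert t.cv_mse >= 0 and not np.isnan(t.cv_mse)

    def test_k_larger_than_rows_rejected(self):
        X, y = _toy_data(n=4)
        with pytest.raises(ValueError):
            ss.hyperparameter_search(X, y, n_trials=1, k=10)

    def test_nu_present_iff_matern(self):
        X, y = _toy_data(n=12)
        _, history = ss.hyperparameter_search(X, y, n_trials=6, k=3, seed=4,
                                              sampler="random")
        for t in history:
            assert (t.params["family"] == "Matern") == \
                (t.params["nu"] is not None)


def test_default_configs_valid():
    for target, params in DEFAULT_CONFIGS.items():
        cfg, tr = _params_to_config({"nu": None, **params})
        assert build_kernel(cfg, 5 if tr.degree == 1 else 20) is not None
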
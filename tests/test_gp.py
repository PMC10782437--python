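"""ARD Matérn 5/2 Gaussian-process surrogate: kernel, posterior, marginal
likelihood, and fixed-noise hyperparameter fitting."""

import numpy as np
import pytest

from boselect.gp import (
    GPModel,
    KernelParams,
    fit_gp,
    gp_posterior,
    log_marginal_likelihood,
    matern52,
    matern52_gram,
)

SQRT5 = np.sqrt(5.0)


def brute_posterior(model, xs):
    """Independent dense linear-algebra posterior (no Cholesky reuse)."""
    K = matern52_gram(model.X, model.X, model.params) + model.noise_variance * np.eye(model.n)
    Kinv = np.linalg.inv(K)
    ks = matern52_gram(np.atleast_2d(xs), model.X, model.params)
    mean = model.mean_const + ks @ Kinv @ (model.y - model.mean_const)
    var = model.params.signal_variance - np.einsum("ij,jk,ik->i", ks, Kinv, ks)
    return mean, var


def brute_lml(model):
    K = matern52_gram(model.X, model.X, model.params) + model.noise_variance * np.eye(model.n)
    r = model.y - model.mean_const
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return -0.5 * r @ np.linalg.inv(K) @ r - 0.5 * logdet - 0.5 * model.n * np.log(2 * np.pi)


@pytest.fixture
def random_model():
    rng = np.random.default_rng(11)
    X = rng.uniform(0, 1, (30, 3))
    y = np.sin(4 * X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.standard_normal(30)
    params = KernelParams(lengthscales=np.array([0.3, 0.5, 0.8]), signal_variance=1.4)
    return GPModel(X, y, params, noise_variance=0.2, mean_const=float(y.mean()))


class TestKernel:
    def test_self_covariance_is_signal_variance(self):
        p = KernelParams(lengthscales=np.ones(4), signal_variance=2.5)
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert matern52(x, x, p) == pytest.approx(2.5, abs=1e-14)

    def test_unit_scaled_distance_value(self):
        p = KernelParams(lengthscales=np.ones(2), signal_variance=1.0)
        expected = (1 + SQRT5 + 5 / 3) * np.exp(-SQRT5)  # 0.52399
        assert matern52(np.zeros(2), np.array([1.0, 0.0]), p) == pytest.approx(
            expected, abs=1e-4
        )
        assert expected == pytest.approx(0.52399, abs=1e-4)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        p = KernelParams(lengthscales=rng.uniform(0.1, 1, 3), signal_variance=1.7)
        for _ in range(10):
            a, b = rng.uniform(0, 1, 3), rng.uniform(0, 1, 3)
            assert matern52(a, b, p) == pytest.approx(matern52(b, a, p), abs=1e-15)

    def test_dimension_mismatch_errors(self):
        p = KernelParams(lengthscales=np.ones(3))
        with pytest.raises(ValueError, match="dimension"):
            matern52(np.zeros(2), np.zeros(2), p)

    def test_gram_is_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (50, 4))
        p = KernelParams(lengthscales=rng.uniform(0.05, 1.0, 4), signal_variance=1.2)
        eigs = np.linalg.eigvalsh(matern52_gram(X, X, p))
        assert eigs.min() >= -1e-8


class TestPosterior:
    def test_matches_brute_force(self, random_model):
        rng = np.random.default_rng(1)
        xs = rng.uniform(0, 1, (30, 3))
        mean, var = gp_posterior(random_model, xs)
        bmean, bvar = brute_posterior(random_model, xs)
        assert np.max(np.abs(mean - bmean)) < 1e-8
        assert np.max(np.abs(var - bvar)) < 1e-8

    def test_prior_with_no_data(self):
        params = KernelParams(lengthscales=np.ones(2), signal_variance=1.5)
        m = GPModel(np.empty((0, 2)), np.empty(0), params, mean_const=0.3)
        mean, var = gp_posterior(m, np.array([0.5, 0.5]))
        assert mean == pytest.approx(0.3)
        assert var == pytest.approx(1.5)

    def test_single_point_closed_form(self):
        params = KernelParams(lengthscales=np.array([0.4]), signal_variance=1.0)
        x1, y1, mean_const, noise = np.array([[0.3]]), np.array([0.9]), 0.2, 0.2
        m = GPModel(x1, y1, params, noise_variance=noise, mean_const=mean_const)
        x = np.array([0.55])
        k = matern52(x, x1[0], params)
        expected = mean_const + k * (y1[0] - mean_const) / (1.0 + noise)
        mean, _ = gp_posterior(m, x)
        assert mean == pytest.approx(expected, abs=1e-10)

    def test_variance_bounded_by_prior(self, random_model):
        rng = np.random.default_rng(2)
        _, var = gp_posterior(random_model, rng.uniform(0, 1, (200, 3)))
        assert np.all(var <= random_model.params.signal_variance + 1e-10)
        assert np.all(var >= 0)

    def test_near_zero_noise_interpolates(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (20, 2))
        y = np.cos(3 * X[:, 0]) * X[:, 1]
        params = KernelParams(lengthscales=np.array([0.5, 0.5]), signal_variance=1.0)
        m = GPModel(X, y, params, noise_variance=1e-9, mean_const=float(y.mean()))
        mean, _ = gp_posterior(m, X)
        assert np.max(np.abs(mean - y)) < 1e-4

    def test_shrinkage_toward_data(self):
        # exact pointwise shrinkage holds for a single observation ...
        params = KernelParams(lengthscales=np.array([0.5]), signal_variance=1.0)
        m1 = GPModel(np.array([[0.4]]), np.array([1.3]), params,
                     noise_variance=0.2, mean_const=0.5)
        mean, _ = gp_posterior(m1, np.array([0.4]))
        assert abs(mean - 1.3) <= abs(1.3 - 0.5)
        assert (mean - 0.5) * (1.3 - 0.5) > 0  # moves toward the datum
        # ... and in aggregate for many observations
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (30, 2))
        y = np.sin(4 * X[:, 0]) + 0.1 * rng.standard_normal(30)
        m = GPModel(X, y, KernelParams(np.array([0.3, 0.5]), 1.4),
                    noise_variance=0.2, mean_const=float(y.mean()))
        mean, _ = gp_posterior(m, X)
        assert np.mean(np.abs(mean - y)) < np.mean(np.abs(y - m.mean_const))

    def test_agrees_with_sklearn_reference(self, random_model):
        """Independent cross-check against scikit-learn's GP regression."""
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        m = random_model
        kernel = ConstantKernel(m.params.signal_variance, "fixed") * Matern(
            length_scale=m.params.lengthscales, nu=2.5, length_scale_bounds="fixed"
        )
        gpr = GaussianProcessRegressor(
            kernel=kernel, alpha=m.noise_variance, optimizer=None
        ).fit(m.X, m.y - m.mean_const)
        xs = np.random.default_rng(4).uniform(0, 1, (25, 3))
        ref_mean, ref_sd = gpr.predict(xs, return_std=True)
        mean, var = gp_posterior(m, xs)
        assert np.max(np.abs(mean - (ref_mean + m.mean_const))) < 1e-8
        assert np.max(np.abs(np.sqrt(var) - ref_sd)) < 1e-6


class TestLogMarginalLikelihood:
    def test_matches_brute_force(self, random_model):
        assert log_marginal_likelihood(random_model) == pytest.approx(
            brute_lml(random_model), abs=1e-8
        )

    def test_single_point_closed_form(self):
        params = KernelParams(lengthscales=np.array([1.0]), signal_variance=1.0)
        m = GPModel(np.array([[0.5]]), np.array([0.7]), params, noise_variance=0.2,
                    mean_const=0.7)
        assert log_marginal_likelihood(m) == pytest.approx(
            -0.5 * np.log(2 * np.pi * 1.2), abs=1e-12
        )

    def test_permutation_invariant(self, random_model):
        perm = np.random.default_rng(6).permutation(random_model.n)
        shuffled = GPModel(
            random_model.X[perm], random_model.y[perm], random_model.params,
            random_model.noise_variance, random_model.mean_const,
        )
        assert log_marginal_likelihood(shuffled) == pytest.approx(
            log_marginal_likelihood(random_model), abs=1e-8
        )

    def test_drops_when_targets_shuffled(self):
        """Smooth targets fit better than the same values randomly permuted."""
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (60, 2))
            y = np.sin(4 * X[:, 0]) + np.cos(3 * X[:, 1])
            m = fit_gp(X, y, noise_variance=0.2, seed=seed)
            m_shuf = fit_gp(X, rng.permutation(y), noise_variance=0.2, seed=seed)
            deltas.append(log_marginal_likelihood(m_shuf) - log_marginal_likelihood(m))
        assert np.median(deltas) < 0


class TestFitGP:
    def test_fixed_noise_is_respected(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 2))
        y = np.sin(5 * X[:, 0]) + 0.1 * rng.standard_normal(40)
        m = fit_gp(X, y, noise_variance=0.3, seed=0)
        assert m.noise_variance == 0.3
        assert m.mean_const == pytest.approx(y.mean())

    def test_fit_beats_arbitrary_hyperparameters(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (50, 2))
        y = np.sin(5 * X[:, 0]) * np.cos(2 * X[:, 1])
        m = fit_gp(X, y, noise_variance=0.2, seed=1)
        fitted = log_marginal_likelihood(m)
        for ls in (0.05, 0.5, 5.0):
            other = GPModel(
                X, y, KernelParams(np.full(2, ls), 1.0), 0.2, float(y.mean())
            )
            assert fitted >= log_marginal_likelihood(other) - 1e-6

    def test_recovers_known_lengthscales(self):
        """Data from a known Matérn 5/2 GP: fitted lengthscales within a
        factor 2 of truth in >= 80% of seeds."""
        true = KernelParams(lengthscales=np.array([0.3, 0.3]), signal_variance=1.0)
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(0, 1, (200, 2))
            K = matern52_gram(X, X, true) + 1e-10 * np.eye(200)
            f = np.linalg.cholesky(K) @ rng.standard_normal(200)
            y = f + np.sqrt(0.2) * rng.standard_normal(200)
            m = fit_gp(X, y, noise_variance=0.2, seed=seed)
            ratios = m.params.lengthscales / true.lengthscales
            if np.all((ratios > 0.5) & (ratios < 2.0)):
                ok += 1
        assert ok >= 0.8 * n_seeds

    def test_duplicate_targets_lengthen_scales(self):
        """Returning cached scores at nearby points teaches longer
        lengthscales than independent noise would."""
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X_base = rng.uniform(0, 1, (30, 2))
            y_base = np.sin(4 * X_base[:, 0])
            # duplicates: same y repeated at jittered x (the caching effect)
            X_dup = np.vstack([X_base, X_base + rng.normal(0, 0.02, X_base.shape)])
            y_dup = np.r_[y_base, y_base]
            y_indep = np.r_[y_base, y_base + np.sqrt(0.2) * rng.standard_normal(30)]
            m_dup = fit_gp(X_dup, y_dup, noise_variance=0.2, seed=seed)
            m_ind = fit_gp(X_dup, y_indep, noise_variance=0.2, seed=seed)
            diffs.append(
                np.median(m_dup.params.lengthscales) - np.median(m_ind.params.lengthscales)
            )
        assert np.median(diffs) > 0

    def test_degenerate_targets_fall_back(self):
        X = np.random.default_rng(2).uniform(0, 1, (10, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_gp(X, np.full(10, 0.5), noise_variance=0.2, seed=0)
        assert m.params.signal_variance == 1.0

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_gp(np.array([[0.5]]), np.array([0.1]), seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (30, 2))
        y = rng.standard_normal(30)
        a = fit_gp(X, y, seed=42)
        b = fit_gp(X, y, seed=42)
        assert np.array_equal(a.params.lengthscales, b.params.lengthscales)
        assert a.params.signal_variance == b.params.signal_variance
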
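"""GP probit classifier: Laplace mode equations, oracles, posterior draws."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from marshniche.gp import (
    DegenerateResponseError,
    GaussianProcessProbitClassifier,
    KernelSpec,
)


def _frame(x):
    return pd.DataFrame({"x": np.atleast_1d(np.asarray(x, dtype=float))})


def _fit_1d(x, y, prior_mean_prob=0.5, **kw):
    est = GaussianProcessProbitClassifier(
        continuous_covariates=["x"], prior_mean_prob=prior_mean_prob, **kw
    )
    return est.fit(_frame(x), np.asarray(y))


class TestLaplaceMode:
    def test_single_presence_mode_solves_scalar_equation(self):
        # n = 1, K = 1 + jitter, zero prior mean: the stationarity condition
        # of the penalized likelihood is f = K * phi(f)/Phi(f)
        est = _fit_1d([0.0], [1])
        K = 1.0 + est.kernel_.jitter
        root = optimize.brentq(lambda f: f - K * norm.pdf(f) / norm.cdf(f), 0.0, 5.0)
        assert est.f_mode_[0] == pytest.approx(root, abs=1e-6)

    def test_label_flip_negates_mode_and_complements_probabilities(self):
        x = [0.0, 0.4, 0.9, 1.5, 2.1]
        y = np.array([1, 1, 0, 1, 0])
        a = _fit_1d(x, y)
        b = _fit_1d(x, 1 - y)
        np.testing.assert_allclose(a.f_mode_, -b.f_mode_, atol=1e-6)
        xs = _frame(np.linspace(-1, 3, 23))
        np.testing.assert_allclose(
            a.predict_probability(xs), 1 - b.predict_probability(xs), atol=1e-6
        )

    def test_all_one_class_rejected(self):
        with pytest.raises(DegenerateResponseError):
            _fit_1d([0.0, 1.0, 2.0], [1, 1, 1])

    def test_interpolation_on_separable_toy(self):
        est = _fit_1d([-1.0, -0.8, 0.8, 1.0], [0, 0, 1, 1])
        p = est.predict_probability(_frame([-0.9, 0.9]))
        assert p[0] < 0.5 < p[1]

    def test_reversion_to_prior_far_from_data(self):
        est = _fit_1d([0.0, 0.2, 0.4], [1, 0, 1], prior_mean_prob=0.5)
        assert est.predict_probability(_frame([500.0]))[0] == pytest.approx(0.5, abs=1e-6)
        est2 = _fit_1d([0.0, 0.2, 0.4, 0.6], [1, 0, 0, 0], prior_mean_prob=None)
        far = est2.predict_probability(_frame([500.0]))[0]
        # prevalence prior: far prediction reverts toward the base rate 0.25
        assert far == pytest.approx(ndtr(norm.ppf(0.25) / np.sqrt(2.0)), abs=1e-6)

    def test_duplicated_evidence_moves_prediction_toward_label(self):
        x, y = [0.0, 1.0, 2.0, 3.0], [0, 1, 0, 1]
        base = _fit_1d(x, y).predict_probability(_frame([1.0]))[0]
        more = _fit_1d(x + [1.0], y + [1]).predict_probability(_frame([1.0]))[0]
        assert more > base


class TestPredictiveIntegration:
    def test_two_point_toy_matches_quadrature(self):
        est = _fit_1d([0.0, 1.0], [1, 0])
        for xstar in (0.25, 0.5, 2.0):
            mu, var = est.latent_predictive(_frame([xstar]))
            oracle, _ = integrate.quad(
                lambda f: ndtr(f) * norm.pdf(f, mu[0], np.sqrt(var[0])), -12, 12
            )
            assert est.predict_probability(_frame([xstar]))[0] == pytest.approx(
                oracle, abs=1e-6
            )

    def test_predictive_variance_bounded_by_prior(self):
        est = _fit_1d([0.0, 0.5, 1.0, 1.5], [0, 1, 1, 0])
        _, var = est.latent_predictive(_frame(np.linspace(-2, 3, 31)))
        assert np.all(var >= est.kernel_.jitter)
        assert np.all(var <= est.kernel_.signal_variance + 1e-9)


def _mcmc_predictive(x_train, y_train, x_test, prior_mean=0.0, n_steps=4000, seed=0):
    """Long-run MCMC posterior predictive of the exact GP probit model.

    Samples the latent vector with emcee and averages the exact conditional
    predictive Phi(mu*(f) / sqrt(1 + v*)) over posterior draws.
    """
    import emcee

    est = GaussianProcessProbitClassifier(continuous_covariates=["x"], prior_mean_prob=0.5)
    est.fit(_frame(x_train), y_train)  # reuse kernel/scaling machinery
    K = est.K_train_
    cf = cho_factor(K, lower=True)
    y_pm = np.where(np.asarray(y_train) == 1, 1.0, -1.0)
    n = len(y_train)

    def log_post(f):
        quad = f @ cho_solve(cf, f)
        return float(log_ndtr(y_pm * (f + prior_mean)).sum() - 0.5 * quad)

    rng = np.random.default_rng(seed)
    nwalkers = 4 * n
    p0 = 0.1 * rng.standard_normal((nwalkers, n))
    sampler = emcee.EnsembleSampler(nwalkers, n, log_post)
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, 500, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False, thin_by=2)
    f_draws = sampler.get_chain(flat=True) + prior_mean

    Xc_test, cat_test = est._encode(_frame(x_test), training=False)
    Ks = est._kernel_matrix(est.kernel_, Xc_test, cat_test, est.Xc_train_, est.cat_train_)
    Kss = est._kernel_matrix(est.kernel_, Xc_test, cat_test)
    A = cho_solve(cf, Ks.T)  # n x n_test
    v = np.maximum(np.diag(Kss) - np.einsum("ij,ij->j", Ks.T, A), 1e-12)
    mu = prior_mean + (f_draws - prior_mean) @ A
    return ndtr(mu / np.sqrt(1.0 + v)).mean(axis=0), est


class TestAgainstMcmcOracle:
    def test_laplace_within_005_of_mcmc_on_small_designs(self):
        designs = [
            ([0.0, 1.0], [1, 0]),
            ([-1.0, -0.3, 0.3, 1.0], [0, 0, 1, 1]),
            ([0.0, 0.3, 0.6, 1.0, 1.4, 2.0], [1, 0, 1, 1, 0, 0]),
        ]
        for x_train, y_train in designs:
            x_test = np.linspace(min(x_train) - 0.5, max(x_train) + 0.5, 7)
            oracle, est = _mcmc_predictive(
                np.array(x_train), np.array(y_train), x_test, seed=42
            )
            laplace = est.predict_probability(_frame(x_test))
            assert np.max(np.abs(laplace - oracle)) <= 0.05


class TestPosteriorDraws:
    def test_draw_mean_converges_to_predictive_probability(self):
        est = _fit_1d([0.0, 1.0], [1, 0])
        xs = _frame([0.2, 0.8])
        n_draws = 100_000
        draws = est.sample_posterior_probabilities(xs, n_draws=n_draws, seed=0)
        analytic = est.predict_probability(xs)
        mc_se = draws.draws.std(axis=0) / np.sqrt(n_draws)
        assert np.all(np.abs(draws.mean() - analytic) <= 3 * mc_se)

    def test_same_seed_identical_draws(self):
        est = _fit_1d([0.0, 0.5, 1.0], [1, 0, 1])
        xs = _frame([0.1, 0.9])
        a = est.sample_posterior_probabilities(xs, n_draws=50, seed=5)
        b = est.sample_posterior_probabilities(xs, n_draws=50, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draws_strictly_inside_unit_interval(self):
        est = _fit_1d([0.0, 1.0], [1, 0])
        d = est.sample_posterior_probabilities(_frame([-50.0, 0.5, 50.0]), 500, seed=1)
        assert np.all((d.draws > 0) & (d.draws < 1))

    def test_too_few_draws_rejected(self):
        est = _fit_1d([0.0, 1.0], [1, 0])
        with pytest.raises(ValueError):
            est.sample_posterior_probabilities(_frame([0.5]), n_draws=1)

    def test_marginal_mode_matches_joint_marginally(self):
        est = _fit_1d([0.0, 0.5, 1.0, 1.5], [0, 1, 1, 0])
        xs = _frame(np.linspace(0, 1.5, 4))
        j = est.sample_posterior_probabilities(xs, 20_000, seed=2, joint=True)
        m = est.sample_posterior_probabilities(xs, 20_000, seed=3, joint=False)
        np.testing.assert_allclose(j.draws.mean(axis=0), m.draws.mean(axis=0), atol=0.02)


class TestAntisymmetryProperty:
    def test_probability_complement_under_label_flip(self):
        rng = np.random.default_rng(0)
        for trial in range(4):
            n = rng.integers(4, 12)
            x = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            a = _fit_1d(x, y)
            b = _fit_1d(x, 1 - y)
            xs = _frame(rng.normal(size=10, scale=2))
            np.testing.assert_allclose(
                a.predict_probability(xs) + b.predict_probability(xs),
                np.ones(10), atol=1e-6,
            )


class TestHyperparameterOptimization:
    def _synthetic(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.uniform(-2, 2, n), "b": rng.uniform(-2, 2, n)})
        latent = 1.0 - (X["a"] / 0.6) ** 2  # depends on 'a' only
        y = (rng.uniform(size=n) < ndtr(latent)).astype(int)
        return X, y

    def test_marginal_likelihood_never_decreases(self):
        X, y = self._synthetic(80, seed=1)
        init = KernelSpec.default(["a", "b"])
        fixed = GaussianProcessProbitClassifier(
            continuous_covariates=["a", "b"], kernel=init, optimize=False
        ).fit(X, y)
        tuned = GaussianProcessProbitClassifier(
            continuous_covariates=["a", "b"], kernel=init, optimize=True
        ).fit(X, y)
        assert tuned.log_marginal_likelihood_ >= fixed.log_marginal_likelihood_ - 1e-9

    def test_irrelevant_covariate_lengthscale_grows(self):
        X, y = self._synthetic(300, seed=2)
        tuned = GaussianProcessProbitClassifier(
            continuous_covariates=["a", "b"], optimize=True
        ).fit(X, y)
        assert tuned.kernel_.continuous_lengthscales["b"] >= 5.0

    def test_signal_lengthscale_recovered_within_factor_three(self):
        # generative bell width 0.6 raw units; lengthscales are in
        # standardized units (sd of U(-2,2) ~ 1.155)
        X, y = self._synthetic(300, seed=3)
        tuned = GaussianProcessProbitClassifier(
            continuous_covariates=["a"], optimize=True
        ).fit(X[["a"]], y)
        ls = tuned.kernel_.continuous_lengthscales["a"]
        target = 0.6 / X["a"].std()
        assert target / 3 <= ls <= target * 3


class TestCategoricalCovariates:
    def test_unknown_level_reverts_toward_prior(self, caplog):
        X = pd.DataFrame({"x": [0.0, 0.5, 1.0, 1.5], "g": ["u", "u", "v", "v"]})
        est = GaussianProcessProbitClassifier(
            continuous_covariates=["x"], categorical_covariates=["g"],
            prior_mean_prob=0.5,
        ).fit(X, [1, 1, 0, 0])
        Xn = pd.DataFrame({"x": [0.25], "g": ["w"]})
        with caplog.at_level("WARNING"):
            p_known = est.predict_probability(pd.DataFrame({"x": [0.25], "g": ["u"]}))[0]
            p_novel = est.predict_probability(Xn)[0]
        assert "unknown level" in caplog.text
        assert abs(p_novel - 0.5) < abs(p_known - 0.5)

    def test_levels_share_strength(self):
        # matching levels must be more similar than mismatching ones
        X = pd.DataFrame({"x": [0.0] * 4, "g": ["u", "u", "v", "v"]})
        est = GaussianProcessProbitClassifier(
            continuous_covariates=["x"], categorical_covariates=["g"],
        ).fit(X, [1, 0, 1, 0])
        Xc, cat = est._encode(X, training=False)
        K = est._kernel_matrix(est.kernel_, Xc, cat)
        assert K[0, 1] > K[0, 2] > 0


class TestSerialization:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        from marshniche.gp import load_model, save_model

        est = _fit_1d([0.0, 0.4, 0.9, 1.5], [1, 0, 1, 0])
        xs = _frame(np.linspace(-1, 3, 11))
        path = tmp_path / "model.json"
        save_model(est, path)
        again = load_model(path)
        np.testing.assert_allclose(
            est.predict_probability(xs), again.predict_probability(xs), atol=1e-12
        )
        d1 = est.sample_posterior_probabilities(xs, 30, seed=1).draws
        d2 = again.sample_posterior_probabilities(xs, 30, seed=1).draws
        np.testing.assert_allclose(d1, d2, atol=1e-12)
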
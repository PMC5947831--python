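"""Gaussian-process presence/absence model with probit link and Laplace inference.

The occurrence of a species in a quadrat is modelled through a latent
Gaussian field over environmental space (the quadrat x explanatory-variable
matrix): occurrence probability is ``Phi(f)`` for latent value ``f``, and
``f`` has a GP prior with constant mean and a squared-exponential kernel
over standardized continuous covariates, multiplied by a similarity term
for categorical covariates (identical levels contribute 1, differing levels
``exp(-1 / l_cat**2)`` so that levels share statistical strength).

Posterior inference over the latent field uses the Laplace approximation: a
Newton iteration locates the posterior mode and the curvature there gives a
Gaussian approximation, from which predictive probabilities, joint
posterior draws and the approximate log marginal likelihood all follow.
The "flat" (uninformative) latent prior is a constant mean at
``probit(prior_mean_prob)`` -- by default the training prevalence -- with
the kernel's stationary variance, so predictions revert to the base rate
far from the data.

The estimator follows the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``) and composes with sklearn model
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

#: Prediction-point count above which posterior draws fall back from the
#: joint Gaussian to independent marginals.
JOINT_DRAW_LIMIT = 2000


class DegenerateResponseError(ValueError):
    """Raised when the response vector contains a single class."""


@dataclass(frozen=True)
class KernelSpec:
    """Hyperparameters of the mixed continuous/categorical kernel.

    ``continuous_lengthscales`` are in standardized (z-score) units of each
    covariate.  Each categorical covariate contributes a multiplicative
    factor of 1 for matching levels and ``exp(-1 / l**2)`` otherwise.
    """

    continuous_lengthscales: dict[str, float]
    signal_variance: float = 1.0
    categorical_covariates: tuple[str, ...] = ()
    categorical_lengthscales: dict[str, float] = field(default_factory=dict)
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be strictly positive")
        for name, ls in self.continuous_lengthscales.items():
            if ls <= 0:
                raise ValueError(f"lengthscale for {name!r} must be strictly positive")
        object.__setattr__(
            self,
            "categorical_lengthscales",
            {
                c: self.categorical_lengthscales.get(c, 1.0)
                for c in self.categorical_covariates
            },
        )
        for name, ls in self.categorical_lengthscales.items():
            if ls <= 0:
                raise ValueError(f"lengthscale for {name!r} must be strictly positive")

    @classmethod
    def default(cls, continuous, categorical=(), jitter: float = 1e-6) -> "KernelSpec":
        """Unit lengthscales and unit signal variance (the fixed-default mode)."""
        return cls(
            continuous_lengthscales={c: 1.0 for c in continuous},
            signal_variance=1.0,
            categorical_covariates=tuple(categorical),
            jitter=jitter,
        )


@dataclass(frozen=True)
class PosteriorDrawSet:
    """Monte-Carlo draws of occurrence probability at prediction points.

    ``draws`` has shape (n_draws, n_points); every entry lies strictly in
    (0, 1).
    """

    draws: np.ndarray
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


def _probit_moments(y_pm: np.ndarray, f: np.ndarray):
    """Log-likelihood, gradient and negative Hessian diag of the probit model.

    ``y_pm`` is the response coded +-1.  Uses ``log_ndtr`` for stable tails.
    """
    z = y_pm * f
    log_lik = log_ndtr(z)
    ratio = np.exp(norm.logpdf(z) - log_ndtr(z))  # phi(z)/Phi(z)
    grad = y_pm * ratio
    w = ratio * (ratio + z)  # -d2/df2 log Phi(y f); >= 0 for the probit
    return log_lik.sum(), grad, np.maximum(w, 1e-12)


class GaussianProcessProbitClassifier(ClassifierMixin, BaseEstimator):
    """GP binary classifier: probit link, Laplace approximation, mixed kernel.

    Parameters
    ----------
    continuous_covariates : sequence of str, optional
        Columns of ``X`` treated as continuous (standardized on fit).  When
        None, numeric columns are used.
    categorical_covariates : sequence of str, optional
        Columns treated as categorical factors.  When None, non-numeric
        columns are used.
    kernel : KernelSpec, optional
        Initial kernel hyperparameters; defaults to unit lengthscales and
        unit variance over the selected covariates.
    prior_mean_prob : float, optional
        Prior occurrence probability defining the constant latent prior
        mean ``probit(prior_mean_prob)``.  None (default) uses the training
        prevalence; 0.5 gives a zero-mean latent prior.
    optimize : bool
        Maximize the Laplace log marginal likelihood over lengthscales and
        signal variance (bounded local search from ``kernel``).  The fitted
        kernel never has lower marginal likelihood than the initial one.
    max_iter, tol : Newton-iteration controls for the posterior mode.
    jitter : float
        Diagonal nugget added to the training kernel matrix.

    Attributes
    ----------
    kernel_ : KernelSpec
        Hyperparameters actually used (post-optimization).
    f_mode_ : ndarray
        Latent posterior mode at the training points.
    log_marginal_likelihood_ : float
    converged_ : bool
    prior_mean_latent_ : float
    classes_ : ndarray of [0, 1]
    """

    def __init__(
        self,
        continuous_covariates=None,
        categorical_covariates=None,
        kernel: KernelSpec | None = None,
        prior_mean_prob: float | None = None,
        optimize: bool = False,
        max_iter: int = 100,
        tol: float = 1e-8,
        jitter: float = 1e-6,
    ):
        self.continuous_covariates = continuous_covariates
        self.categorical_covariates = categorical_covariates
        self.kernel = kernel
        self.prior_mean_prob = prior_mean_prob
        self.optimize = optimize
        self.max_iter = max_iter
        self.tol = tol
        self.jitter = jitter

    # ------------------------------------------------------------------ #
    # covariate handling

    def _resolve_columns(self, X: pd.DataFrame):
        if self.continuous_covariates is None and self.categorical_covariates is None:
            cont = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
            cat = [c for c in X.columns if c not in cont]
        else:
            cont = list(self.continuous_covariates or [])
            cat = list(self.categorical_covariates or [])
        missing = [c for c in cont + cat if c not in X.columns]
        if missing:
            raise ValueError(f"covariate column(s) not in X: {missing}")
        return cont, cat

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def _encode(self, X: pd.DataFrame, training: bool):
        """Standardized continuous matrix and integer-coded categorical matrix."""
        Xc = X[self.continuous_covariates_].to_numpy(dtype=float)
        if not np.all(np.isfinite(Xc)):
            raise ValueError("continuous covariates must be finite and complete")
        if training:
            self.X_mean_ = Xc.mean(axis=0)
            sd = Xc.std(axis=0, ddof=0)
            self.X_sd_ = np.where(sd > 0, sd, 1.0)
        Xc = (Xc - self.X_mean_) / self.X_sd_
        cat = np.zeros((len(X), len(self.categorical_covariates_)), dtype=int)
        for j, c in enumerate(self.categorical_covariates_):
            col = X[c].astype(str).to_numpy()
            if training:
                self.categories_.setdefault(c, list(dict.fromkeys(col)))
            levels = {lv: i for i, lv in enumerate(self.categories_[c])}
            codes = np.array([levels.get(v, -1) for v in col])
            if not training and (codes == -1).any():
                novel = sorted(set(col[codes == -1]))
                logger.warning(
                    "unknown level(s) %s for covariate %r: treated as matching "
                    "no training level",
                    novel, c,
                )
                # distinct negative codes so novel levels also mismatch each other
                for k, lv in enumerate(novel):
                    codes[col == lv] = -(k + 1)
            cat[:, j] = codes
        return Xc, cat

    def _kernel_matrix(self, spec: KernelSpec, Ac, Acat, Bc=None, Bcat=None):
        if Bc is None:
            Bc, Bcat = Ac, Acat
        ls = np.array(
            [spec.continuous_lengthscales[c] for c in self.continuous_covariates_]
        )
        sq = cdist(Ac / ls, Bc / ls, metric="sqeuclidean") if ls.size else np.zeros(
            (len(Ac), len(Bc))
        )
        K = spec.signal_variance * np.exp(-0.5 * sq)
        for j, c in enumerate(self.categorical_covariates_):
            lcat = spec.categorical_lengthscales[c]
            mism = Acat[:, j][:, None] != Bcat[:, j][None, :]
            K = K * np.where(mism, np.exp(-1.0 / lcat**2), 1.0)
        return K

    # ------------------------------------------------------------------ #
    # Laplace machinery

    def _laplace(self, spec: KernelSpec, K: np.ndarray, y_pm: np.ndarray, m: float):
        """Newton iteration for the latent posterior mode (prior mean m).

        Returns (f_mode, grad, W, L, a, log_marginal_likelihood, converged).
        """
        n = len(y_pm)
        f = np.full(n, m)
        obj_old = -np.inf
        a = np.zeros(n)
        converged = False
        for _ in range(self.max_iter):
            ll, grad, W = _probit_moments(y_pm, f)
            sW = np.sqrt(W)
            B = np.eye(n) + sW[:, None] * K * sW[None, :]
            L = cholesky(B, lower=True)
            b = W * (f - m) + grad
            a = b - sW * cho_solve((L, True), sW * (K @ b))
            f = m + K @ a
            ll_new = log_ndtr(y_pm * f).sum()
            obj = -0.5 * a @ (f - m) + ll_new
            if abs(obj - obj_old) < self.tol:
                converged = True
                break
            obj_old = obj
        ll, grad, W = _probit_moments(y_pm, f)
        sW = np.sqrt(W)
        B = np.eye(n) + sW[:, None] * K * sW[None, :]
        L = cholesky(B, lower=True)
        lml = -0.5 * a @ (f - m) + ll - np.log(np.diag(L)).sum()
        return f, grad, W, L, a, lml, converged

    def _lml_for(self, spec: KernelSpec) -> float:
        K = self._kernel_matrix(spec, self.Xc_train_, self.cat_train_)
        K = K + spec.jitter * np.eye(len(K))
        try:
            *_, lml, conv = self._laplace(spec, K, self.y_pm_, self.prior_mean_latent_)
        except np.linalg.LinAlgError:
            return -np.inf
        return lml if np.isfinite(lml) else -np.inf

    def _optimize_kernel(self, initial: KernelSpec) -> KernelSpec:
        """Bounded local maximization of the Laplace log marginal likelihood.

        Optimizes log lengthscales (continuous and categorical) and log
        signal variance; on any optimizer failure, or if no improvement is
        found, returns the initial spec.
        """
        cont = self.continuous_covariates_
        cats = self.categorical_covariates_

        def build(theta):
            i = 0
            ls = {c: float(np.exp(theta[i + j])) for j, c in enumerate(cont)}
            i += len(cont)
            var = float(np.exp(theta[i]))
            i += 1
            cls_ = {c: float(np.exp(theta[i + j])) for j, c in enumerate(cats)}
            return replace(
                initial,
                continuous_lengthscales=ls,
                signal_variance=var,
                categorical_lengthscales=cls_,
            )

        theta0 = np.concatenate(
            [
                np.log([initial.continuous_lengthscales[c] for c in cont]),
                [np.log(initial.signal_variance)],
                np.log([initial.categorical_lengthscales[c] for c in cats]),
            ]
        )
        bounds = (
            [(np.log(0.05), np.log(100.0))] * len(cont)
            + [(np.log(0.01), np.log(100.0))]
            + [(np.log(0.1), np.log(100.0))] * len(cats)
        )

        def neg_lml(theta):
            return -self._lml_for(build(theta))

        lml0 = self._lml_for(initial)
        try:
            res = optimize.minimize(
                neg_lml,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxfun": 60, "eps": 1e-3},
            )
            candidate = build(res.x)
            if -res.fun > lml0:
                return candidate
        except Exception as exc:  # noqa: BLE001 -- optimizer failure is non-fatal
            logger.warning("hyperparameter optimization failed (%s); keeping initial", exc)
        return initial

    # ------------------------------------------------------------------ #
    # sklearn surface

    def fit(self, X, y):
        """Fit the Laplace-approximated GP to presences/absences.

        ``X`` is a quadrat x variable table (DataFrame or array); ``y`` is
        binary 0/1.  Requires at least one presence and one absence.
        """
        X = self._as_frame(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1, True, False}:
            raise ValueError("y must be binary 0/1")
        y = y.astype(int)
        if len(y) > 1 and y.min() == y.max():
            raise DegenerateResponseError(
                "response contains a single class; need >=1 presence and >=1 absence"
            )
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")

        cont, cat = self._resolve_columns(X)
        self.continuous_covariates_ = cont
        self.categorical_covariates_ = cat
        self.categories_ = {}
        self.Xc_train_, self.cat_train_ = self._encode(X, training=True)
        self.y_pm_ = np.where(y == 1, 1.0, -1.0)
        self.classes_ = np.array([0, 1])

        prevalence = y.mean()
        p0 = prevalence if self.prior_mean_prob is None else self.prior_mean_prob
        p0 = float(np.clip(p0, 1e-6, 1 - 1e-6))
        self.prior_mean_latent_ = float(norm.ppf(p0))

        spec = self.kernel or KernelSpec.default(cont, cat, jitter=self.jitter)
        if self.optimize:
            spec = self._optimize_kernel(spec)
        self.kernel_ = spec

        K = self._kernel_matrix(spec, self.Xc_train_, self.cat_train_)
        K = K + spec.jitter * np.eye(len(K))
        f, grad, W, L, a, lml, converged = self._laplace(
            spec, K, self.y_pm_, self.prior_mean_latent_
        )
        self.K_train_ = K
        self.f_mode_ = f
        self.grad_mode_ = grad
        self.W_ = W
        self.L_ = L
        self.log_marginal_likelihood_ = float(lml)
        self.converged_ = bool(converged)
        if not converged:
            logger.warning("Newton iteration did not converge in %d steps", self.max_iter)
        return self

    def _check_fitted(self):
        if not hasattr(self, "f_mode_"):
            raise RuntimeError("model is not fitted")

    def latent_predictive(self, X, full_cov: bool = False):
        """Laplace predictive mean and (co)variance of the latent field.

        Returns ``(mu, var)`` with marginal variances, or ``(mu, cov)``
        when ``full_cov``.
        """
        self._check_fitted()
        X = self._as_frame(X)
        Xc, cat = self._encode(X, training=False)
        Ks = self._kernel_matrix(self.kernel_, Xc, cat, self.Xc_train_, self.cat_train_)
        mu = self.prior_mean_latent_ + Ks @ self.grad_mode_
        sW = np.sqrt(self.W_)
        V = solve_triangular(self.L_, sW[:, None] * Ks.T, lower=True)
        if full_cov:
            Kss = self._kernel_matrix(self.kernel_, Xc, cat)
            cov = Kss - V.T @ V
            return mu, cov
        kss = np.full(len(X), self.kernel_.signal_variance)
        var = np.maximum(kss - np.einsum("ij,ij->j", V, V), self.kernel_.jitter)
        return mu, var

    def predict_proba(self, X):
        """Posterior predictive occurrence probabilities, shape (n, 2).

        The positive-class column is ``Phi(mu / sqrt(1 + var))`` with the
        Laplace latent predictive moments; far from the training data it
        reverts to ``Phi(prior_mean_latent_)``.
        """
        mu, var = self.latent_predictive(X)
        p = ndtr(mu / np.sqrt(1.0 + var))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.column_stack([1 - p, p])

    def predict_probability(self, X) -> np.ndarray:
        """Positive-class probabilities as a flat vector."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_probability(X) >= 0.5).astype(int)

    def sample_posterior_probabilities(
        self, X, n_draws: int = 1000, seed=None, joint: bool | None = None
    ) -> PosteriorDrawSet:
        """Draw occurrence probabilities from the Laplace posterior.

        Latent values are drawn from the joint Gaussian approximation over
        the prediction points (independent marginals above
        ``JOINT_DRAW_LIMIT`` points, or as requested via ``joint``) and
        mapped through the probit link.  Deterministic given ``seed``.
        """
        if n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        self._check_fitted()
        X = self._as_frame(X)
        n_points = len(X)
        if joint is None:
            joint = n_points <= JOINT_DRAW_LIMIT
            if not joint:
                logger.info(
                    "%d prediction points > %d: drawing independent marginals",
                    n_points, JOINT_DRAW_LIMIT,
                )
        rng = np.random.default_rng(seed)
        if joint:
            mu, cov = self.latent_predictive(X, full_cov=True)
            cov = cov + self.kernel_.jitter * np.eye(n_points)
            Lc = cholesky(cov, lower=True)
            z = rng.standard_normal((n_draws, n_points))
            latent = mu[None, :] + z @ Lc.T
        else:
            mu, var = self.latent_predictive(X)
            latent = mu[None, :] + rng.standard_normal((n_draws, n_points)) * np.sqrt(
                var
            )[None, :]
        draws = np.clip(ndtr(latent), 1e-12, 1 - 1e-12)
        return PosteriorDrawSet(draws=draws, seed=seed)


def save_model(est: GaussianProcessProbitClassifier, path) -> None:
    """Serialize a fitted model to a keyed JSON text file.

    Stores the kernel hyperparameters, covariate scaling, categorical level
    maps and the Laplace state (training covariates, latent mode, gradient,
    curvature) -- everything prediction needs.
    """
    import json

    est._check_fitted()
    state = {
        "continuous_covariates": est.continuous_covariates_,
        "categorical_covariates": est.categorical_covariates_,
        "categories": est.categories_,
        "kernel": {
            "continuous_lengthscales": est.kernel_.continuous_lengthscales,
            "signal_variance": est.kernel_.signal_variance,
            "categorical_covariates": list(est.kernel_.categorical_covariates),
            "categorical_lengthscales": est.kernel_.categorical_lengthscales,
            "jitter": est.kernel_.jitter,
        },
        "X_mean": est.X_mean_.tolist(),
        "X_sd": est.X_sd_.tolist(),
        "Xc_train": est.Xc_train_.tolist(),
        "cat_train": est.cat_train_.tolist(),
        "prior_mean_latent": est.prior_mean_latent_,
        "f_mode": est.f_mode_.tolist(),
        "grad_mode": est.grad_mode_.tolist(),
        "W": est.W_.tolist(),
        "L": est.L_.tolist(),
        "log_marginal_likelihood": est.log_marginal_likelihood_,
        "converged": est.converged_,
    }
    with open(path, "w") as fh:
        json.dump(state, fh)


def load_model(path) -> GaussianProcessProbitClassifier:
    """Rebuild a fitted model from :func:`save_model` output."""
    import json

    with open(path) as fh:
        state = json.load(fh)
    kern = state["kernel"]
    est = GaussianProcessProbitClassifier(
        continuous_covariates=state["continuous_covariates"],
        categorical_covariates=state["categorical_covariates"],
        kernel=KernelSpec(
            continuous_lengthscales=kern["continuous_lengthscales"],
            signal_variance=kern["signal_variance"],
            categorical_covariates=tuple(kern["categorical_covariates"]),
            categorical_lengthscales=kern["categorical_lengthscales"],
            jitter=kern["jitter"],
        ),
    )
    est.continuous_covariates_ = state["continuous_covariates"]
    est.categorical_covariates_ = state["categorical_covariates"]
    est.categories_ = state["categories"]
    est.kernel_ = est.kernel
    est.X_mean_ = np.asarray(state["X_mean"])
    est.X_sd_ = np.asarray(state["X_sd"])
    est.Xc_train_ = np.asarray(state["Xc_train"])
    est.cat_train_ = np.asarray(state["cat_train"], dtype=int)
    est.prior_mean_latent_ = state["prior_mean_latent"]
    est.f_mode_ = np.asarray(state["f_mode"])
    est.grad_mode_ = np.asarray(state["grad_mode"])
    est.W_ = np.asarray(state["W"])
    est.L_ = np.asarray(state["L"])
    est.log_marginal_likelihood_ = state["log_marginal_likelihood"]
    est.converged_ = state["converged"]
    est.classes_ = np.array([0, 1])
    return est


def optimize_hyperparameters(X, y, initial: KernelSpec, **fit_kwargs) -> KernelSpec:
    """Maximize the Laplace log marginal likelihood starting from ``initial``.

    Convenience wrapper returning the optimized :class:`KernelSpec`; never
    returns a spec with lower marginal likelihood than the initial one.
    """
    est = GaussianProcessProbitClassifier(
        kernel=initial,
        continuous_covariates=list(initial.continuous_lengthscales),
        categorical_covariates=list(initial.categorical_covariates),
        optimize=True,
        **fit_kwargs,
    )
    est.fit(X, y)
    return est.kernel_
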
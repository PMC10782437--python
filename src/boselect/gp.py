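"""Gaussian-process surrogate with an ARD Matérn 5/2 kernel and fixed noise.

The surrogate models the selectivity objective over the unit hypercube.
Two modelling choices are deliberate:

* the observation-noise variance is *fixed* (default 0.2), never estimated:
  because duplicate molecule proposals return cached scores, a maximum-
  likelihood noise estimate would collapse toward zero and the process
  would overfit repeated observations;
* one lengthscale per input dimension (automatic relevance determination),
  fitted together with the signal variance by maximizing the log marginal
  likelihood with multi-restart L-BFGS-B using analytic gradients.

The prior mean is the constant mean of the observations: scores live in
[0, 1], so a zero prior mean would systematically inflate expected
improvement far from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.optimize import minimize

__all__ = [
    "KernelParams",
    "GPModel",
    "matern52",
    "matern52_gram",
    "fit_gp",
    "gp_posterior",
    "log_marginal_likelihood",
]

SQRT5 = np.sqrt(5.0)

#: Lengthscale bounds in hypercube units; prevents degenerate fits.
LENGTHSCALE_BOUNDS = (1e-3, 10.0)
SIGNAL_VARIANCE_BOUNDS = (1e-6, 100.0)

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class KernelParams:
    """ARD Matérn 5/2 hyperparameters: per-dimension lengthscales and a
    signal variance."""

    lengthscales: np.ndarray
    signal_variance: float = 1.0

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        object.__setattr__(self, "lengthscales", ls)
        if np.any(ls <= 0) or self.signal_variance <= 0:
            raise ValueError("lengthscales and signal variance must be positive")


def _scaled_dist(X1: np.ndarray, X2: np.ndarray, params: KernelParams) -> np.ndarray:
    ls = params.lengthscales
    if X1.shape[-1] != ls.shape[0] or X2.shape[-1] != ls.shape[0]:
        raise ValueError(
            f"dimension mismatch: inputs have {X1.shape[-1]}/{X2.shape[-1]} dims, "
            f"kernel has {ls.shape[0]} lengthscales"
        )
    diff = (X1[:, None, :] - X2[None, :, :]) / ls
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def _matern52_of_dist(d: np.ndarray, signal_variance: float) -> np.ndarray:
    return signal_variance * (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * np.exp(-SQRT5 * d)


def matern52(x: np.ndarray, x2: np.ndarray, params: KernelParams) -> float:
    """Matérn 5/2 covariance between two points:
    ``sigma^2 * (1 + sqrt5*d + 5/3*d^2) * exp(-sqrt5*d)`` with ``d`` the
    lengthscale-scaled Euclidean distance."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    d = _scaled_dist(x[None, :], x2[None, :], params)[0, 0]
    return float(_matern52_of_dist(np.asarray(d), params.signal_variance))


def matern52_gram(X1: np.ndarray, X2: np.ndarray, params: KernelParams) -> np.ndarray:
    """Cross-covariance matrix between two point sets."""
    return _matern52_of_dist(_scaled_dist(X1, X2, params), params.signal_variance)


@dataclass
class GPModel:
    """Fitted GP state: training inputs in the hypercube, observed scores,
    kernel hyperparameters, fixed noise variance, constant prior mean."""

    X: np.ndarray
    y: np.ndarray
    params: KernelParams
    noise_variance: float = 0.2
    mean_const: float = 0.0
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def factorize(self) -> tuple[np.ndarray, np.ndarray]:
        """Cholesky of the noisy Gram matrix and the weight vector
        ``alpha = K^{-1} (y - mean)``, cached; jitter escalates on failure."""
        if self._chol is None:
            K = matern52_gram(self.X, self.X, self.params)
            K[np.diag_indices_from(K)] += self.noise_variance
            last_err: Exception | None = None
            for jitter in _JITTERS:
                try:
                    L = linalg.cholesky(K + jitter * np.eye(self.n), lower=True)
                    break
                except linalg.LinAlgError as err:  # pragma: no cover - rare
                    last_err = err
            else:  # pragma: no cover
                raise linalg.LinAlgError(
                    "Gram matrix not positive definite after jitter escalation"
                ) from last_err
            self._chol = L
            self._alpha = linalg.cho_solve((L, True), self.y - self.mean_const)
        return self._chol, self._alpha

    def with_data(self, X: np.ndarray, y: np.ndarray) -> "GPModel":
        """Same hyperparameters, new data (mean reset to mean(y))."""
        y = np.asarray(y, dtype=float).ravel()
        return GPModel(
            X=X,
            y=y,
            params=self.params,
            noise_variance=self.noise_variance,
            mean_const=float(y.mean()) if y.size else 0.0,
        )


def gp_posterior(
    model: GPModel, x: np.ndarray, full_cov: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at one point or a batch of points.

    Observation noise enters the Gram matrix only, so the returned variance
    is that of the latent function, not of a noisy observation.  With no
    training data the prior ``(mean_const, signal_variance)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = np.atleast_2d(x)
    sv = model.params.signal_variance
    if model.n == 0:
        mean = np.full(Xs.shape[0], model.mean_const)
        var = np.full(Xs.shape[0], sv)
    else:
        L, alpha = model.factorize()
        Ks = matern52_gram(Xs, model.X, model.params)
        mean = model.mean_const + Ks @ alpha
        V = linalg.solve_triangular(L, Ks.T, lower=True)
        var = np.maximum(sv - np.einsum("ij,ij->j", V, V), 0.0)
    if single:
        return float(mean[0]), float(var[0])
    return mean, var


def log_marginal_likelihood(model: GPModel) -> float:
    """Gaussian log marginal likelihood of the observations under the model
    (fixed noise in the Gram matrix)."""
    if model.n < 1:
        raise ValueError("need at least one observation")
    L, alpha = model.factorize()
    r = model.y - model.mean_const
    return float(
        -0.5 * r @ alpha - np.log(np.diag(L)).sum() - 0.5 * model.n * np.log(2 * np.pi)
    )


def _nll_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    r: np.ndarray,
    noise_variance: float,
) -> tuple[float, np.ndarray]:
    """Negative LML and gradient w.r.t. log-lengthscales and log-signal-variance.

    Uses d(LML)/d(theta_j) = 0.5 * tr((alpha alpha^T - K^{-1}) dK/d(theta_j)).
    """
    n, dim = X.shape
    ls = np.exp(theta[:dim])
    sv = np.exp(theta[dim])
    params = KernelParams(lengthscales=ls, signal_variance=sv)
    D = _scaled_dist(X, X, params)
    K = _matern52_of_dist(D, sv)
    Kn = K.copy()
    Kn[np.diag_indices_from(Kn)] += noise_variance
    try:
        L = linalg.cholesky(Kn, lower=True)
    except linalg.LinAlgError:
        Kn[np.diag_indices_from(Kn)] += 1e-8
        L = linalg.cholesky(Kn, lower=True)
    alpha = linalg.cho_solve((L, True), r)
    nll = 0.5 * r @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # d(LML)/dK = 0.5 * A

    grad = np.empty(dim + 1)
    # dK/d(log l_i) = sv*(5/3)*(1+sqrt5*D)*exp(-sqrt5*D) .* S_i,
    # S_i = ((x_i - x'_i)/l_i)^2 — the distance factor cancels, no 1/D singularity.
    W = A * (sv * (5.0 / 3.0) * (1.0 + SQRT5 * D) * np.exp(-SQRT5 * D))
    for i in range(dim):
        S = ((X[:, i, None] - X[None, :, i]) / ls[i]) ** 2
        grad[i] = -0.5 * np.sum(W * S)
    grad[dim] = -0.5 * np.sum(A * K)  # dK/d(log sv) = K
    return float(nll), grad


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    noise_variance: float = 0.2,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 4,
    maxiter: int = 100,
) -> GPModel:
    """Fit kernel hyperparameters by maximum marginal likelihood, noise fixed.

    L-BFGS-B from ``n_restarts`` log-uniform initializations (plus one
    moderate default start); the best final likelihood wins.  Deterministic
    for a fixed integer seed.  Degenerate targets (zero variance) fall back
    to unit signal variance with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit a GP")
    n, dim = X.shape
    mean_const = float(y.mean())
    r = y - mean_const

    if np.var(y) == 0.0:
        warnings.warn(
            "degenerate targets (zero variance); falling back to unit signal variance",
            stacklevel=2,
        )
        params = KernelParams(lengthscales=np.ones(dim), signal_variance=1.0)
        return GPModel(X, y, params, noise_variance, mean_const)

    rng = np.random.default_rng(seed)
    lb = np.log(np.r_[np.full(dim, LENGTHSCALE_BOUNDS[0]), SIGNAL_VARIANCE_BOUNDS[0]])
    ub = np.log(np.r_[np.full(dim, LENGTHSCALE_BOUNDS[1]), SIGNAL_VARIANCE_BOUNDS[1]])
    bounds = list(zip(lb, ub))

    starts = [np.log(np.r_[np.full(dim, 0.5), max(np.var(y), 1e-4)])]
    for _ in range(n_restarts):
        ls0 = np.exp(rng.uniform(np.log(0.03), np.log(3.0), size=dim))
        sv0 = np.exp(rng.uniform(np.log(0.01), np.log(4.0)))
        starts.append(np.log(np.r_[ls0, sv0]))

    best_theta, best_nll = None, np.inf
    for theta0 in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(theta0, lb, ub),
            args=(X, r, noise_variance),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if res.fun < best_nll:
            best_nll, best_theta = res.fun, res.x

    params = KernelParams(
        lengthscales=np.exp(best_theta[:dim]),
        signal_variance=float(np.exp(best_theta[dim])),
    )
    return GPModel(X, y, params, noise_variance, mean_const)
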
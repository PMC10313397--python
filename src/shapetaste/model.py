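"""Bayesian model for within-subjects VAS ratings of four shape conditions.

Model
-----
Each participant contributes one 4-vector of ratings (one score per shape
condition) for a given taste.  Rows are modelled as i.i.d. draws from a
4-dimensional multivariate normal,

    y_p ~ MVN(mu, Sigma),   Sigma = diag(sigma) @ R @ diag(sigma),

with independent priors

    mu_i    ~ Uniform(0, 100)          (VAS units)
    sigma_i ~ Uniform(0, 50)           (VAS units)
    R       ~ LKJ(eta)                 (correlation matrix)

The LKJ density is used up to its normalizing constant (density
proportional to det(R)^(eta-1)); MCMC only requires the target up to a
constant.  The likelihood is a plain, untruncated multivariate normal even
though VAS scores live in [0, 100]: only the priors are bounded.

The module also provides the bijection between the bounded parameter space
and an unconstrained 14-dimensional real vector (4 means, 4 scales, 6
canonical partial correlations), with its log-Jacobian, which is what the
random-walk sampler operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .conditions import N_CONDITIONS, SHAPES

__all__ = [
    "PriorSpec",
    "ModelParams",
    "N_FREE_PARAMS",
    "PARAM_NAMES",
    "build_covariance",
    "lkj_log_density",
    "log_prior",
    "mvn_log_likelihood",
    "log_posterior",
    "to_unconstrained",
    "to_constrained",
    "make_taste_target",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: strictly-lower-triangle index order for the 6 free correlation entries
_TRIL_ROWS, _TRIL_COLS = np.tril_indices(N_CONDITIONS, k=-1)

#: 4 means + 4 scales + 6 correlations
N_FREE_PARAMS = 2 * N_CONDITIONS + len(_TRIL_ROWS)

PARAM_NAMES: tuple[str, ...] = tuple(
    [f"mu[{s}]" for s in SHAPES]
    + [f"sigma[{s}]" for s in SHAPES]
    + [f"corr[{SHAPES[i]},{SHAPES[j]}]" for i, j in zip(_TRIL_ROWS, _TRIL_COLS)]
)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters: Uniform bounds for mu and sigma, LKJ shape.

    ``lkj_eta = 1`` makes the correlation prior uniform over correlation
    matrices, the least-informative member of the family.
    """

    mu_lower: float = 0.0
    mu_upper: float = 100.0
    sigma_lower: float = 0.0
    sigma_upper: float = 50.0
    lkj_eta: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu_lower < self.mu_upper:
            raise ValueError("mu_lower must be < mu_upper")
        if not self.sigma_lower < self.sigma_upper:
            raise ValueError("sigma_lower must be < sigma_upper")
        if not self.lkj_eta > 0:
            raise ValueError("lkj_eta must be positive")


def _validate_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    # positive definiteness via Cholesky
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix must be positive definite") from None
    return corr


@dataclass(frozen=True)
class ModelParams:
    """Condition means, scales and correlation matrix of the rating model."""

    mu: np.ndarray
    sigma: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        corr = _validate_corr(self.corr)
        if not (mu.shape == sigma.shape == (corr.shape[0],)):
            raise ValueError("mu, sigma and corr dimensions must agree")
        if np.any(sigma <= 0):
            raise ValueError("all sigma must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "corr", corr)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]


def build_covariance(sigma: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Covariance matrix ``diag(sigma) @ corr @ diag(sigma)``."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (sigma.size, sigma.size):
        raise ValueError(
            f"dimension mismatch: sigma has {sigma.size} entries, "
            f"corr has shape {corr.shape}"
        )
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be positive")
    return corr * np.outer(sigma, sigma)


def lkj_log_density(corr: np.ndarray, eta: float) -> float:
    """Unnormalized LKJ log-density ``(eta - 1) * log det(corr)``.

    The normalizing constant is omitted; the density is defined up to a
    constant, which is all MCMC requires.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    corr = _validate_corr(corr)
    sign, logdet = np.linalg.slogdet(corr)
    return float((eta - 1.0) * logdet)


def log_prior(params: ModelParams, priors: PriorSpec | None = None) -> float:
    """Joint log-prior: Uniform components plus the LKJ correlation term.

    Returns ``-inf`` for parameters outside the prior support.
    """
    if priors is None:
        priors = PriorSpec()
    mu, sigma = params.mu, params.sigma
    if np.any(mu <= priors.mu_lower) or np.any(mu >= priors.mu_upper):
        return float("-inf")
    if np.any(sigma <= priors.sigma_lower) or np.any(sigma >= priors.sigma_upper):
        return float("-inf")
    d = params.dim
    out = -d * np.log(priors.mu_upper - priors.mu_lower)
    out += -d * np.log(priors.sigma_upper - priors.sigma_lower)
    out += lkj_log_density(params.corr, priors.lkj_eta)
    return float(out)


def mvn_log_likelihood(data: np.ndarray, params: ModelParams) -> float:
    """Multivariate-normal log-likelihood of an ``n x d`` score matrix.

    Columns must be in canonical condition order.  Rows (participants) are
    independent given the parameters.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d = params.dim
    if data.shape[1] != d:
        raise ValueError(f"data must have {d} columns, got {data.shape[1]}")
    cov = build_covariance(params.sigma, params.corr)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular or not positive definite; "
            "check sigma and the correlation matrix"
        ) from None
    diff = data - params.mu
    z = np.linalg.solve(chol, diff.T)  # (d, n)
    quad = float(np.sum(z * z))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    n = data.shape[0]
    return -0.5 * (n * d * _LOG_2PI + n * logdet + quad)


def log_posterior(
    data: np.ndarray, params: ModelParams, priors: PriorSpec | None = None
) -> float:
    """Unnormalized log-posterior ``log_prior + mvn_log_likelihood``."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return float("-inf")
    return lp + mvn_log_likelihood(data, params)


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------
# mu_i    = lo + width * expit(x_i)
# sigma_i = lo + width * expit(x_i)
# R       built from canonical partial correlations z = tanh(y) via the
#          Cholesky-factor recursion; the map is a bijection between R^6 and
#          the interior of the space of 4x4 correlation matrices.


def _constrain_batch(
    y: np.ndarray, priors: PriorSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map a ``(K, 14)`` unconstrained batch to model parameters.

    Returns ``(mu (K,4), sigma (K,4), corr (K,4,4), chol_L (K,4,4),
    log_jac (K,))`` where ``log_jac`` is the log-Jacobian of the full
    unconstrained -> constrained map.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    K = y.shape[0]
    d = N_CONDITIONS
    y_mu, y_sig, y_cor = y[:, :d], y[:, d : 2 * d], y[:, 2 * d :]

    w_mu = priors.mu_upper - priors.mu_lower
    w_sig = priors.sigma_upper - priors.sigma_lower
    mu = priors.mu_lower + w_mu * expit(y_mu)
    sigma = priors.sigma_lower + w_sig * expit(y_sig)
    # d/dx [lo + w*expit(x)] = w * expit(x) * expit(-x)
    log_jac = np.sum(log_expit(y_mu) + log_expit(-y_mu), axis=1) + d * np.log(w_mu)
    log_jac += np.sum(log_expit(y_sig) + log_expit(-y_sig), axis=1) + d * np.log(w_sig)

    z = np.tanh(y_cor)
    # tanh Jacobian: log(1 - z^2), clipped away from 0 for extreme inputs
    log_jac += np.sum(np.log1p(-np.clip(z * z, 0.0, 1.0 - 1e-16)), axis=1)

    # Cholesky factor from canonical partial correlations.  Jacobian of
    # z -> R is triangular; its log-determinant accumulates
    # log L[j,j] + 0.5*log(rem) at each filled entry (i, j).
    L = np.zeros((K, d, d))
    L[:, 0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        rem = np.ones(K)
        for j in range(i):
            zij = z[:, idx]
            idx += 1
            sq = np.sqrt(np.maximum(rem, 1e-300))
            L[:, i, j] = zij * sq
            log_jac += np.log(np.maximum(L[:, j, j], 1e-300)) + 0.5 * np.log(
                np.maximum(rem, 1e-300)
            )
            rem = rem - L[:, i, j] ** 2
        L[:, i, i] = np.sqrt(np.maximum(rem, 1e-300))
    corr = L @ np.swapaxes(L, 1, 2)
    return mu, sigma, corr, L, log_jac


def to_constrained(
    vector: np.ndarray, priors: PriorSpec | None = None
) -> tuple[ModelParams, float]:
    """Map an unconstrained 14-vector to ``(ModelParams, log_jacobian)``."""
    if priors is None:
        priors = PriorSpec()
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_FREE_PARAMS,):
        raise ValueError(f"expected a vector of length {N_FREE_PARAMS}")
    if not np.all(np.isfinite(vector)):
        raise ValueError("unconstrained vector must be finite")
    mu, sigma, corr, _, log_jac = _constrain_batch(vector[None, :], priors)
    # symmetrize against roundoff before validation
    R = (corr[0] + corr[0].T) / 2.0
    np.fill_diagonal(R, 1.0)
    return ModelParams(mu=mu[0], sigma=sigma[0], corr=R), float(log_jac[0])


def to_unconstrained(
    params: ModelParams, priors: PriorSpec | None = None
) -> np.ndarray:
    """Map interior ``ModelParams`` to the unconstrained 14-vector."""
    if priors is None:
        priors = PriorSpec()
    mu, sigma, corr = params.mu, params.sigma, params.corr
    if np.any(mu <= priors.mu_lower) or np.any(mu >= priors.mu_upper):
        raise ValueError("mu must lie strictly inside the prior support")
    if np.any(sigma <= priors.sigma_lower) or np.any(sigma >= priors.sigma_upper):
        raise ValueError("sigma must lie strictly inside the prior support")

    def _logit(p: np.ndarray) -> np.ndarray:
        return np.log(p) - np.log1p(-p)

    y_mu = _logit((mu - priors.mu_lower) / (priors.mu_upper - priors.mu_lower))
    y_sig = _logit(
        (sigma - priors.sigma_lower) / (priors.sigma_upper - priors.sigma_lower)
    )
    L = np.linalg.cholesky(corr)
    z = np.empty(len(_TRIL_ROWS))
    idx = 0
    for i in range(1, N_CONDITIONS):
        rem = 1.0
        for j in range(i):
            z[idx] = L[i, j] / np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
    if np.any(np.abs(z) >= 1.0):
        raise ValueError("correlation matrix lies on the boundary of its support")
    return np.concatenate([y_mu, y_sig, np.arctanh(z)])


class TasteTarget:
    """Batched unconstrained-space log-posterior for one taste's ratings.

    Evaluates ``log_posterior(constrained(y)) + log_jacobian(y)`` for a
    ``(K, 14)`` batch of unconstrained points in one vectorized pass; this is
    the density handed to the sampler.
    """

    def __init__(self, data: np.ndarray, priors: PriorSpec | None = None):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] != N_CONDITIONS:
            raise ValueError(f"data must have {N_CONDITIONS} columns")
        self.data = data
        self.priors = priors if priors is not None else PriorSpec()
        self.n_dim = N_FREE_PARAMS
        self.param_names = PARAM_NAMES
        d = N_CONDITIONS
        self._prior_const = -d * np.log(
            self.priors.mu_upper - self.priors.mu_lower
        ) - d * np.log(self.priors.sigma_upper - self.priors.sigma_lower)

    def log_density(self, y: np.ndarray) -> np.ndarray:
        """Log target for a ``(K, 14)`` batch; returns shape ``(K,)``."""
        priors = self.priors
        data = self.data
        n, d = data.shape
        mu, sigma, corr, L, log_jac = _constrain_batch(y, priors)
        # log det R from the Cholesky factor of the correlation matrix
        diagL = np.maximum(np.diagonal(L, axis1=1, axis2=2), 1e-300)
        logdet_R = 2.0 * np.sum(np.log(diagL), axis=1)
        lp = self._prior_const + (priors.lkj_eta - 1.0) * logdet_R

        # covariance Cholesky: diag(sigma) @ L  (lower triangular)
        cholS = L * sigma[:, :, None]
        logdet_S = 2.0 * np.sum(
            np.log(np.maximum(np.diagonal(cholS, axis1=1, axis2=2), 1e-300)), axis=1
        )
        diff = data[None, :, :] - mu[:, None, :]  # (K, n, d)
        # solve cholS @ v = diff^T per batch element
        v = np.linalg.solve(cholS, np.swapaxes(diff, 1, 2))  # (K, d, n)
        quad = np.einsum("kdn,kdn->k", v, v)
        ll = -0.5 * (n * d * _LOG_2PI + n * logdet_S + quad)
        return lp + ll + log_jac

    def constrain(self, y: np.ndarray) -> np.ndarray:
        """Map a ``(K, 14)`` unconstrained batch to constrained parameter
        columns ``[mu(4), sigma(4), corr lower triangle(6)]``."""
        mu, sigma, corr, _, _ = _constrain_batch(y, self.priors)
        tril = corr[:, _TRIL_ROWS, _TRIL_COLS]
        return np.concatenate([mu, sigma, tril], axis=1)

    def sample_initial(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one unconstrained start point from the prior.

        Means and scales are drawn from their Uniform priors (shrunk 1% from
        the boundary so the logit is finite); partial correlations from a
        mild tanh-normal spread around zero.
        """
        p = self.priors
        mu = rng.uniform(
            p.mu_lower + 0.01 * (p.mu_upper - p.mu_lower),
            p.mu_upper - 0.01 * (p.mu_upper - p.mu_lower),
            N_CONDITIONS,
        )
        sigma = rng.uniform(
            p.sigma_lower + 0.01 * (p.sigma_upper - p.sigma_lower),
            p.sigma_upper - 0.01 * (p.sigma_upper - p.sigma_lower),
            N_CONDITIONS,
        )

        def _logit(x: np.ndarray) -> np.ndarray:
            return np.log(x) - np.log1p(-x)

        y_mu = _logit((mu - p.mu_lower) / (p.mu_upper - p.mu_lower))
        y_sig = _logit((sigma - p.sigma_lower) / (p.sigma_upper - p.sigma_lower))
        y_cor = rng.normal(0.0, 0.5, len(_TRIL_ROWS))
        return np.concatenate([y_mu, y_sig, y_cor])


def make_taste_target(data: np.ndarray, priors: PriorSpec | None = None) -> TasteTarget:
    """Build the sampler-facing target density for one taste's score matrix."""
    return TasteTarget(data, priors)
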
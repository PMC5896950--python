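"""Bayesian Poisson log-linear emulator for shear-event counts.

Model
-----
Counts y_k ~ Poisson(lambda_k) with log lambda_k = x_k . B, where x_k is
the quadratic basis row built from the six detachment covariates (time,
particle count, shear rate, EPS composition, biofilm height, mass) and
B the coefficient vector with independent normal priors N(m_i, v_i)
(v_i^-1 = 0 gives a flat prior).  The log posterior, up to a constant, is

    log pi(B | y) = sum_i alpha_i beta_i - sum_i beta_i^2 / (2 v_i)
                    - sum_k exp(x_k . B),
    alpha_i = m_i / v_i + sum_k x_ik y_k .

There is no conjugacy, so sampling uses a Gaussian random-walk Metropolis
chain started at the maximum-likelihood estimate, with proposal
covariance proportional to the inverse Fisher information at the MLE and
a global scale adapted toward ~23% acceptance during burn-in only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .basis import QuadraticBasis, build_quadratic_features

__all__ = [
    "PoissonPrior",
    "PoissonPosterior",
    "CountPredictive",
    "build_quadratic_features",
    "poisson_pmf",
    "log_posterior",
    "poisson_mle",
    "metropolis_sample",
    "predict_counts",
    "ergodic_diagnostics",
]

_LOG_LAMBDA_MAX = 700.0  # beyond this exp() overflows a double


@dataclass
class PoissonPrior:
    """Independent normal priors N(mean_i, 1/precision_i) per coefficient.

    A zero precision entry is a flat prior (the mean is then inert).
    """

    mean: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.precision = np.atleast_1d(np.asarray(self.precision, dtype=float))
        if (self.precision < 0).any():
            raise ValueError("prior precisions must be >= 0")
        if self.mean.shape != self.precision.shape:
            raise ValueError("prior mean/precision length mismatch")

    @classmethod
    def flat(cls, q: int, mean: float = 0.5) -> "PoissonPrior":
        """The study's default prior: m_i = 0.5, v_i^-1 = 0, for all q terms."""
        return cls(mean=np.full(q, mean), precision=np.zeros(q))


def poisson_pmf(k, lam) -> np.ndarray | float:
    """Poisson probability mass lambda^k e^-lambda / k!, in log space."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be a non-negative integer")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lambda must be positive")
    out = stats.poisson.pmf(k, lam)
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


def _prior_alpha(X: np.ndarray, y: np.ndarray, prior: PoissonPrior) -> np.ndarray:
    """alpha_i = m_i / v_i + sum_k x_ik y_k (prior term 0 when flat)."""
    return prior.mean * prior.precision + X.T @ y


def log_posterior(
    B: np.ndarray,
    basis: QuadraticBasis | np.ndarray,
    y: np.ndarray,
    prior: PoissonPrior,
    alpha: np.ndarray | None = None,
) -> float:
    """Unnormalized log posterior of the coefficient vector.

    Returns -inf (never NaN) when exp(x . B) would overflow, so such
    proposals are simply rejected.
    """
    X = basis.matrix if isinstance(basis, QuadraticBasis) else np.asarray(basis)
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts y must be non-negative integers")
    if alpha is None:
        alpha = _prior_alpha(X, y, prior)
    eta = X @ B
    if np.max(eta) > _LOG_LAMBDA_MAX:
        return -np.inf
    return float(alpha @ B - 0.5 * np.sum(prior.precision * B**2) - np.sum(np.exp(eta)))


def log_likelihood(B, X, y) -> float:
    """Poisson log likelihood including the constant -sum log(y_k!)."""
    eta = np.asarray(X) @ np.asarray(B, dtype=float)
    if np.max(eta) > _LOG_LAMBDA_MAX:
        return -np.inf
    return float(y @ eta - np.sum(np.exp(eta)) - np.sum(gammaln(np.asarray(y) + 1.0)))


def poisson_mle(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    lam_floor: float = 1e-8,
):
    """Maximum-likelihood coefficients by Newton iteration.

    Returns (B_hat, fisher) where fisher = X^T diag(lambda_hat) X.  Counts
    that are all zero are accepted: the intercept is floored at
    log(lam_floor).  A singular Fisher matrix (collinear basis columns)
    is reported as an error since the chain proposal needs its inverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    if y.sum() == 0:
        # all-zero counts: the MLE intercept diverges to -inf; floor the
        # fitted rate at lam_floor instead of failing
        B = np.linalg.lstsq(X, np.full(n, np.log(lam_floor)), rcond=None)[0]
        lam = np.exp(np.clip(X @ B, -500, 500))
        fisher = X.T @ (lam[:, None] * X)
        if np.linalg.cond(X.T @ X) > 1e12:
            raise ValueError(
                "Fisher information is singular at the MLE; the basis has "
                "collinear or zero-variance columns"
            )
        return B, fisher
    B = np.zeros(q)
    ybar = max(y.mean(), lam_floor)
    # start from an intercept-only fit when the basis has a constant column
    const = np.flatnonzero(np.all(X == X[0], axis=0) & (X[0] != 0))
    if const.size:
        B[const[0]] = np.log(ybar) / X[0, const[0]]
    step_ok = True
    for _ in range(max_iter):
        eta = np.clip(X @ B, -500, 500)
        lam = np.exp(eta)
        grad = X.T @ (y - lam)
        fisher = X.T @ (lam[:, None] * X)
        try:
            delta = np.linalg.solve(fisher + 1e-10 * np.eye(q), grad)
        except np.linalg.LinAlgError:
            step_ok = False
            break
        # damped step to keep exp() in range
        scale = 1.0
        while scale > 1e-6 and np.max(np.abs(X @ (B + scale * delta))) > 400:
            scale /= 2
        B = B + scale * delta
        if np.max(np.abs(scale * delta)) < tol:
            break
    lam = np.exp(np.clip(X @ B, -500, 500))
    fisher = X.T @ (lam[:, None] * X)
    cond = np.linalg.cond(fisher)
    if not step_ok or not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "Fisher information is singular at the MLE; the basis has "
            "collinear or zero-variance columns — drop or merge the "
            "offending covariates before sampling"
        )
    return B, fisher


@dataclass
class PoissonPosterior:
    """Retained Metropolis draws of the basis coefficients."""

    draws: np.ndarray  # S x q
    acceptance_rate: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None
    alpha: np.ndarray
    labels: list[tuple[int, int]] | None = None
    proposal_scale: float = field(default=1.0)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        a = 100 * (1 - level) / 2
        return np.percentile(self.draws, [a, 100 - a], axis=0)


def metropolis_sample(
    basis: QuadraticBasis | np.ndarray,
    y: np.ndarray,
    prior: PoissonPrior | None = None,
    n_iter: int = 60_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int | None = None,
    proposal_scale: float | None = None,
    adapt: bool = True,
    target_acceptance: float = 0.234,
) -> PoissonPosterior:
    """Random-walk Metropolis sampling of the coefficient posterior.

    The chain starts at the MLE; proposals are multivariate normal with
    covariance (2.38^2 / q) * s^2 * fisher^-1, where the global scale s is
    tuned toward the target acceptance during burn-in and frozen after.
    ``proposal_scale=0`` degenerates to a chain that never moves (useful
    for tests).  Deterministic under a fixed seed.
    """
    X = basis.matrix if isinstance(basis, QuadraticBasis) else np.asarray(basis)
    labels = basis.labels if isinstance(basis, QuadraticBasis) else None
    y = np.asarray(y, dtype=float)
    q = X.shape[1]
    if prior is None:
        prior = PoissonPrior.flat(q)
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = _prior_alpha(X, y, prior)

    B, fisher = poisson_mle(X, y)
    # proposal shape from the inverse Fisher information at the MLE
    prop_cov = np.linalg.inv(fisher + 1e-10 * np.eye(q))
    L = np.linalg.cholesky((prop_cov + prop_cov.T) / 2 + 1e-14 * np.eye(q))
    base = 2.38 / np.sqrt(q)
    log_s = 0.0 if proposal_scale is None else np.log(max(proposal_scale, 1e-300))
    fixed_scale = proposal_scale is not None and not adapt

    lp = log_posterior(B, X, y, prior, alpha=alpha)
    keep = np.empty(((n_iter - burn_in) // thin, q))
    kept = 0
    accepted_post = 0
    n_post = 0
    for it in range(n_iter):
        if proposal_scale == 0:
            prop = B
            lp_prop = lp
            accept = False
        else:
            s = base * np.exp(log_s)
            prop = B + s * (L @ rng.standard_normal(q))
            lp_prop = log_posterior(prop, X, y, prior, alpha=alpha)
            accept = np.log(rng.uniform()) < lp_prop - lp
        if accept:
            B, lp = prop, lp_prop
        if it < burn_in:
            if adapt and not fixed_scale and proposal_scale != 0:
                log_s += (float(accept) - target_acceptance) / (1 + it) ** 0.6
        else:
            n_post += 1
            accepted_post += int(accept)
            if (it - burn_in) % thin == 0 and kept < len(keep):
                keep[kept] = B
                kept += 1
    return PoissonPosterior(
        draws=keep[:kept],
        acceptance_rate=accepted_post / max(n_post, 1),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        alpha=alpha,
        labels=labels,
        proposal_scale=float(np.exp(log_s)),
    )


@dataclass
class CountPredictive:
    """Posterior-predictive count draws at new covariate rows."""

    lambda_draws: np.ndarray  # S x n_new
    count_draws: np.ndarray  # S x n_new
    lower: np.ndarray  # 2.5% of counts
    median: np.ndarray
    upper: np.ndarray  # 97.5%

    @property
    def mean(self) -> np.ndarray:
        return self.count_draws.mean(axis=0)

    @property
    def lambda_mean(self) -> np.ndarray:
        return self.lambda_draws.mean(axis=0)


def predict_counts(
    posterior: PoissonPosterior,
    basis_new: QuadraticBasis | np.ndarray,
    seed: int | None = None,
    level: float = 0.95,
) -> CountPredictive:
    """Posterior-predictive distribution of counts at new points.

    Per retained draw B_s and row k: lambda = exp(x_k . B_s), one Poisson
    draw; the interval is the empirical central ``level`` band of the
    count draws.
    """
    X = (
        basis_new.matrix
        if isinstance(basis_new, QuadraticBasis)
        else np.atleast_2d(np.asarray(basis_new))
    )
    if posterior.n_draws == 0:
        raise ValueError("posterior contains no draws")
    if X.shape[1] != posterior.draws.shape[1]:
        raise ValueError(
            f"basis has {X.shape[1]} columns but the posterior has "
            f"{posterior.draws.shape[1]} coefficients"
        )
    eta = posterior.draws @ X.T
    if np.max(eta) > _LOG_LAMBDA_MAX:
        raise ValueError("predictive mean overflows; inputs far outside training range")
    lam = np.exp(eta)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    a = 100 * (1 - level) / 2
    lo, med, hi = np.percentile(counts, [a, 50, 100 - a], axis=0)
    return CountPredictive(
        lambda_draws=lam, count_draws=counts, lower=lo, median=med, upper=hi
    )


@dataclass
class ErgodicDiagnostics:
    running_mean: np.ndarray  # S x q cumulative means
    batch_means: np.ndarray  # n_batches x q
    batch_se: np.ndarray  # q
    n_batches: int


def ergodic_diagnostics(chain: np.ndarray, n_batches: int = 20) -> ErgodicDiagnostics:
    """Running ergodic means and batch-means standard errors.

    The retained chain is split into ``n_batches`` consecutive batches;
    SE_i = sd(batch means of coordinate i) / sqrt(n_batches).
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    if chain.shape[0] < chain.shape[1] and chain.shape[0] == 1:
        chain = chain.T  # a single 1-D chain passed as a row
    S = chain.shape[0]
    if n_batches < 2 or S < 2 * n_batches:
        raise ValueError("chain too short for the requested number of batches")
    width = S // n_batches
    trimmed = chain[: width * n_batches]
    running = np.cumsum(chain, axis=0) / np.arange(1, S + 1)[:, None]
    bm = trimmed.reshape(n_batches, width, -1).mean(axis=1)
    se = bm.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return ErgodicDiagnostics(
        running_mean=running, batch_means=bm, batch_se=se, n_batches=n_batches
    )


def mcse_mean(chain_1d: np.ndarray, widths=(10, 25, 50)) -> float:
    """Conservative batch-means Monte-Carlo SE of a chain's mean.

    Takes the largest SE across several batch counts, guarding against a
    single batch width understating autocorrelation.
    """
    chain_1d = np.asarray(chain_1d, dtype=float).ravel()
    ses = []
    for n_batches in widths:
        if len(chain_1d) >= 2 * n_batches:
            ses.append(ergodic_diagnostics(chain_1d[:, None], n_batches).batch_se[0])
    if not ses:
        raise ValueError("chain too short for batch-means SE")
    return float(max(ses))
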
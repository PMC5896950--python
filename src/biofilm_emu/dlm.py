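"""Bayesian dynamic linear model emulator for log detached-cluster volume.

Model
-----
For a panel of m runs observed over T time bins,

    Y_t = F beta_t + v_t,    v_t ~ N(0, V),    V = diag(1/phi_y,i),
    beta_t = G beta_{t-1} + w_t,  w_t ~ N(0, W),  W = diag(1/phi_beta,j),
    beta_0 ~ N(m0, C0),      G = diag(psi_1, ..., psi_p),

where F holds one row per run: the seven simulator parameters plus the
run's number of shear events, all min-max scaled to [0, 1].  Priors:
psi_j ~ N(psi0, tau0) and phi_y,i, phi_beta,j ~ Gamma(shape, rate).

Inference is a systematic-scan Gibbs sampler: the full state trajectory
is drawn by forward-filtering backward-sampling (FFBS), then psi and the
precisions from their conjugate full conditionals.  The Kalman filter is
run in information form (p x p linear algebra) whenever all observation
variances are positive, falling back to the covariance recursion
otherwise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .preprocess import MinMaxScaler, normalize_inputs  # noqa: F401  (module surface)

__all__ = [
    "DLMSpec",
    "DLMParams",
    "KalmanResult",
    "DLMPosterior",
    "VolumePredictive",
    "normalize_inputs",
    "kalman_filter",
    "ffbs_sample_states",
    "gibbs_update_G",
    "gibbs_update_variances",
    "gibbs_sample",
    "predict_volumes",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class DLMSpec:
    """Regression matrix, initial-state prior and hyperparameters.

    Defaults are the study's: psi0 = 0, tau0 = 1, alpha_y = 3, b_y = 0.01,
    alpha_beta = 3, b_beta = 1, m0 = 0, C0 = I_p.  Gamma hyperparameters
    use the shape-rate convention (prior mean precision = alpha / b).
    """

    F: np.ndarray
    m0: np.ndarray | None = None
    C0: np.ndarray | None = None
    psi0: float = 0.0
    tau0: float = 1.0
    alpha_y: float = 3.0
    b_y: float = 0.01
    alpha_beta: float = 3.0
    b_beta: float = 1.0
    gamma_scale: bool = False  # interpret b as a gamma scale instead of rate

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim == 1:
            self.F = self.F[None, :]
        if self.F.ndim not in (2, 3):
            raise ValueError("F must be (m, p) or time-varying (T, m, p)")
        p = self.F.shape[-1]
        self.m0 = np.zeros(p) if self.m0 is None else np.asarray(self.m0, dtype=float)
        self.C0 = np.eye(p) if self.C0 is None else np.asarray(self.C0, dtype=float)
        if self.m0.shape != (p,) or self.C0.shape != (p, p):
            raise ValueError("m0/C0 dimensions do not match F")
        for name in ("tau0", "alpha_y", "b_y", "alpha_beta", "b_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"hyperparameter {name} must be >= 0")

    @property
    def time_varying(self) -> bool:
        return self.F.ndim == 3

    @property
    def m(self) -> int:
        return self.F.shape[-2]

    @property
    def p(self) -> int:
        return self.F.shape[-1]

    @property
    def rate_y(self) -> float:
        return 1.0 / self.b_y if self.gamma_scale else self.b_y

    @property
    def rate_beta(self) -> float:
        return 1.0 / self.b_beta if self.gamma_scale else self.b_beta


@dataclass
class DLMParams:
    """Diagonal, time-invariant G, V, W in precision parameterization."""

    psi: np.ndarray  # p
    phi_y: np.ndarray  # m observation precisions
    phi_beta: np.ndarray  # p evolution precisions

    def __post_init__(self) -> None:
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.phi_y = np.atleast_1d(np.asarray(self.phi_y, dtype=float))
        self.phi_beta = np.atleast_1d(np.asarray(self.phi_beta, dtype=float))
        if (self.phi_y <= 0).any() or (self.phi_beta <= 0).any():
            raise ValueError("precisions must be strictly positive")

    @property
    def G(self) -> np.ndarray:
        return np.diag(self.psi)

    @property
    def V(self) -> np.ndarray:
        return np.diag(1.0 / self.phi_y)

    @property
    def W(self) -> np.ndarray:
        return np.diag(1.0 / self.phi_beta)


@dataclass
class KalmanResult:
    """Per-step filtering output; index t-1 holds quantities for time t."""

    a: np.ndarray  # T x p prior state means
    R: np.ndarray  # T x p x p prior state covariances
    f: np.ndarray  # T x m one-step predictive means
    Q: np.ndarray | None  # T x m x m predictive covariances (None if not stored)
    filtered_mean: np.ndarray  # T x p
    filtered_cov: np.ndarray  # T x p x p
    step_loglik: np.ndarray  # T, log pi(Y_t | Y_1:t-1)

    @property
    def loglik(self) -> float:
        return float(self.step_loglik.sum())


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.swapaxes(-1, -2)) / 2


def _coerce(F, G, V, W):
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    m, p = F.shape[-2], F.shape[-1]
    G = np.asarray(G, dtype=float)
    G = np.diag(G) if G.ndim == 1 else G
    V = np.asarray(V, dtype=float)
    V = np.diag(V) if V.ndim == 1 else V
    W = np.asarray(W, dtype=float)
    W = np.diag(W) if W.ndim == 1 else W
    if G.shape != (p, p) or V.shape != (m, m) or W.shape != (p, p):
        raise ValueError("G/V/W dimensions do not conform with F")
    return F, G, V, W, m, p


def kalman_filter(
    F: np.ndarray,
    G: np.ndarray,
    V: np.ndarray,
    W: np.ndarray,
    m0: np.ndarray,
    C0: np.ndarray,
    Y: np.ndarray,
    store_Q: bool = True,
) -> KalmanResult:
    """Forward Kalman recursion with one-step predictive log densities.

    Standard recursions: a_t = G m_{t-1}, R_t = G C_{t-1} G' + W,
    f_t = F a_t, Q_t = F R_t F' + V, K_t = R_t F' Q_t^-1,
    m_t = a_t + K_t (Y_t - f_t), C_t = R_t - K_t F R_t.

    Parameters
    ----------
    F : ndarray (m, p) or (T, m, p)
        Static or time-varying regression matrix.
    Y : ndarray (m, T)
        Observation panel; a 1-D array is treated as m = 1.
    """
    F, G, V, W, m, p = _coerce(F, G, V, W)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[0] != m:
        raise ValueError(f"Y has {Y.shape[0]} rows, F has {m}")
    if not np.isfinite(Y).all():
        raise ValueError("Y must be finite")
    T = Y.shape[1]
    if F.ndim == 3 and F.shape[0] != T:
        raise ValueError(f"time-varying F has {F.shape[0]} steps, Y has {T}")
    m0 = np.asarray(m0, dtype=float)
    C0 = np.asarray(C0, dtype=float)

    a = np.empty((T, p))
    R = np.empty((T, p, p))
    f = np.empty((T, m))
    Q = np.empty((T, m, m)) if store_Q else None
    mt = np.empty((T, p))
    Ct = np.empty((T, p, p))
    step_ll = np.empty(T)

    m_prev, C_prev = m0, C0
    for t in range(T):
        Ft = F if F.ndim == 2 else F[t]
        a[t] = G @ m_prev
        R[t] = _sym(G @ C_prev @ G.T + W)
        f[t] = Ft @ a[t]
        Qt = _sym(Ft @ R[t] @ Ft.T + V)
        if store_Q:
            Q[t] = Qt
        e = Y[:, t] - f[t]
        try:
            cho = sla.cho_factor(Qt, lower=True)
        except np.linalg.LinAlgError as err:
            cond = np.linalg.cond(Qt)
            raise np.linalg.LinAlgError(
                f"singular one-step predictive covariance Q at t={t + 1} "
                f"(condition number {cond:.3g}); check for zero observation "
                "variances or duplicated rows of F"
            ) from err
        FR = Ft @ R[t]
        K = sla.cho_solve(cho, FR).T  # R F' Q^-1
        mt[t] = a[t] + K @ e
        Ct[t] = _sym(R[t] - K @ FR)
        logdet = 2 * np.sum(np.log(np.diag(cho[0])))
        step_ll[t] = -0.5 * (m * _LOG2PI + logdet + e @ sla.cho_solve(cho, e))
        m_prev, C_prev = mt[t], Ct[t]
    return KalmanResult(
        a=a, R=R, f=f, Q=Q, filtered_mean=mt, filtered_cov=Ct, step_loglik=step_ll
    )


def _filter_info_diag(F, psi, v_diag, w_diag, m0, C0, Y):
    """Information-form filter for diagonal G/V/W: all p x p algebra.

    Uses the Woodbury identity on Q = F R F' + V so the per-step cost is
    O(m p^2 + p^3) instead of O(m^3).  Requires positive v and w.
    """
    m, p = F.shape[-2], F.shape[-1]
    T = Y.shape[1]
    static = F.ndim == 2
    a = np.empty((T, p))
    R = np.empty((T, p, p))
    mt = np.empty((T, p))
    Ct = np.empty((T, p, p))
    step_ll = np.empty(T)
    if static:
        Fv = F / v_diag[:, None]  # V^-1 F
        FvF = F.T @ Fv  # F' V^-1 F
    sum_log_v = np.sum(np.log(v_diag))
    m_prev, C_prev = m0, C0
    eye = np.eye(p)
    w_mat = np.diag(w_diag)
    Fcur = F if static else None
    for t in range(T):
        if not static:
            Fcur = F[t]
            Fv = Fcur / v_diag[:, None]
            FvF = Fcur.T @ Fv
        a[t] = psi * m_prev
        Rt = psi[:, None] * C_prev * psi[None, :] + w_mat
        R[t] = Rt
        cR = sla.cholesky(Rt, lower=True, check_finite=False)
        Rinv = sla.cho_solve((cR, True), eye, check_finite=False)
        M = Rinv + FvF
        cM = sla.cholesky(M, lower=True, check_finite=False)
        Cnew = sla.cho_solve((cM, True), eye, check_finite=False)
        Cnew = _sym(Cnew)
        e = Y[:, t] - Fcur @ a[t]
        u = Fv.T @ e  # F' V^-1 e
        mt[t] = a[t] + Cnew @ u
        Ct[t] = Cnew
        # logdet Q = logdet V + logdet R + logdet M; quad by Woodbury
        logdet = (
            sum_log_v
            + 2 * np.sum(np.log(np.diag(cR)))
            + 2 * np.sum(np.log(np.diag(cM)))
        )
        quad = e @ (e / v_diag) - u @ (Cnew @ u)
        step_ll[t] = -0.5 * (m * _LOG2PI + logdet + quad)
        m_prev, C_prev = mt[t], Ct[t]
    return a, R, mt, Ct, step_ll


def _sample_mvn(mean, cov, rng):
    """Draw from N(mean, cov) robustly for PSD (possibly singular) cov."""
    cov = _sym(np.asarray(cov, dtype=float))
    try:
        L = sla.cholesky(cov, lower=True, check_finite=False)
        return mean + L @ rng.standard_normal(len(mean))
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(cov)
        tol = 1e-12 * max(1.0, float(np.max(np.abs(w))))
        w = np.where(w < tol, 0.0, w)
        return mean + (U * np.sqrt(w)) @ rng.standard_normal(len(mean))


def _backward_sample(psi, a, R, mt, Ct, m0, C0, rng):
    """Backward pass of FFBS; returns states (T+1, p) incl. beta_0."""
    T, p = mt.shape
    states = np.empty((T + 1, p))
    states[T] = _sample_mvn(mt[T - 1], Ct[T - 1], rng)
    for t in range(T - 1, -1, -1):
        C_t = Ct[t - 1] if t > 0 else C0
        m_t = mt[t - 1] if t > 0 else m0
        GC = psi[:, None] * C_t  # G C_t
        Rn = R[t]  # R_{t+1} in 1-based time
        try:
            cRn = sla.cholesky(Rn, lower=True, check_finite=False)
            X = sla.cho_solve((cRn, True), GC, check_finite=False)
        except np.linalg.LinAlgError:
            X = sla.pinvh(Rn) @ GC
        J = X.T  # C_t G' R^-1
        h = m_t + J @ (states[t + 1] - a[t])
        H = C_t - J @ GC
        states[t] = _sample_mvn(h, H, rng)
    return states


def ffbs_sample_states(
    spec: DLMSpec,
    params: DLMParams,
    Y: np.ndarray,
    seed=None,
    kf: KalmanResult | None = None,
) -> np.ndarray:
    """One joint draw of beta_{0:T} by forward-filtering backward-sampling.

    Returns an array of shape (T+1, p); row 0 is beta_0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if kf is None:
        kf = kalman_filter(
            spec.F, params.G, params.V, params.W, spec.m0, spec.C0, Y, store_Q=False
        )
    return _backward_sample(
        params.psi, kf.a, kf.R, kf.filtered_mean, kf.filtered_cov, spec.m0, spec.C0, rng
    )


def gibbs_update_G(
    states: np.ndarray,
    phi_beta: np.ndarray,
    psi0: float,
    tau0: float,
    rng,
) -> np.ndarray:
    """Draw each AR coefficient psi_j from its normal full conditional.

    Combining the prior N(psi0, tau0) with the AR(1) likelihood of
    {beta_{j,t} | beta_{j,t-1}} at precision phi_beta,j gives
    precision = 1/tau0 + phi_beta,j * sum_t beta_{j,t-1}^2 and
    mean = (psi0/tau0 + phi_beta,j * sum_t beta_{j,t-1} beta_{j,t}) /
    precision.  tau0 = 0 is the dogmatic prior: psi_j = psi0 exactly.
    """
    states = np.asarray(states, dtype=float)
    if tau0 == 0:
        return np.full(states.shape[1], psi0)
    prev, curr = states[:-1], states[1:]
    S_xx = np.sum(prev**2, axis=0)
    S_xy = np.sum(prev * curr, axis=0)
    prec = 1.0 / tau0 + phi_beta * S_xx
    mean = (psi0 / tau0 + phi_beta * S_xy) / prec
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def gibbs_update_variances(
    Y: np.ndarray,
    F: np.ndarray,
    states: np.ndarray,
    psi: np.ndarray,
    spec: DLMSpec,
    rng,
):
    """Draw observation and evolution precisions from gamma conditionals.

    phi_y,i ~ Gamma(alpha_y + T/2, b_y + 1/2 sum_t (Y_it - F_i beta_t)^2),
    phi_beta,j ~ Gamma(alpha_beta + T/2, b_beta + 1/2 sum_t (beta_jt -
    psi_j beta_j,t-1)^2), shape-rate convention.
    """
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[1]
    if F.ndim == 3:
        fitted = np.einsum("tmp,tp->tm", F, states[1:])
    else:
        fitted = states[1:] @ F.T  # T x m
    ss_y = np.sum((Y.T - fitted) ** 2, axis=0)
    assert (ss_y >= 0).all()
    shape_y = spec.alpha_y + T / 2
    phi_y = rng.gamma(shape_y, 1.0 / (spec.rate_y + ss_y / 2))
    resid_b = states[1:] - psi * states[:-1]
    ss_b = np.sum(resid_b**2, axis=0)
    shape_b = spec.alpha_beta + T / 2
    phi_beta = rng.gamma(shape_b, 1.0 / (spec.rate_beta + ss_b / 2))
    return phi_y, phi_beta


@dataclass
class DLMPosterior:
    """Thinned Gibbs draws of (psi, phi_y, phi_beta) and state paths."""

    psi_draws: np.ndarray  # S x p
    phi_y_draws: np.ndarray  # S x m
    phi_beta_draws: np.ndarray  # S x p
    state_draws: np.ndarray | None  # S x (T+1) x p
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None
    spec: DLMSpec | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.psi_draws.shape[0]

    def posterior_mean_states(self) -> np.ndarray:
        if self.state_draws is None:
            raise ValueError("state draws were not stored")
        return self.state_draws.mean(axis=0)


def gibbs_sample(
    spec: DLMSpec,
    Y: np.ndarray,
    n_iter: int = 20_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int | None = None,
    store_states: bool = True,
) -> DLMPosterior:
    """Systematic-scan Gibbs sampler over (states | params) and (params | states).

    Each sweep draws the full state path by FFBS (information-form Kalman
    filter), then psi from its normal conditional and the precisions from
    their gamma conditionals.  Deterministic under a fixed seed.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    m, p = spec.m, spec.p
    if Y.shape[0] != m:
        raise ValueError("panel row count does not match F")
    T = Y.shape[1]
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)

    # initialize at prior means
    psi = np.full(p, spec.psi0 if spec.tau0 == 0 else 0.5)
    phi_y = np.full(m, spec.alpha_y / max(spec.rate_y, 1e-12))
    phi_beta = np.full(p, spec.alpha_beta / max(spec.rate_beta, 1e-12))

    S = (n_iter - burn_in + thin - 1) // thin
    psi_draws = np.empty((S, p))
    phi_y_draws = np.empty((S, m))
    phi_beta_draws = np.empty((S, p))
    state_draws = np.empty((S, T + 1, p)) if store_states else None
    kept = 0
    for it in range(n_iter):
        a, R, mt, Ct, _ = _filter_info_diag(
            spec.F, psi, 1.0 / phi_y, 1.0 / phi_beta, spec.m0, spec.C0, Y
        )
        states = _backward_sample(psi, a, R, mt, Ct, spec.m0, spec.C0, rng)
        psi = gibbs_update_G(states, phi_beta, spec.psi0, spec.tau0, rng)
        phi_y, phi_beta = gibbs_update_variances(Y, spec.F, states, psi, spec, rng)
        if max(phi_y.max(), phi_beta.max()) > 1e12:
            warnings.warn(
                "divergent precision draw (> 1e12); the model is close to "
                "non-identifiable for this panel",
                stacklevel=2,
            )
        if it >= burn_in and (it - burn_in) % thin == 0:
            psi_draws[kept] = psi
            phi_y_draws[kept] = phi_y
            phi_beta_draws[kept] = phi_beta
            if store_states:
                state_draws[kept] = states
            kept += 1
    return DLMPosterior(
        psi_draws=psi_draws[:kept],
        phi_y_draws=phi_y_draws[:kept],
        phi_beta_draws=phi_beta_draws[:kept],
        state_draws=None if not store_states else state_draws[:kept],
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        spec=spec,
    )


@dataclass
class VolumePredictive:
    """Posterior-predictive log-volume trajectories for new runs."""

    draws: np.ndarray  # S x m_new x T
    mean: np.ndarray  # m_new x T
    lower: np.ndarray
    upper: np.ndarray


def predict_volumes(
    posterior: DLMPosterior,
    F_new: np.ndarray,
    seed: int | None = None,
    level: float = 0.95,
    obs_noise: str = "harmonic",
) -> VolumePredictive:
    """Predict log detached volume over time for new input rows.

    For each retained draw s: Y*_t = F* beta_t^(s) + v*, with v* drawn at
    the harmonic-mean training observation precision of that draw
    (``obs_noise="harmonic"``, the default), a fresh draw from the gamma
    prior (``"prior"``), or omitted (``"none"``).  Rows of ``F_new`` must
    be scaled with the training min/max.
    """
    if posterior.state_draws is None:
        raise ValueError("posterior must store state draws for prediction")
    F_new = np.asarray(F_new, dtype=float)
    if F_new.ndim == 1:
        F_new = F_new[None, :]
    if F_new.shape[-1] != posterior.psi_draws.shape[1]:
        raise ValueError("F_new column count does not match the fitted model")
    if ((F_new < -0.5) | (F_new > 1.5)).any():
        warnings.warn(
            "F_new values far outside [0, 1]; inputs look un-normalized",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    S = posterior.n_draws
    if F_new.ndim == 3:  # time-varying test inputs (T, m_new, p)
        if F_new.shape[0] != posterior.state_draws.shape[1] - 1:
            raise ValueError("time-varying F_new step count does not match the panel")
        paths = np.einsum("tkp,stp->skt", F_new, posterior.state_draws[:, 1:, :])
    else:
        paths = np.einsum("kp,stp->skt", F_new, posterior.state_draws[:, 1:, :])
    if obs_noise == "harmonic":
        var = (1.0 / posterior.phi_y_draws).mean(axis=1)  # 1 / harmonic mean
        noise = np.sqrt(var)[:, None, None] * rng.standard_normal(paths.shape)
        draws = paths + noise
    elif obs_noise == "prior":
        spec = posterior.spec
        if spec is None:
            raise ValueError("posterior has no spec; cannot draw prior noise")
        phi = rng.gamma(spec.alpha_y, 1.0 / spec.rate_y, size=S)
        draws = paths + rng.standard_normal(paths.shape) / np.sqrt(phi)[:, None, None]
    elif obs_noise == "none":
        draws = paths
    else:
        raise ValueError("obs_noise must be 'harmonic', 'prior' or 'none'")
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(draws, [a, 100 - a], axis=0)
    return VolumePredictive(draws=draws, mean=draws.mean(axis=0), lower=lo, upper=hi)
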
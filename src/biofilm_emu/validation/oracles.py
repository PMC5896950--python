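"""Brute-force reference implementations used to validate the fast code.

Everything here deliberately avoids the recursions and samplers it
checks: state-space moments come from dense joint-Gaussian conditioning,
Poisson posteriors from numeric quadrature, and the height operator from
explicit per-column loops.  These are oracles for tests — slow, simple
and written straight from the definitions.
"""
from __future__ import annotations

import numpy as np

from ..config import GridSpec
from ..height import ParticleSnapshot
from ..poisson import log_posterior


def _condition(mu, Sigma, idx_a, idx_b, y_b):
    """Gaussian conditional (a | b = y_b) by direct linear algebra."""
    mu = np.asarray(mu)
    Sigma = np.asarray(Sigma)
    Saa = Sigma[np.ix_(idx_a, idx_a)]
    Sab = Sigma[np.ix_(idx_a, idx_b)]
    Sbb = Sigma[np.ix_(idx_b, idx_b)]
    sol = np.linalg.solve(Sbb, np.column_stack([y_b - mu[idx_b]]))
    mean = mu[idx_a] + (Sab @ sol).ravel()
    cov = Saa - Sab @ np.linalg.solve(Sbb, Sab.T)
    return mean, (cov + cov.T) / 2


def dense_state_space_joint(F, G, V, W, m0, C0, T):
    """Exact joint normal of (beta_0..beta_T, Y_1..Y_T).

    Built from the linear map of the independent Gaussian block
    z = (beta_0, w_1..w_T, v_1..v_T); no filtering recursions involved.

    Returns (mu, Sigma, state_slice, obs_slice) where state_slice(t)
    gives the indices of beta_t and obs_slice(t) those of Y_t (1-based t).
    """
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
    nz = p * (T + 1) + m * T  # z dimension
    dim = p * (T + 1) + m * T  # output dimension

    # covariance of z, block diagonal
    Sz = np.zeros((nz, nz))
    Sz[:p, :p] = C0
    for t in range(T):
        s = p + t * p
        Sz[s : s + p, s : s + p] = W
    off = p * (T + 1)
    for t in range(T):
        s = off + t * m
        Sz[s : s + m, s : s + m] = V
    mu_z = np.zeros(nz)
    mu_z[:p] = np.asarray(m0, dtype=float)

    # linear map L: beta_t = G^t beta_0 + sum_{s<=t} G^{t-s} w_s; Y_t = F beta_t + v_t
    L = np.zeros((dim, nz))
    Gpow = [np.eye(p)]
    for _ in range(T):
        Gpow.append(G @ Gpow[-1])
    for t in range(T + 1):
        r = t * p
        L[r : r + p, :p] = Gpow[t]
        for s in range(1, t + 1):
            L[r : r + p, p + (s - 1) * p : p + s * p] = Gpow[t - s]
    for t in range(1, T + 1):
        r = p * (T + 1) + (t - 1) * m
        Ft = F if F.ndim == 2 else F[t - 1]
        L[r : r + m, :] = Ft @ L[t * p : (t + 1) * p, :]
        L[r : r + m, off + (t - 1) * m : off + t * m] += np.eye(m)

    mu = L @ mu_z
    Sigma = L @ Sz @ L.T

    def state_slice(t):
        return list(range(t * p, (t + 1) * p))

    def obs_slice(t):
        start = p * (T + 1) + (t - 1) * m
        return list(range(start, start + m))

    return mu, Sigma, state_slice, obs_slice


def dense_filter_moments(F, G, V, W, m0, C0, Y):
    """Filtered and one-step predictive moments by dense conditioning.

    Returns dict of arrays keyed a, R, f, Q, filtered_mean, filtered_cov
    with the same shapes as the Kalman recursion output.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y[None, :] if Y.ndim == 1 else Y
    m, T = Y.shape
    p = np.asarray(F).shape[-1]
    mu, Sigma, st, ob = dense_state_space_joint(F, G, V, W, m0, C0, T)
    out = {
        "a": np.empty((T, p)),
        "R": np.empty((T, p, p)),
        "f": np.empty((T, m)),
        "Q": np.empty((T, m, m)),
        "filtered_mean": np.empty((T, p)),
        "filtered_cov": np.empty((T, p, p)),
    }
    for t in range(1, T + 1):
        past = [i for s in range(1, t) for i in ob(s)]
        y_past = Y[:, : t - 1].T.ravel()
        # prior state / predictive observation given Y_{1:t-1}
        if past:
            out["a"][t - 1], out["R"][t - 1] = _condition(mu, Sigma, st(t), past, y_past)
            out["f"][t - 1], out["Q"][t - 1] = _condition(mu, Sigma, ob(t), past, y_past)
        else:
            out["a"][t - 1] = mu[st(t)]
            out["R"][t - 1] = Sigma[np.ix_(st(t), st(t))]
            out["f"][t - 1] = mu[ob(t)]
            out["Q"][t - 1] = Sigma[np.ix_(ob(t), ob(t))]
        upto = past + ob(t)
        y_upto = Y[:, :t].T.ravel()
        out["filtered_mean"][t - 1], out["filtered_cov"][t - 1] = _condition(
            mu, Sigma, st(t), upto, y_upto
        )
    return out


def dense_smoother_means(F, G, V, W, m0, C0, Y):
    """Smoothed state means E[beta_t | Y_1:T], t = 0..T, by dense conditioning."""
    Y = np.asarray(Y, dtype=float)
    Y = Y[None, :] if Y.ndim == 1 else Y
    m, T = Y.shape
    p = np.asarray(F).shape[-1]
    mu, Sigma, st, ob = dense_state_space_joint(F, G, V, W, m0, C0, T)
    allobs = [i for s in range(1, T + 1) for i in ob(s)]
    y_all = Y.T.ravel()
    means = np.empty((T + 1, p))
    for t in range(T + 1):
        means[t], _ = _condition(mu, Sigma, st(t), allobs, y_all)
    return means


def quadrature_poisson_posterior(X, y, prior, n_sd=10.0, n_grid=801):
    """Posterior mean/sd of a 1- or 2-coefficient Poisson model by quadrature.

    Evaluates the unnormalized posterior on a tensor grid spanning
    ``n_sd`` Laplace-approximation standard deviations around the mode
    and normalizes by trapezoidal integration.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    q = X.shape[1]
    if q > 2:
        raise ValueError("quadrature oracle supports at most 2 coefficients")

    def logpost(B):
        return log_posterior(np.asarray(B), X, y, prior)

    # mode and curvature by direct Newton on the log posterior
    B = np.zeros(q)
    for _ in range(200):
        lam = np.exp(np.clip(X @ B, -300, 300))
        grad = (
            prior.mean * prior.precision
            + X.T @ np.asarray(y, dtype=float)
            - prior.precision * B
            - X.T @ lam
        )
        hess = -(X.T @ (lam[:, None] * X)) - np.diag(prior.precision)
        step = np.linalg.solve(hess, -grad)
        while np.max(np.abs(X @ (B + step))) > 250:
            step /= 2
        B = B + step
        if np.max(np.abs(step)) < 1e-12:
            break
    sd_hat = np.sqrt(np.diag(np.linalg.inv(-hess)))
    centre = B
    axes = [
        np.linspace(c - n_sd * s, c + n_sd * s, n_grid)
        for c, s in zip(centre, sd_hat)
    ]
    if q == 1:
        lp = np.array([logpost([b]) for b in axes[0]])
        w = np.exp(lp - lp.max())
        Z = np.trapezoid(w, axes[0])
        mean = np.trapezoid(w * axes[0], axes[0]) / Z
        var = np.trapezoid(w * (axes[0] - mean) ** 2, axes[0]) / Z
        return np.array([mean]), np.sqrt([var])
    # 2-D: evaluate the log posterior over the grid in vectorized chunks
    axes = [np.linspace(c - n_sd * s, c + n_sd * s, 401) for c, s in zip(centre, sd_hat)]
    B1, B2 = np.meshgrid(axes[0], axes[1], indexing="ij")
    pts = np.column_stack([B1.ravel(), B2.ravel()])
    alpha = prior.mean * prior.precision + X.T @ np.asarray(y, dtype=float)
    lp = np.empty(len(pts))
    for s in range(0, len(pts), 20_000):
        blk = pts[s : s + 20_000]
        eta = blk @ X.T  # (chunk, n)
        lp[s : s + 20_000] = (
            blk @ alpha
            - 0.5 * np.sum(prior.precision * blk**2, axis=1)
            - np.sum(np.exp(np.clip(eta, -700, 700)), axis=1)
        )
    lp = lp.reshape(B1.shape)
    w = np.exp(lp - lp.max())
    Z = np.trapezoid(np.trapezoid(w, axes[1], axis=1), axes[0])
    means, sds = [], []
    for grid in (B1, B2):
        mean = np.trapezoid(np.trapezoid(w * grid, axes[1], axis=1), axes[0]) / Z
        var = (
            np.trapezoid(np.trapezoid(w * (grid - mean) ** 2, axes[1], axis=1), axes[0])
            / Z
        )
        means.append(mean)
        sds.append(np.sqrt(var))
    return np.array(means), np.array(sds)


def brute_force_height(
    snapshot: ParticleSnapshot, grid: GridSpec, occupied_only: bool = False
) -> float:
    """Height operator by explicit per-column loops over base blocks."""
    pos = snapshot.positions
    if len(pos) == 0:
        return 0.0
    heights = np.zeros((grid.N_x, grid.N_y))
    seen = np.zeros((grid.N_x, grid.N_y), dtype=bool)
    for ix in range(grid.N_x):
        for iy in range(grid.N_y):
            x_lo, x_hi = ix * grid.block_dx, (ix + 1) * grid.block_dx
            y_lo, y_hi = iy * grid.block_dy, (iy + 1) * grid.block_dy
            for x, y, z in pos:
                inside_x = (
                    x_lo <= x < x_hi or (ix == grid.N_x - 1 and x == x_hi)
                )
                inside_y = (
                    y_lo <= y < y_hi or (iy == grid.N_y - 1 and y == y_hi)
                )
                if inside_x and inside_y:
                    seen[ix, iy] = True
                    heights[ix, iy] = max(heights[ix, iy], z)
    if occupied_only:
        return float(heights[seen].mean()) if seen.any() else 0.0
    return float(heights.mean())
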
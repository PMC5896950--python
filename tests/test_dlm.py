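"""DLM emulator: filter vs dense-Gaussian oracle, FFBS, Gibbs conditionals."""
import numpy as np
import pytest
from scipy import stats

from biofilm_emu.dlm import (
    DLMParams,
    DLMSpec,
    ffbs_sample_states,
    gibbs_sample,
    gibbs_update_G,
    gibbs_update_variances,
    kalman_filter,
    predict_volumes,
)
from biofilm_emu.preprocess import MinMaxScaler, normalize_inputs
from biofilm_emu.synthetic import simulate_volumes
from biofilm_emu.validation.oracles import dense_filter_moments


class TestNormalize:
    def test_endpoints_map_to_zero_and_one(self, rng):
        X = rng.normal(size=(30, 3))
        Xn, scaler = normalize_inputs(X)
        assert np.allclose(Xn.min(axis=0), 0.0)
        assert np.allclose(Xn.max(axis=0), 1.0)

    def test_round_trip(self, rng):
        X = rng.uniform(-3, 9, size=(50, 4))
        Xn, scaler = normalize_inputs(X)
        assert np.max(np.abs(scaler.inverse_transform(Xn) - X)) < 1e-12

    def test_hand_computed_column(self):
        Xn, _ = normalize_inputs(np.array([[2.0], [4.0], [6.0]]))
        assert Xn.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="K_e"):
            MinMaxScaler.fit(X, names=["gamma", "K_e"])


def _random_instance(rng, m=2, p=2, T=3):
    F = rng.normal(size=(m, p))
    psi = rng.uniform(-0.9, 0.9, p)
    v = rng.uniform(0.2, 1.5, m)
    w = rng.uniform(0.1, 1.0, p)
    m0 = rng.normal(size=p)
    A = rng.normal(size=(p, p))
    C0 = A @ A.T + 0.5 * np.eye(p)
    Y, _ = simulate_volumes(F, psi, v, w, T, seed=rng, m0=m0, C0=C0)
    return F, psi, v, w, m0, C0, Y


class TestKalman:
    def test_matches_dense_joint_gaussian_oracle(self, rng):
        for _ in range(10):
            F, psi, v, w, m0, C0, Y = _random_instance(rng)
            kf = kalman_filter(F, psi, v, w, m0, C0, Y)
            oracle = dense_filter_moments(F, psi, v, w, m0, C0, Y)
            for key, ours in (
                ("f", kf.f), ("Q", kf.Q),
                ("filtered_mean", kf.filtered_mean), ("filtered_cov", kf.filtered_cov),
            ):
                assert np.max(np.abs(ours - oracle[key])) < 1e-8

    def test_static_limit_equals_batch_regression_posterior(self, rng):
        """G = I, W = 0 reduces to Bayesian linear regression on stacked data."""
        m, p, T = 3, 2, 6
        F = rng.normal(size=(m, p))
        v = np.full(m, 0.5)
        m0, C0 = rng.normal(size=p), np.eye(p)
        beta = rng.normal(size=p)
        Y = F @ np.tile(beta, (T, 1)).T + rng.normal(0, np.sqrt(0.5), (m, T))
        kf = kalman_filter(F, np.ones(p), v, np.zeros(p), m0, C0, Y)
        # closed form on the T-fold stacked design
        Xs = np.tile(F, (T, 1))
        ys = Y.T.ravel()
        prec = np.linalg.inv(C0) + Xs.T @ Xs / 0.5
        mean = np.linalg.solve(prec, np.linalg.inv(C0) @ m0 + Xs.T @ ys / 0.5)
        assert np.allclose(kf.filtered_mean[-1], mean, atol=1e-8)
        assert np.allclose(kf.filtered_cov[-1], np.linalg.inv(prec), atol=1e-8)

    def test_uninformative_observations_leave_prior_untouched(self, rng):
        F, psi, _, w, m0, C0, Y = _random_instance(rng, m=2, p=2, T=4)
        kf = kalman_filter(F, psi, np.full(2, 1e12), w, m0, C0, Y)
        assert np.allclose(kf.filtered_mean, kf.a, atol=1e-4)
        assert np.max(np.abs(kf.filtered_cov - kf.R) / (np.abs(kf.R) + 1)) < 1e-4

    def test_filtering_never_inflates_uncertainty(self, rng):
        F, psi, v, w, m0, C0, Y = _random_instance(rng, m=3, p=2, T=5)
        kf = kalman_filter(F, psi, v, w, m0, C0, Y)
        for t in range(5):
            eig = np.linalg.eigvalsh(kf.R[t] - kf.filtered_cov[t])
            assert eig.min() > -1e-10

    def test_predictive_loglik_is_sum_of_step_densities(self, rng):
        F, psi, v, w, m0, C0, Y = _random_instance(rng, m=2, p=2, T=5)
        kf = kalman_filter(F, psi, v, w, m0, C0, Y)
        direct = sum(
            stats.multivariate_normal(kf.f[t], kf.Q[t]).logpdf(Y[:, t])
            for t in range(5)
        )
        assert kf.loglik == pytest.approx(direct, abs=1e-10)

    def test_info_and_direct_forms_agree(self, rng):
        """m > p with positive V uses the Woodbury path; force the direct
        path with a zero observation variance hidden by a full matrix."""
        F, psi, v, w, m0, C0, Y = _random_instance(rng, m=6, p=2, T=4)
        fast = kalman_filter(F, psi, v, w, m0, C0, Y)
        direct = kalman_filter(F, np.diag(psi), np.diag(v), np.diag(w), m0, C0, Y)
        assert np.allclose(fast.filtered_mean, direct.filtered_mean, atol=1e-9)
        assert np.allclose(fast.loglik, direct.loglik, atol=1e-8)

    def test_time_varying_F_matches_dense_oracle(self, rng):
        m, p, T = 3, 2, 4
        Ft = rng.normal(size=(T, m, p))
        psi = rng.uniform(-0.8, 0.8, p)
        v = rng.uniform(0.2, 1.0, m)
        w = rng.uniform(0.1, 1.0, p)
        m0, C0 = rng.normal(size=p), np.eye(p)
        Y = rng.normal(size=(m, T))
        kf = kalman_filter(Ft, psi, v, w, m0, C0, Y)
        oracle = dense_filter_moments(Ft, psi, v, w, m0, C0, Y)
        for key, ours in (("f", kf.f), ("Q", kf.Q), ("filtered_mean", kf.filtered_mean)):
            assert np.max(np.abs(ours - oracle[key])) < 1e-8

    def test_constant_stack_equals_static_gibbs(self, rng):
        m, p, T = 4, 2, 6
        F = rng.uniform(0, 1, size=(m, p))
        Y = rng.normal(size=(m, T))
        a = gibbs_sample(DLMSpec(F=F), Y, n_iter=200, burn_in=50, thin=2, seed=3)
        b = gibbs_sample(
            DLMSpec(F=np.tile(F, (T, 1, 1))), Y, n_iter=200, burn_in=50, thin=2, seed=3
        )
        # identical up to BLAS summation-order noise in F' V^-1 F
        assert np.allclose(a.psi_draws, b.psi_draws, atol=1e-10)
        assert np.allclose(a.phi_y_draws, b.phi_y_draws, rtol=1e-8)

    def test_singular_predictive_covariance_reported(self):
        F = np.ones((2, 1))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            kalman_filter(
                F, np.ones(1), np.zeros(2), np.ones(1), np.zeros(1), np.eye(1),
                np.zeros((2, 3)),
            )


class TestFFBS:
    def test_frozen_evolution_gives_constant_path(self, rng):
        m, p, T = 4, 2, 8
        F = rng.normal(size=(m, p))
        Y, _ = simulate_volumes(F, np.ones(p), 0.2 * np.ones(m), np.zeros(p), T, seed=rng)
        spec = DLMSpec(F=F)
        params = DLMParams(psi=np.ones(p), phi_y=np.full(m, 5.0), phi_beta=np.full(p, 1.0))
        # zero W is expressed through the filter run with W = 0
        kf = kalman_filter(F, np.ones(p), 0.2 * np.ones(m), np.zeros(p), spec.m0, spec.C0, Y)
        states = ffbs_sample_states(spec, params, Y, seed=0, kf=kf)
        assert np.max(np.ptp(states, axis=0)) < 1e-10

    def test_terminal_draws_match_filter_law(self, rng):
        m, p, T = 3, 2, 6
        F = rng.normal(size=(m, p))
        psi = np.array([0.8, 0.4])
        v, w = 0.3 * np.ones(m), 0.4 * np.ones(p)
        Y, _ = simulate_volumes(F, psi, v, w, T, seed=rng)
        spec = DLMSpec(F=F)
        params = DLMParams(psi=psi, phi_y=1 / v, phi_beta=1 / w)
        kf = kalman_filter(F, psi, v, w, spec.m0, spec.C0, Y, store_Q=False)
        gen = np.random.default_rng(42)
        draws = np.stack(
            [ffbs_sample_states(spec, params, Y, seed=gen, kf=kf)[-1] for _ in range(5000)]
        )
        assert np.allclose(draws.mean(axis=0), kf.filtered_mean[-1], atol=0.05)
        emp = np.cov(draws.T)
        assert np.max(np.abs(emp - kf.filtered_cov[-1])) / np.max(
            np.abs(kf.filtered_cov[-1])
        ) < 0.10

    def test_seed_reproducibility(self, rng):
        F, psi, v, w, m0, C0, Y = _random_instance(rng, m=3, p=2, T=5)
        spec = DLMSpec(F=F, m0=m0, C0=C0)
        params = DLMParams(psi=psi, phi_y=1 / v, phi_beta=1 / w)
        s1 = ffbs_sample_states(spec, params, Y, seed=9)
        s2 = ffbs_sample_states(spec, params, Y, seed=9)
        assert np.array_equal(s1, s2)


class _MeanRng:
    """Stub generator whose normal() returns the conditional mean."""

    def normal(self, loc, scale=None):
        return np.asarray(loc)


class TestGibbsConditionals:
    def test_dogmatic_prior_pins_psi(self, rng):
        states = rng.normal(size=(20, 3))
        psi = gibbs_update_G(states, np.ones(3), psi0=0.7, tau0=0.0, rng=rng)
        assert (psi == 0.7).all()

    def test_recovers_ar_coefficient_from_long_path(self, rng):
        T = 500
        path = np.zeros((T + 1, 1))
        for t in range(1, T + 1):
            path[t] = 0.9 * path[t - 1] + rng.normal(0, 0.5)
        draws = np.stack(
            [gibbs_update_G(path, np.array([4.0]), 0.0, 1.0, rng) for _ in range(500)]
        )
        assert draws.mean() == pytest.approx(0.9, abs=0.05)

    def test_flat_prior_conditional_mean_is_least_squares(self, rng):
        states = rng.normal(size=(40, 2)).cumsum(axis=0)
        ls = (states[:-1] * states[1:]).sum(0) / (states[:-1] ** 2).sum(0)
        mean = gibbs_update_G(states, np.full(2, 3.0), 0.0, 1e6, _MeanRng())
        assert np.allclose(mean, ls, atol=1e-6)

    def test_zero_residuals_draw_from_prior_plus_count(self, rng):
        m, p, T = 4, 2, 30
        F = rng.normal(size=(m, p))
        states = rng.normal(size=(T + 1, p))
        psi = np.zeros(p)
        Y = (states[1:] @ F.T).T  # exact fit: zero observation residuals
        states_ar = np.vstack([np.zeros(p), np.zeros((T, p))])  # zero evolution residuals
        spec = DLMSpec(F=F, alpha_y=3.0, b_y=0.01, alpha_beta=3.0, b_beta=1.0)
        phi_y = np.stack(
            [
                gibbs_update_variances(Y, F, states, psi * 0 + 0, spec, rng)[0]
                for _ in range(2000)
            ]
        )
        # observation residuals are zero -> Gamma(alpha + T/2, b) for each row
        expected = (3.0 + T / 2) / 0.01
        assert phi_y.mean() == pytest.approx(expected, rel=0.05)
        phi_b = np.stack(
            [
                gibbs_update_variances(Y, F, states_ar, np.zeros(p), spec, rng)[1]
                for _ in range(2000)
            ]
        )
        assert phi_b.mean() == pytest.approx((3.0 + T / 2) / 1.0, rel=0.05)

    def test_precision_shrinks_with_huge_residuals(self, rng):
        m, p, T = 3, 2, 10
        F = rng.normal(size=(m, p))
        states = rng.normal(size=(T + 1, p))
        Y = (states[1:] @ F.T).T + 100.0
        spec = DLMSpec(F=F)
        phi_y, _ = gibbs_update_variances(Y, F, states, np.zeros(p), spec, rng)
        assert (phi_y < 0.01).all()


class TestGibbs:
    def test_seed_determinism(self, rng):
        F, psi, v, w, m0, C0, Y = _random_instance(rng, m=4, p=2, T=10)
        spec = DLMSpec(F=F)
        a = gibbs_sample(spec, Y, n_iter=300, burn_in=100, thin=2, seed=3)
        b = gibbs_sample(spec, Y, n_iter=300, burn_in=100, thin=2, seed=3)
        assert np.array_equal(a.psi_draws, b.psi_draws)
        assert np.array_equal(a.state_draws, b.state_draws)

    def test_single_step_panel_matches_conjugate_posterior(self, rng):
        """T = 1: the FFBS state draw is the one-step Bayes update."""
        m, p = 5, 2
        F = rng.normal(size=(m, p))
        v = np.full(m, 0.25)
        w = np.full(p, 0.5)
        psi = np.array([0.6, 0.3])
        Y, _ = simulate_volumes(F, psi, v, w, 1, seed=rng)
        spec = DLMSpec(F=F)
        params = DLMParams(psi=psi, phi_y=1 / v, phi_beta=1 / w)
        gen = np.random.default_rng(17)
        draws = np.stack(
            [ffbs_sample_states(spec, params, Y, seed=gen)[-1] for _ in range(4000)]
        )
        R = np.diag(psi) @ spec.C0 @ np.diag(psi) + np.diag(w)
        prec = np.linalg.inv(R) + F.T @ np.diag(1 / v) @ F
        C1 = np.linalg.inv(prec)
        m1 = C1 @ (F.T @ np.diag(1 / v) @ Y[:, 0])  # prior mean is zero
        assert np.allclose(draws.mean(axis=0), m1, atol=4 * np.sqrt(np.diag(C1) / 4000).max())
        assert np.max(np.abs(np.cov(draws.T) - C1)) / np.max(np.abs(C1)) < 0.10

    def test_two_chains_converge_to_same_distribution(self, rng):
        """Split-chain potential scale reduction below 1.05 on synthetic data."""
        m, p, T = 10, 2, 30
        F = rng.uniform(0, 1, size=(m, p))
        Y, _ = simulate_volumes(F, [0.8, 0.5], np.full(m, 0.04), np.full(p, 0.25), T, seed=rng)
        spec = DLMSpec(F=F, tau0=100.0, alpha_y=0.1, b_y=0.001, alpha_beta=0.1, b_beta=0.001)
        chains = [
            gibbs_sample(spec, Y, n_iter=1500, burn_in=500, thin=2, seed=s, store_states=False).psi_draws
            for s in (1, 2)
        ]
        for j in range(p):
            seqs = np.stack([c[:, j] for c in chains])
            n = seqs.shape[1]
            W_ = seqs.var(axis=1, ddof=1).mean()
            B_ = n * seqs.mean(axis=1).var(ddof=1)
            rhat = np.sqrt(((n - 1) / n * W_ + B_ / n) / W_)
            assert rhat < 1.05


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    m, p, T = 12, 3, 15
    F = rng.uniform(0, 1, size=(m, p))
    Y, beta = simulate_volumes(F, [0.9, 0.7, 0.5], np.full(m, 0.04), np.full(p, 0.1), T, seed=rng)
    spec = DLMSpec(F=F, tau0=100.0, alpha_y=0.1, b_y=0.001, alpha_beta=0.1, b_beta=0.001)
    post = gibbs_sample(spec, Y, n_iter=2000, burn_in=500, thin=3, seed=5)
    return F, Y, post


class TestPredictVolumes:

    def test_in_sample_prediction_tracks_training_row(self, fitted):
        F, Y, post = fitted
        pred = predict_volumes(post, F[2:3], seed=0)
        inside = (Y[2] >= pred.lower[0]) & (Y[2] <= pred.upper[0])
        assert inside.mean() >= 0.8

    def test_prediction_depends_on_inputs(self, fitted):
        F, Y, post = fitted
        lo = predict_volumes(post, np.zeros((1, 3)), seed=1, obs_noise="none")
        hi = predict_volumes(post, np.ones((1, 3)), seed=1, obs_noise="none")
        assert not np.allclose(lo.mean, hi.mean)

    def test_unnormalized_inputs_warn(self, fitted):
        F, Y, post = fitted
        with pytest.warns(UserWarning, match="un-normalized"):
            predict_volumes(post, np.full((1, 3), 25.0), seed=2)

    def test_interval_ordering(self, fitted):
        F, Y, post = fitted
        pred = predict_volumes(post, F[:3], seed=3)
        assert (pred.lower <= pred.mean).all() and (pred.mean <= pred.upper).all()
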
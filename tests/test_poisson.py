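"""Poisson emulator: pmf, exact log posterior, Metropolis sampler, prediction."""
import numpy as np
import pytest
from scipy import stats

from biofilm_emu.basis import build_quadratic_features
from biofilm_emu.poisson import (
    PoissonPosterior,
    PoissonPrior,
    ergodic_diagnostics,
    log_likelihood,
    log_posterior,
    mcse_mean,
    metropolis_sample,
    poisson_mle,
    poisson_pmf,
    predict_counts,
)
from biofilm_emu.validation.oracles import quadrature_poisson_posterior


class TestPmf:
    def test_closed_form_at_zero(self):
        assert poisson_pmf(0, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_normalizes(self):
        ks = np.arange(201)
        assert poisson_pmf(ks, 3.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_and_variance_equal_lambda(self):
        ks = np.arange(400)
        p = poisson_pmf(ks, 7.0)
        mean = (ks * p).sum()
        var = ((ks - mean) ** 2 * p).sum()
        assert mean == pytest.approx(7.0, abs=1e-9)
        assert var == pytest.approx(7.0, abs=1e-9)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            poisson_pmf(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_pmf(3, 0.0)
        with pytest.raises(ValueError):
            poisson_pmf(2.5, 1.0)


class TestLogPosterior:
    def test_flat_prior_equals_likelihood_up_to_constant(self, rng):
        X = rng.uniform(0, 1, size=(50, 3))
        y = rng.poisson(2.0, 50)
        prior = PoissonPrior.flat(3)
        diffs = [
            log_posterior(B, X, y, prior) - log_likelihood(B, X, y)
            for B in rng.normal(0, 0.5, size=(5, 3))
        ]
        assert np.ptp(diffs) < 1e-8

    def test_value_at_zero_coefficients(self, rng):
        n = 37
        X = rng.uniform(0, 1, size=(n, 2))
        y = rng.poisson(1.5, n)
        # alpha . 0 - 0 - sum_k exp(0) = -n under a flat prior
        assert log_posterior(np.zeros(2), X, y, PoissonPrior.flat(2)) == pytest.approx(-n)

    def test_informative_prior_penalty(self, rng):
        X = rng.uniform(0, 1, size=(10, 1))
        y = rng.poisson(2.0, 10)
        flat = PoissonPrior.flat(1)
        tight = PoissonPrior(mean=np.array([0.5]), precision=np.array([100.0]))
        B = np.array([2.0])
        # quadratic penalty plus the alpha shift from m_i / v_i
        expected = -0.5 * 100 * 2.0**2 + 100 * 0.5 * 2.0
        got = log_posterior(B, X, y, tight) - log_posterior(B, X, y, flat)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_normalized_density_integrates_to_one(self):
        # 1-coefficient intercept model with y = (2, 3)
        X = np.ones((2, 1))
        y = np.array([2, 3])
        prior = PoissonPrior.flat(1)
        grid = np.linspace(-5, 5, 20_001)
        lp = np.array([log_posterior(np.array([b]), X, y, prior) for b in grid])
        w = np.exp(lp - lp.max())
        dens = w / np.trapezoid(w, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_overflow_returns_neg_inf_not_nan(self):
        X = np.full((3, 1), 100.0)
        y = np.array([1, 2, 3])
        val = log_posterior(np.array([50.0]), X, y, PoissonPrior.flat(1))
        assert val == -np.inf

    def test_concavity_under_flat_prior(self, rng):
        """Poisson log likelihood is concave: midpoint above the min."""
        X = rng.uniform(0, 1, size=(40, 4))
        y = rng.poisson(3.0, 40)
        prior = PoissonPrior.flat(4)
        for _ in range(20):
            B1, B2 = rng.normal(0, 1.0, size=(2, 4))
            f1 = log_posterior(B1, X, y, prior)
            f2 = log_posterior(B2, X, y, prior)
            fm = log_posterior((B1 + B2) / 2, X, y, prior)
            assert fm >= min(f1, f2) - 1e-9

    def test_counts_must_be_nonnegative_integers(self, rng):
        X = rng.uniform(0, 1, size=(5, 2))
        with pytest.raises(ValueError, match="non-negative integers"):
            log_posterior(np.zeros(2), X, np.array([1.0, 2.5, 0, 1, 1]), PoissonPrior.flat(2))


class TestMle:
    def test_matches_glm_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 1, size=(600, 2))
        basis = build_quadratic_features(x)
        B_true = np.array([0.5, 0.8, -0.6, 0.4, 0.5, -0.3])
        y = rng.poisson(np.exp(basis.matrix @ B_true))
        B_hat, _ = poisson_mle(basis.matrix, y)
        ref = sm.GLM(y, basis.matrix, family=sm.families.Poisson()).fit()
        assert np.allclose(B_hat, ref.params, atol=1e-6)

    def test_all_zero_counts_floored(self):
        X = np.ones((20, 1))
        B_hat, _ = poisson_mle(X, np.zeros(20))
        assert B_hat[0] == pytest.approx(np.log(1e-8), rel=0.2)

    def test_collinear_columns_rejected(self, rng):
        x = rng.uniform(0, 1, 50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            poisson_mle(X, rng.poisson(2.0, 50))


class TestMetropolis:
    def test_zero_proposal_scale_freezes_chain_at_mle(self, rng):
        X = np.ones((50, 1))
        y = rng.poisson(4.0, 50)
        B_mle, _ = poisson_mle(X, y)
        post = metropolis_sample(
            X, y, n_iter=500, burn_in=100, thin=5, seed=0, proposal_scale=0, adapt=False
        )
        assert np.allclose(post.draws, B_mle[None, :])

    def test_seed_determinism(self, rng):
        x = rng.uniform(0, 1, size=(100, 1))
        X = np.column_stack([np.ones(100), x])
        y = rng.poisson(np.exp(0.5 + x[:, 0]))
        a = metropolis_sample(X, y, n_iter=2000, burn_in=500, thin=2, seed=7)
        b = metropolis_sample(X, y, n_iter=2000, burn_in=500, thin=2, seed=7)
        c = metropolis_sample(X, y, n_iter=2000, burn_in=500, thin=2, seed=8)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(a.draws, c.draws)
        assert 0 < a.acceptance_rate < 1

    def test_intercept_posterior_rate_matches_quadrature(self, rng):
        """E[exp(beta0) | y] from the chain vs the quadrature oracle."""
        y = rng.poisson(4.0, 200)
        X = np.ones((200, 1))
        post = metropolis_sample(X, y, n_iter=40_000, burn_in=2_000, thin=5, seed=3)
        grid_mean, _ = quadrature_poisson_posterior(X, y, PoissonPrior.flat(1))
        # quadrature mean of exp(beta) via the same oracle densities
        grid = np.linspace(grid_mean[0] - 1, grid_mean[0] + 1, 10_001)
        lp = np.array(
            [log_posterior(np.array([b]), X, y, PoissonPrior.flat(1)) for b in grid]
        )
        w = np.exp(lp - lp.max())
        rate_quad = np.trapezoid(w * np.exp(grid), grid) / np.trapezoid(w, grid)
        rates = np.exp(post.draws[:, 0])
        assert abs(rates.mean() - rate_quad) < 2 * mcse_mean(rates)

    def test_flat_prior_posterior_mean_near_mle(self, rng):
        x = rng.uniform(0, 1, size=(600, 2))
        basis = build_quadratic_features(x)
        y = rng.poisson(np.exp(basis.matrix @ np.array([0.5, 0.8, -0.6, 0.4, 0.5, -0.3])))
        B_mle, _ = poisson_mle(basis.matrix, y)
        post = metropolis_sample(basis, y, n_iter=12_000, burn_in=2_000, thin=5, seed=5)
        assert (np.abs(post.mean() - B_mle) < 2 * post.sd()).all()

    def test_chain_histogram_matches_target_density(self, rng):
        """Kolmogorov-Smirnov distance to the quadrature-normalized
        1-D posterior below 0.03 at 1e5 draws (detailed-balance smoke)."""
        y = rng.poisson(3.0, 50)
        X = np.ones((50, 1))
        post = metropolis_sample(X, y, n_iter=101_000, burn_in=1_000, thin=1, seed=11)
        draws = np.sort(post.draws[:, 0])
        grid = np.linspace(draws[0] - 0.3, draws[-1] + 0.3, 4001)
        lp = np.array(
            [log_posterior(np.array([b]), X, y, PoissonPrior.flat(1)) for b in grid]
        )
        w = np.exp(lp - lp.max())
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        target_cdf = np.interp(draws, grid, cdf)
        empirical = np.arange(1, len(draws) + 1) / len(draws)
        ks = np.max(np.abs(empirical - target_cdf))
        assert ks < 0.03


class TestPredict:
    def _collapsed_posterior(self, q=2):
        return PoissonPosterior(
            draws=np.zeros((500, q)),
            acceptance_rate=0.2,
            n_iter=1,
            burn_in=0,
            thin=1,
            seed=0,
            alpha=np.zeros(q),
        )

    def test_collapsed_at_zero_gives_unit_rate(self, rng):
        post = self._collapsed_posterior()
        pred = predict_counts(post, rng.uniform(0, 1, size=(10, 2)), seed=0)
        assert np.allclose(pred.lambda_draws, 1.0)
        assert (pred.upper <= 4).all() and (pred.lower == 0).all()

    def test_total_expectation_identity(self, rng):
        x = rng.uniform(0, 1, size=(150, 1))
        X = np.column_stack([np.ones(150), x])
        y = rng.poisson(np.exp(0.8 + 0.7 * x[:, 0]))
        post = metropolis_sample(X, y, n_iter=11_000, burn_in=1_000, thin=5, seed=2)
        pred = predict_counts(post, X, seed=4)
        lam_mean = pred.lambda_draws.mean()
        count_mean = pred.count_draws.mean()
        se = pred.count_draws.std() / np.sqrt(pred.count_draws.size)
        assert abs(count_mean - lam_mean) < 4 * se

    def test_heldout_calibration(self, rng):
        """>= 90% of fresh counts fall in the 95% predictive intervals."""
        B_true = np.array([0.5, 0.8, -0.6, 0.4, 0.5, -0.3])
        x = rng.uniform(0, 1, size=(600, 2))
        basis = build_quadratic_features(x)
        y = rng.poisson(np.exp(basis.matrix @ B_true))
        post = metropolis_sample(basis, y, n_iter=9_000, burn_in=2_000, thin=3, seed=6)
        x_new = rng.uniform(0, 1, size=(200, 2))
        basis_new = build_quadratic_features(x_new)
        y_new = rng.poisson(np.exp(basis_new.matrix @ B_true))
        pred = predict_counts(post, basis_new, seed=7)
        coverage = np.mean((y_new >= pred.lower) & (y_new <= pred.upper))
        assert coverage >= 0.90

    def test_basis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            predict_counts(self._collapsed_posterior(2), np.zeros((3, 5)))


class TestErgodic:
    def test_constant_chain(self):
        diag = ergodic_diagnostics(np.full((200, 1), 2.5), n_batches=10)
        assert (diag.running_mean == 2.5).all()
        assert diag.batch_se[0] == 0.0

    def test_iid_normal_batch_se_in_theoretical_window(self, rng):
        chain = rng.standard_normal((10_000, 1))
        diag = ergodic_diagnostics(chain, n_batches=100)
        assert 0.005 <= diag.batch_se[0] <= 0.02  # theory: 0.01

    def test_final_running_mean_is_plain_mean(self, rng):
        chain = rng.normal(size=(500, 2))
        diag = ergodic_diagnostics(chain, n_batches=10)
        assert np.allclose(diag.running_mean[-1], chain.mean(axis=0))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ergodic_diagnostics(np.zeros((10, 1)), n_batches=10)
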
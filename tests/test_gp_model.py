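import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from plumefall.gp_model import (
    ConvergenceError,
    Hyperparams,
    ModelConfig,
    PosteriorDraws,
    build_covariance,
    fit_arrays,
    inverse_transform,
    kernel_periodic,
    kernel_se,
    marginal_loglik,
    quarter_transform,
)


class TestQuarterTransform:
    def test_forward_and_inverse(self):
        assert quarter_transform(16.0) == pytest.approx(2.0)
        assert inverse_transform(2.0) == pytest.approx(16.0)

    def test_round_trip(self):
        assert inverse_transform(quarter_transform(137.2)) == pytest.approx(137.2, rel=1e-10)

    def test_median_shift_effect(self):
        # an additive +/-0.5 on the quarter scale at 140 mg/kg moves the raw
        # concentration by about +100 / -65 mg/kg
        y = quarter_transform(140.0)
        up = inverse_transform(y + 0.5) - 140.0
        down = inverse_transform(y - 0.5) - 140.0
        assert round(up / 5) * 5 == 100
        assert round(down / 5) * 5 == -65

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quarter_transform(0.0)
        with pytest.raises(ValueError):
            inverse_transform(-1.0)


class TestKernels:
    def test_se_identity_and_closed_form(self):
        assert kernel_se(0.7, 0.7, 2.0) == pytest.approx(1.0)
        assert kernel_se(0.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    def test_periodic_closed_forms(self):
        assert kernel_periodic(123.0, 123.0 + 360.0, 0.7) == pytest.approx(1.0)
        assert kernel_periodic(0.0, 180.0, 1.0) == pytest.approx(np.exp(-2.0))
        assert kernel_periodic(10.0, 350.0, 0.8) == pytest.approx(kernel_periodic(0.0, 20.0, 0.8))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 2), b=st.floats(0, 2),
        t1=st.floats(0, 360), t2=st.floats(0, 360),
        rho=st.floats(0.05, 3),
    )
    def test_symmetry_and_range(self, a, b, t1, t2, rho):
        kse = kernel_se(a, b, rho)
        kp = kernel_periodic(t1, t2, rho)
        assert kse == pytest.approx(kernel_se(b, a, rho))
        assert kp == pytest.approx(kernel_periodic(t2, t1, rho))
        # exact zero only through floating-point underflow at extreme lags
        assert 0 <= kse <= 1 and 0 <= kp <= 1

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            kernel_se(0, 1, 0.0)
        with pytest.raises(ValueError):
            kernel_periodic(0, 1, -1.0)


class TestBuildCovariance:
    def test_single_point(self, hp):
        K = build_covariance(np.array([0.5]), np.array([10.0]), hp, jitter=1e-6)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(hp.alpha + 1e-6)

    def test_diagonal_equals_alpha_plus_jitter(self, hp):
        rng = np.random.default_rng(1)
        K = build_covariance(rng.uniform(0.1, 1.5, 20), rng.uniform(0, 360, 20), hp, 1e-8)
        assert np.allclose(np.diag(K), hp.alpha + 1e-8)

    def test_positive_semidefinite_on_random_points(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            hp = Hyperparams(
                mu=np.zeros(5),
                alpha=float(rng.uniform(0.1, 5)),
                rho_r=float(rng.uniform(0.05, 2)),
                rho_theta=float(rng.uniform(0.05, 2)),
                sigma=0.3,
            )
            K = build_covariance(rng.uniform(0, 2, 50), rng.uniform(0, 360, 50), hp)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestHyperparams:
    def test_zero_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to zero"):
            Hyperparams(mu=np.array([1.0, 0, 0, 0, 0]), alpha=1, rho_r=1, rho_theta=1, sigma=1)

    def test_positive_scales_enforced(self):
        with pytest.raises(ValueError, match="alpha"):
            Hyperparams(mu=np.zeros(5), alpha=0, rho_r=1, rho_theta=1, sigma=1)


class TestMarginalLikelihood:
    def _data(self, n=25, seed=3):
        rng = np.random.default_rng(seed)
        return (
            rng.uniform(0.1, 1.5, n),
            rng.uniform(0, 360, n),
            rng.integers(0, 5, n),
            rng.normal(3.5, 1.0, n),
        )

    def test_matches_dense_mvn_oracle(self, hp):
        r, theta, k, y = self._data()
        ours = marginal_loglik(y, r, theta, k, hp, jitter_frac=1e-9)
        # independent oracle: explicit alpha*K + sigma^2 I through scipy
        dr2 = (r[:, None] - r[None, :]) ** 2
        s2 = np.sin(np.pi * np.abs(theta[:, None] - theta[None, :]) / 360.0) ** 2
        cov = hp.alpha * np.exp(-dr2 / hp.rho_r ** 2 - 2 * s2 / hp.rho_theta ** 2)
        cov += (hp.sigma ** 2 + 1e-9 * hp.alpha) * np.eye(r.size)
        ref = multivariate_normal(mean=hp.mu[k], cov=cov).logpdf(y)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_invariant_under_sample_reordering(self, hp):
        r, theta, k, y = self._data()
        perm = np.random.default_rng(0).permutation(r.size)
        a = marginal_loglik(y, r, theta, k, hp)
        b = marginal_loglik(y[perm], r[perm], theta[perm], k[perm], hp)
        assert a == pytest.approx(b, rel=1e-12)

    def test_vanishing_alpha_reduces_to_anova_likelihood(self, hp):
        # with alpha -> 0 the GP disappears and the model is iid
        # N(mu_k, sigma^2) per observation
        from scipy.stats import norm

        r, theta, k, y = self._data()
        tiny = Hyperparams(mu=hp.mu, alpha=1e-12, rho_r=hp.rho_r,
                           rho_theta=hp.rho_theta, sigma=hp.sigma)
        ours = marginal_loglik(y, r, theta, k, tiny, jitter_frac=0.0)
        ref = norm(loc=hp.mu[k], scale=hp.sigma).logpdf(y).sum()
        assert ours == pytest.approx(ref, abs=1e-6)


class TestFit:
    def test_draws_satisfy_zero_sum_and_count(self):
        rng = np.random.default_rng(5)
        n = 30
        r = rng.uniform(0.1, 1.5, n)
        theta = rng.uniform(0, 360, n)
        k = rng.integers(0, 5, n)
        y = 3.5 + 0.5 * np.cos(np.deg2rad(theta)) + rng.normal(0, 0.4, n)
        cfg = ModelConfig(iterations=800, ess_min=50)
        draws = fit_arrays(y, r, theta, k, config=cfg, seed=1)
        assert draws.n_draws == cfg.n_retained
        assert np.allclose(draws.mu.sum(axis=1), 0.0, atol=1e-10)
        assert (draws.alpha > 0).all() and (draws.sigma > 0).all()
        assert draws.diagnostics["max_rhat"] <= cfg.rhat_max

    def test_prior_only_soil_offsets_have_projected_sd(self):
        # under the sum-to-zero constraint the N(0,1) offsets become
        # N(0, I - J/5): each coordinate has sd sqrt(4/5)
        rng = np.random.default_rng(6)
        cfg = ModelConfig(iterations=4000, likelihood=False, ess_min=50)
        draws = fit_arrays(
            np.zeros(4), rng.uniform(0.1, 1.5, 4), rng.uniform(0, 360, 4),
            np.arange(4) % 5, config=cfg, seed=2,
        )
        sds = draws.mu.std(axis=0, ddof=1)
        assert np.allclose(sds, np.sqrt(0.8), atol=0.06)
        assert abs(draws.mu.mean()) < 0.05

    def test_unconverged_chains_fail_loudly(self):
        rng = np.random.default_rng(7)
        n = 20
        y = rng.normal(3.5, 1.0, n)
        cfg = ModelConfig(iterations=400, ess_min=1e9)  # unreachable ESS floor
        with pytest.raises(ConvergenceError) as exc:
            fit_arrays(y, rng.uniform(0.1, 1.5, n), rng.uniform(0, 360, n),
                       rng.integers(0, 5, n), config=cfg, seed=3)
        assert "min_ess" in exc.value.diagnostics

    def test_duplicate_locations_rejected(self):
        cfg = ModelConfig(iterations=100)
        with pytest.raises(ValueError, match="distinct"):
            fit_arrays(np.array([1.0, 2.0]), np.array([0.5, 0.5]),
                       np.array([10.0, 10.0]), np.array([0, 1]), config=cfg, seed=0)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        n, m = 6, 11
        mu_free = rng.normal(0, 0.5, (m, 4))
        mu = np.column_stack([mu_free, -mu_free.sum(axis=1)])
        draws = PosteriorDraws(
            mu=mu,
            alpha=rng.uniform(0.5, 1.5, m),
            rho_r=rng.uniform(0.2, 1, m),
            rho_theta=rng.uniform(0.2, 1, m),
            sigma=rng.uniform(0.1, 0.5, m),
            f=rng.normal(0, 1, (m, n)),
            r=rng.uniform(0.1, 1.5, n),
            theta=rng.uniform(0, 360, n),
            y_t=rng.normal(3.5, 1, n),
            k_idx=rng.integers(0, 5, n),
            diagnostics={},
        )
        dpath, xpath = tmp_path / "draws.csv", tmp_path / "data.csv"
        draws.to_csv(dpath, xpath)
        back = PosteriorDraws.from_csv(dpath, xpath)
        assert np.allclose(back.f, draws.f)
        assert np.allclose(back.mu, draws.mu)
        assert np.allclose(back.r, draws.r)
        assert np.array_equal(back.k_idx, draws.k_idx)
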
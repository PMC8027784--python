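import numpy as np
import pytest

from plumefall.geometry import make_grid
from plumefall.gp_model import Hyperparams, PosteriorDraws, build_covariance, cross_covariance
from plumefall.prediction import back_transform_field, predict_f, predict_y


def make_draws(hp, r, theta, f, n_draws=1, jitter_frac=1e-9, sigma=None):
    """PosteriorDraws with every draw fixed at one parameter set."""
    m = n_draws
    n = np.asarray(r).size
    f = np.broadcast_to(np.asarray(f, dtype=float), (m, n)).copy()
    sig = hp.sigma if sigma is None else sigma
    return PosteriorDraws(
        mu=np.broadcast_to(hp.mu, (m, 5)).copy(),
        alpha=np.full(m, hp.alpha),
        rho_r=np.full(m, hp.rho_r),
        rho_theta=np.full(m, hp.rho_theta),
        sigma=np.full(m, sig),
        f=f,
        r=np.asarray(r, dtype=float),
        theta=np.asarray(theta, dtype=float),
        y_t=f[0].copy(),
        k_idx=np.zeros(n, dtype=int),
        diagnostics={},
        jitter_frac=jitter_frac,
    )


@pytest.fixture
def five_points(hp):
    rng = np.random.default_rng(0)
    r = rng.uniform(0.2, 1.4, 5)
    theta = rng.uniform(0, 360, 5)
    K = build_covariance(r, theta, hp, jitter=1e-10)
    f = np.linalg.cholesky(K) @ rng.standard_normal(5)
    return r, theta, f


class TestPredictF:
    def test_conditional_matches_dense_joint_oracle(self, hp, five_points):
        """5 training + 3 grid points: GP conditioning must equal brute-force
        conditioning of the 8x8 joint Gaussian."""
        r, theta, f = five_points
        gr = np.array([0.3, 0.8, 1.3])
        gt = np.array([15.0, 250.0, 300.0])

        # oracle: build the full 8x8 covariance and condition numerically
        allr, allt = np.concatenate([gr, r]), np.concatenate([gt, theta])
        J = build_covariance(allr, allt, hp)
        Kgg, Kgd, Kdd = J[:3, :3], J[:3, 3:], J[3:, 3:]
        mean_ref = Kgd @ np.linalg.solve(Kdd, f)
        cov_ref = Kgg - Kgd @ np.linalg.solve(Kdd, Kgd.T)

        # implementation path: many draws at frozen hyperparameters
        draws = make_draws(hp, r, theta, f, n_draws=4000, jitter_frac=0.0)
        from plumefall.geometry import PolarGrid

        grid = PolarGrid(r_values=gr, theta_values=gt, r=gr, theta=gt)
        field = predict_f(draws, grid, seed=1)
        mean_mc = field.f_draws.mean(axis=0)
        cov_mc = np.cov(field.f_draws.T)

        # the conditional mean is deterministic: tight tolerance via MC mean
        assert np.allclose(mean_mc, mean_ref, atol=4 * np.sqrt(np.diag(cov_ref) / 4000).max())
        assert np.allclose(cov_mc, cov_ref, atol=0.05 * hp.alpha)

    def test_exact_conditional_moments_against_oracle(self, hp, five_points):
        """The internal conditional mean/cov formulas agree with the dense
        oracle to 1e-8 (deterministic check, no sampling)."""
        r, theta, f = five_points
        gr = np.array([0.3, 0.8, 1.3])
        gt = np.array([15.0, 250.0, 300.0])
        Kdd = build_covariance(r, theta, hp)
        Kgd = cross_covariance(gr, gt, r, theta, hp)
        Kgg = build_covariance(gr, gt, hp)
        mean = Kgd @ np.linalg.solve(Kdd, f)
        cov = Kgg - Kgd @ np.linalg.solve(Kdd, Kgd.T)

        allr, allt = np.concatenate([gr, r]), np.concatenate([gt, theta])
        J = build_covariance(allr, allt, hp)
        mean_ref = J[:3, 3:] @ np.linalg.solve(J[3:, 3:], f)
        cov_ref = J[:3, :3] - J[:3, 3:] @ np.linalg.solve(J[3:, 3:], J[3:, :3])
        assert np.allclose(mean, mean_ref, atol=1e-8)
        assert np.allclose(cov, cov_ref, atol=1e-8)

    def test_interpolates_latent_field_at_data_location(self, hp):
        r = np.array([0.4, 0.7, 1.0, 1.2])
        theta = np.array([10.0, 100.0, 200.0, 300.0])
        f = np.array([0.5, -0.2, 0.8, 0.1])
        draws = make_draws(hp, r, theta, f, n_draws=50, jitter_frac=1e-12)
        from plumefall.geometry import PolarGrid

        grid = PolarGrid(
            r_values=np.array([0.7]), theta_values=np.array([100.0]),
            r=np.array([0.7]), theta=np.array([100.0]),
        )
        field = predict_f(draws, grid, seed=0)
        assert np.allclose(field.f_draws, -0.2, atol=1e-3)

    def test_prior_predictive_with_no_data(self, hp):
        empty = make_draws(hp, np.empty(0), np.empty(0), np.empty((1, 0)), n_draws=3000)
        grid = make_grid(0.1, 1.5, 4)
        field = predict_f(empty, grid, seed=2)
        assert np.allclose(field.f_draws.mean(axis=0), 0.0, atol=4 * np.sqrt(hp.alpha / 3000) * 2)
        assert np.allclose(field.f_draws.var(axis=0), hp.alpha, rtol=0.15)

    def test_near_source_rings_excluded_with_warning(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=2)
        grid = make_grid(0.02, 1.5, 5)
        with pytest.warns(UserWarning, match="excluding"):
            field = predict_f(draws, grid, seed=0)
        assert field.grid.r_values.min() >= 0.1
        with pytest.raises(ValueError, match="below"):
            predict_f(draws, grid, seed=0, strict=True)

    def test_uncertainty_grows_away_from_data(self, hp):
        # data clustered at one bearing: predictive sd across draws must be
        # larger on the far side of the circle
        rng = np.random.default_rng(3)
        r = np.full(10, 0.7)
        theta = rng.uniform(260, 310, 10)
        f = rng.normal(0, 0.5, 10)
        draws = make_draws(hp, r, theta, f, n_draws=800)
        from plumefall.geometry import PolarGrid

        gr = np.array([0.7, 0.7])
        gt = np.array([285.0, 105.0])
        grid = PolarGrid(r_values=np.array([0.7]), theta_values=gt, r=gr, theta=gt)
        field = predict_f(draws, grid, seed=4)
        sd = field.f_draws.std(axis=0)
        assert sd[1] > 2 * sd[0]

    def test_periodic_across_bearing_seam(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=600)
        from plumefall.geometry import PolarGrid

        def field_at(bearing):
            grid = PolarGrid(
                r_values=np.array([0.9]), theta_values=np.array([bearing]),
                r=np.array([0.9]), theta=np.array([bearing]),
            )
            return predict_f(draws, grid, seed=5).f_draws

        lo = field_at(1e-7)
        hi = field_at(360.0 - 1e-7)
        assert np.allclose(lo.mean(), hi.mean(), atol=1e-3)

    def test_more_data_never_inflates_variance(self, hp):
        rng = np.random.default_rng(6)
        r = rng.uniform(0.2, 1.4, 12)
        theta = rng.uniform(0, 360, 12)
        K = build_covariance(r, theta, hp, jitter=1e-10)
        f = np.linalg.cholesky(K) @ rng.standard_normal(12)
        grid = make_grid(0.2, 1.4, 5)

        def pred_var(k):
            draws = make_draws(hp, r[:k], theta[:k], f[:k], n_draws=1500)
            return predict_f(draws, grid, seed=7).f_draws.var(axis=0)

        v6, v12 = pred_var(6), pred_var(12)
        assert (v12 <= v6 + 0.08 * hp.alpha).all()  # MC slack


class TestPredictY:
    def test_zero_sigma_is_identity(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=20, sigma=1e-300)
        field = predict_f(draws, make_grid(0.2, 1.2, 4), seed=8)
        field = predict_y(field, draws, seed=9)
        assert np.allclose(field.y_draws, field.f_draws, atol=1e-12)

    def test_noise_variance_matches_sigma(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=6000)
        field = predict_f(draws, make_grid(0.2, 1.2, 3), seed=10, thin=6000)
        field = predict_y(field, draws, seed=11)
        resid = field.y_draws - field.f_draws
        assert np.allclose(resid.var(axis=0), hp.sigma ** 2, rtol=0.1)
        assert np.allclose(
            field.y_draws.mean(axis=0), field.f_draws.mean(axis=0),
            atol=4 * hp.sigma / np.sqrt(6000),
        )


class TestBackTransform:
    def _const_field(self, hp, value, n_draws=9):
        draws = make_draws(hp, np.array([0.5]), np.array([0.0]), np.array([0.0]), 1)
        grid = make_grid(0.2, 1.2, 3)
        from plumefall.prediction import FieldGrid

        return FieldGrid(
            grid=grid,
            f_draws=np.full((n_draws, grid.n_locations), value),
            sigma=np.full(n_draws, hp.sigma),
            draw_indices=np.arange(n_draws),
        )

    def test_constant_draws(self, hp):
        field = self._const_field(hp, 2.0)
        summ = back_transform_field(field)
        assert np.allclose(summ.table["mean"], 16.0)
        for q in ("q10", "q25", "q75", "q90"):
            assert np.allclose(summ.table[q], 16.0)

    def test_quantiles_monotone(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=400)
        field = predict_f(draws, make_grid(0.2, 1.2, 4), seed=12)
        t = back_transform_field(field).table
        assert (t["q10"] <= t["q25"]).all()
        assert (t["q25"] <= t["q75"]).all()
        assert (t["q75"] <= t["q90"]).all()

    def test_median_commutes_with_monotone_transform(self, hp, five_points):
        r, theta, f = five_points
        draws = make_draws(hp, r, theta, f, n_draws=401)
        field = predict_f(draws, make_grid(0.2, 1.2, 4), seed=13)
        field.f_draws = np.abs(field.f_draws)  # restrict to the monotone branch
        t = back_transform_field(field, quantile_levels=(50,)).table
        med_f = np.percentile(field.f_draws, 50, axis=0)
        assert np.allclose(t["q50"], med_f ** 4, rtol=1e-10)

    def test_sign_preserving_flag(self, hp):
        field = self._const_field(hp, -1.5)
        literal = back_transform_field(field)
        clipped = back_transform_field(field, sign_preserving=True)
        assert np.allclose(literal.table["mean"], (-1.5) ** 4)
        assert np.allclose(clipped.table["mean"], 0.0)
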
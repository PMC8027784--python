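"""Hierarchical Bayesian GP regression of surface-soil Pb around a point source.

Model
-----
Concentrations are modelled on the quarter-power scale, ``y = Pb^(1/4)``,
which stabilises the heavy right tail of field XRF data more gently than a
log. For sample i with soil type k[i] at polar location (r_i, theta_i):

    y_i = mu_{k[i]} + f(r_i, theta_i) + eps_i,     eps_i ~ N(0, sigma^2)

* ``mu_k`` — five soil-type offsets under a sum-to-zero constraint
  (identifiability: a constant can otherwise shuttle between mu and f),
  each with a N(0, 1) prior on the constrained vector.
* ``f`` — a zero-mean Gaussian process with product kernel

      Cov(f(r1,t1), f(r2,t2)) = alpha * K1(r1,r2) * K2(t1,t2)
      K1 = exp(-(r1-r2)^2 / rho_r^2)                       (squared exponential)
      K2 = exp(-2 sin^2(pi |t1-t2| / 360) / rho_theta^2)   (periodic, 360 deg)

  so the fitted surface is smooth in distance and continuous across the
  0/360 bearing seam.
* Half-normal priors on the scales: rho_r ~ N+(0, 1.5^2) km,
  rho_theta ~ N+(0, 1), alpha, sigma ~ N+(0, 6^2) (transformed units).

Inference marginalises f analytically — y ~ N(mu_{k}, alpha*K + sigma^2 I) —
and samples the 8 remaining parameters (4 free offsets + 4 scales) with an
affine-invariant ensemble sampler, then draws the latent vector f at the
data locations exactly from its conditional Gaussian for each retained
posterior draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .geometry import Sector
from .sample_io import SOIL_TYPES, SoilSample

__all__ = [
    "quarter_transform",
    "inverse_transform",
    "kernel_se",
    "kernel_periodic",
    "build_covariance",
    "cross_covariance",
    "marginal_loglik",
    "Hyperparams",
    "ModelConfig",
    "PosteriorDraws",
    "ConvergenceError",
    "fit",
    "fit_arrays",
]

N_TYPES = len(SOIL_TYPES)


# --------------------------------------------------------------------------
# outcome transform
# --------------------------------------------------------------------------

def quarter_transform(pb):
    """Quarter-power transform, mg/kg -> (mg/kg)^(1/4)."""
    pb = np.asarray(pb, dtype=float)
    if np.any(pb <= 0):
        raise ValueError("Pb concentrations must be positive")
    out = pb ** 0.25
    return float(out) if out.ndim == 0 else out


def inverse_transform(y):
    """Back-transform, (mg/kg)^(1/4) -> mg/kg."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("transformed values must be non-negative")
    out = y ** 4
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def kernel_se(r1, r2, rho_r: float):
    """Squared-exponential kernel in distance: exp(-(r1-r2)^2 / rho_r^2)."""
    if rho_r <= 0:
        raise ValueError("rho_r must be positive")
    d = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    return np.exp(-(d ** 2) / rho_r ** 2)


def kernel_periodic(theta1, theta2, rho_theta: float):
    """Periodic kernel in bearing with period 360 degrees."""
    if rho_theta <= 0:
        raise ValueError("rho_theta must be positive")
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float))
    s = np.sin(np.pi * d / 360.0)
    return np.exp(-2.0 * s ** 2 / rho_theta ** 2)


def _cross_kernel(r1, t1, r2, t2, alpha, rho_r, rho_theta):
    """alpha * K1 * K2 between two point sets (vectorised outer product)."""
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))
    dr2 = (r1[:, None] - r2[None, :]) ** 2
    s2 = np.sin(np.pi * np.abs(t1[:, None] - t2[None, :]) / 360.0) ** 2
    return alpha * np.exp(-dr2 / rho_r ** 2 - 2.0 * s2 / rho_theta ** 2)


def build_covariance(r, theta, hp: "Hyperparams", jitter: float = 0.0) -> np.ndarray:
    """Product-kernel covariance at a point set, plus diagonal jitter."""
    K = _cross_kernel(r, theta, r, theta, hp.alpha, hp.rho_r, hp.rho_theta)
    if jitter:
        K[np.diag_indices_from(K)] += jitter
    return K


def cross_covariance(r1, t1, r2, t2, hp: "Hyperparams") -> np.ndarray:
    """Product-kernel covariance between two point sets."""
    return _cross_kernel(r1, t1, r2, t2, hp.alpha, hp.rho_r, hp.rho_theta)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparams:
    """One parameter set: soil offsets (sum-to-zero) and kernel scales."""

    mu: np.ndarray  # length-5, transformed units, sums to zero
    alpha: float    # GP marginal variance, transformed-units^2
    rho_r: float    # distance length-scale, km
    rho_theta: float  # angular length-scale, dimensionless
    sigma: float    # observational noise sd, transformed units

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (N_TYPES,):
            raise ValueError(f"mu must have length {N_TYPES}")
        if abs(mu.sum()) > 1e-12 * max(1.0, np.abs(mu).max()):
            raise ValueError("soil-type offsets must sum to zero")
        for name in ("alpha", "rho_r", "rho_theta", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class ModelConfig:
    """Priors, sampler settings, and the spatial conventions of the analysis."""

    # prior sds (half-normal for the scales)
    mu_sd: float = 1.0
    rho_r_sd: float = 1.5
    rho_theta_sd: float = 1.0
    alpha_sd: float = 6.0
    sigma_sd: float = 6.0
    # sampler
    chains: int = 4
    iterations: int = 3000
    warmup_frac: float = 0.5
    n_walkers: int = 32
    #: ensemble sweeps; defaults to ``iterations``. The ensemble sampler
    #: needs more sweeps than a gradient-based sampler needs iterations for
    #: the same effective sample size, so short runs can raise this without
    #: changing the number of retained draws.
    steps: Optional[int] = None
    # numerics
    jitter_frac: float = 1e-9  # diagonal jitter = jitter_frac * alpha
    # convergence gates
    rhat_max: float = 1.05
    ess_min: float = 100.0
    # prior-only mode (likelihood switched off)
    likelihood: bool = True
    # spatial conventions carried along the pipeline
    sector: Sector = field(default_factory=Sector)
    grid_r_min_km: float = 0.1
    grid_r_max_km: float = 1.5
    grid_n: int = 30

    @property
    def n_warmup(self) -> int:
        return int(round(self.iterations * self.warmup_frac))

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.n_warmup)


class ConvergenceError(RuntimeError):
    """MCMC did not mix (R-hat too large or effective sample size too small)."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------------------------
# log density
# --------------------------------------------------------------------------

def _expand_mu(mu_free: np.ndarray) -> np.ndarray:
    """Map 4 free offsets to the 5-vector summing to zero exactly."""
    return np.concatenate([mu_free, [-float(np.sum(mu_free))]])


def marginal_loglik(
    y_t: np.ndarray,
    r: np.ndarray,
    theta: np.ndarray,
    k_idx: np.ndarray,
    hp: Hyperparams,
    jitter_frac: float = 1e-9,
) -> float:
    """Log density of y_t under the GP-marginalised model.

    Marginalising the latent field gives y ~ N(mu_k, alpha*K + sigma^2 I);
    evaluated via Cholesky.
    """
    n = y_t.size
    S = build_covariance(r, theta, hp, jitter=jitter_frac * hp.alpha)
    S[np.diag_indices(n)] += hp.sigma ** 2
    resid = y_t - hp.mu[k_idx]
    c, low = cho_factor(S, lower=True, overwrite_a=True, check_finite=False)
    alpha_v = cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (resid @ alpha_v + logdet + n * np.log(2.0 * np.pi)))


class _Posterior:
    """Collapsed log-posterior over x = (log alpha, log rho_r, log rho_theta, log sigma).

    Both the latent field f and the soil offsets mu are Gaussian given the
    scales, so they are integrated out analytically:

        y | scales ~ N(0, alpha*K + sigma^2 I + X C X^T)

    where X maps each sample to its free-offset coordinates under the
    sum-to-zero parameterization (row e_k for k < 5, row of -1 for the
    fifth type) and C = I - J/5 is the prior covariance of the free
    offsets implied by iid N(0, mu_sd^2) priors on the constrained
    5-vector. MCMC then runs over only 4 well-identified scale parameters
    (on the log scale, half-normal priors mapped through the exp
    Jacobian); mu and f are recovered per retained draw from their exact
    conditional Gaussians.
    """

    NDIM = 4

    #: guard against numerically absurd scales before exponentiating
    LOG_BOUND = 12.0

    def __init__(self, y_t, r, theta, k_idx, config: ModelConfig):
        self.y = np.asarray(y_t, dtype=float)
        self.k = np.asarray(k_idx, dtype=int)
        self.cfg = config
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        # geometry-only precomputes; hyperparameters just rescale them
        self.dr2 = (r[:, None] - r[None, :]) ** 2
        self.s2 = np.sin(np.pi * np.abs(theta[:, None] - theta[None, :]) / 360.0) ** 2
        self.n = self.y.size
        # free-offset design and prior (Sherman-Morrison: (I+J)^-1 = I - J/5)
        X = np.zeros((self.n, N_TYPES - 1))
        for i, ki in enumerate(self.k):
            if ki < N_TYPES - 1:
                X[i, ki] = 1.0
            else:
                X[i, :] = -1.0
        self.X = X
        self.C_mu = config.mu_sd ** 2 * (
            np.eye(N_TYPES - 1) - np.ones((N_TYPES - 1, N_TYPES - 1)) / N_TYPES
        )
        self.P_mu = np.linalg.inv(self.C_mu)
        self.XCXt = X @ self.C_mu @ X.T

    def kernel(self, alpha: float, rho_r: float, rho_theta: float) -> np.ndarray:
        return alpha * np.exp(-self.dr2 / rho_r ** 2 - 2.0 * self.s2 / rho_theta ** 2)

    def log_prior(self, x: np.ndarray) -> float:
        if np.any(np.abs(x) > self.LOG_BOUND):
            return -np.inf
        alpha, rho_r, rho_theta, sigma = np.exp(x)
        cfg = self.cfg
        # half-normal on each scale s plus the log-Jacobian d s / d log s = s
        lp = -0.5 * (rho_r / cfg.rho_r_sd) ** 2
        lp -= 0.5 * (rho_theta / cfg.rho_theta_sd) ** 2
        lp -= 0.5 * (alpha / cfg.alpha_sd) ** 2
        lp -= 0.5 * (sigma / cfg.sigma_sd) ** 2
        lp += float(np.sum(x))
        return lp

    def log_likelihood(self, x: np.ndarray) -> float:
        alpha, rho_r, rho_theta, sigma = np.exp(x)
        S = self.kernel(alpha, rho_r, rho_theta)
        S += self.XCXt
        S[np.diag_indices(self.n)] += sigma ** 2 + self.cfg.jitter_frac * alpha
        try:
            c, low = cho_factor(S, lower=True, overwrite_a=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        v = cho_solve((c, low), self.y, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return float(-0.5 * (self.y @ v + logdet + self.n * np.log(2.0 * np.pi)))

    def __call__(self, x: np.ndarray) -> float:
        lp = self.log_prior(x)
        if not np.isfinite(lp):
            return -np.inf
        if self.cfg.likelihood:
            ll = self.log_likelihood(x)
            if not np.isfinite(ll):
                return -np.inf
            lp += ll
        return lp


# --------------------------------------------------------------------------
# posterior draws container
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained joint posterior draws plus the data they condition on.

    ``f`` holds the latent spatial term at the n data locations, one row per
    retained draw. Diagnostics carry split-R-hat and bulk ESS per parameter
    computed on the full walker array before subsampling.
    """

    mu: np.ndarray          # (m, 5)
    alpha: np.ndarray       # (m,)
    rho_r: np.ndarray       # (m,)
    rho_theta: np.ndarray   # (m,)
    sigma: np.ndarray       # (m,)
    f: np.ndarray           # (m, n)
    r: np.ndarray           # (n,)
    theta: np.ndarray       # (n,)
    y_t: np.ndarray         # (n,)
    k_idx: np.ndarray       # (n,)
    diagnostics: dict
    jitter_frac: float = 1e-9

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    @property
    def n_data(self) -> int:
        return self.r.size

    def hyperparams(self, i: int) -> Hyperparams:
        return Hyperparams(
            mu=self.mu[i],
            alpha=float(self.alpha[i]),
            rho_r=float(self.rho_r[i]),
            rho_theta=float(self.rho_theta[i]),
            sigma=float(self.sigma[i]),
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, and central 90%/95% intervals per parameter."""
        cols = {f"mu[{SOIL_TYPES[k]}]": self.mu[:, k] for k in range(N_TYPES)}
        cols.update(
            alpha=self.alpha, rho_r=self.rho_r, rho_theta=self.rho_theta, sigma=self.sigma
        )
        rows = []
        for name, v in cols.items():
            q = np.percentile(v, [2.5, 5, 95, 97.5])
            rows.append(
                dict(parameter=name, mean=v.mean(), sd=v.std(ddof=1),
                     q2_5=q[0], q5=q[1], q95=q[2], q97_5=q[3])
            )
        return pd.DataFrame(rows)

    def to_csv(self, draws_path, data_path=None) -> None:
        """One row per draw; optionally the conditioning data alongside."""
        df = pd.DataFrame(
            {f"mu_{k + 1}": self.mu[:, k] for k in range(N_TYPES)}
            | {"alpha": self.alpha, "rho_r": self.rho_r,
               "rho_theta": self.rho_theta, "sigma": self.sigma}
            | {f"f_{i}": self.f[:, i] for i in range(self.n_data)}
        )
        df.to_csv(draws_path, index=False)
        if data_path is not None:
            pd.DataFrame(
                {"r_km": self.r, "bearing_deg": self.theta,
                 "y_quarter": self.y_t, "soil_type_index": self.k_idx}
            ).to_csv(data_path, index=False)

    @classmethod
    def from_csv(cls, draws_path, data_path, jitter_frac: float = 1e-9) -> "PosteriorDraws":
        dd = pd.read_csv(draws_path)
        dat = pd.read_csv(data_path)
        n = len(dat)
        return cls(
            mu=dd[[f"mu_{k + 1}" for k in range(N_TYPES)]].to_numpy(),
            alpha=dd["alpha"].to_numpy(),
            rho_r=dd["rho_r"].to_numpy(),
            rho_theta=dd["rho_theta"].to_numpy(),
            sigma=dd["sigma"].to_numpy(),
            f=dd[[f"f_{i}" for i in range(n)]].to_numpy(),
            r=dat["r_km"].to_numpy(),
            theta=dat["bearing_deg"].to_numpy(),
            y_t=dat["y_quarter"].to_numpy(),
            k_idx=dat["soil_type_index"].to_numpy(dtype=int),
            diagnostics={},
            jitter_frac=jitter_frac,
        )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _map_start(post: _Posterior, rng: np.random.Generator) -> np.ndarray:
    """Posterior-mode starting point (multistart L-BFGS-B on -log posterior)."""
    best_x, best_val = None, np.inf
    starts = [np.array([0.0, -0.7, -0.7, -0.7])]
    for _ in range(2):
        starts.append(rng.normal(-0.3, 0.7, _Posterior.NDIM))
    for x0 in starts:
        res = minimize(lambda x: -post(x), x0, method="L-BFGS-B")
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    return np.asarray(best_x, dtype=float)


def _diagnose(chain: np.ndarray) -> dict:
    """Split-R-hat and bulk ESS per parameter; chain is (steps, walkers, ndim)."""
    import arviz as az

    names = ["log_alpha", "log_rho_r", "log_rho_theta", "log_sigma"]
    # arviz expects (chain, draw); walkers play the role of chains
    data = {name: chain[:, :, j].T for j, name in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.convert_to_dataset(data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return {
        "rhat": {name: float(rhat[name].values) for name in names},
        "ess": {name: float(ess[name].values) for name in names},
    }


def _draw_mu_f(
    draws_x: np.ndarray,
    post: _Posterior,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional draws of (mu, f) given each retained scale draw.

    Factorises p(mu, f | y, scales) = p(mu | y, scales) p(f | y, mu, scales):
    the free offsets have Gaussian posterior with precision
    P + X^T S^-1 X (S = alpha*K + sigma^2 I), and given mu the field is
    f | y ~ N(A S^-1 resid, A - A S^-1 A) with A = alpha*K. In prior-only
    mode both come straight from their priors.
    """
    m = draws_x.shape[0]
    n = post.n
    n_free = N_TYPES - 1
    mu_out = np.empty((m, N_TYPES))
    f_out = np.empty((m, n))
    eye = np.eye(n)
    C_mu_chol = cholesky(post.C_mu, lower=True)
    for i in range(m):
        alpha, rho_r, rho_theta, sigma = np.exp(draws_x[i])
        A = post.kernel(alpha, rho_r, rho_theta)
        jit = max(cfg.jitter_frac * alpha, 1e-12)
        if not cfg.likelihood:
            mu_free = C_mu_chol @ rng.standard_normal(n_free)
            mu_out[i] = _expand_mu(mu_free)
            L = cholesky(A + 10 * jit * eye, lower=True, check_finite=False)
            f_out[i] = L @ rng.standard_normal(n)
            continue
        S = A + (sigma ** 2 + jit) * eye
        c, low = cho_factor(S, lower=True, check_finite=False)
        Sinv_y = cho_solve((c, low), post.y, check_finite=False)
        Sinv_X = cho_solve((c, low), post.X, check_finite=False)
        Q = post.P_mu + post.X.T @ Sinv_X
        Lq = cholesky(Q, lower=True, check_finite=False)
        mean_mu = cho_solve((Lq, True), post.X.T @ Sinv_y, check_finite=False)
        mu_free = mean_mu + solve_triangular(
            Lq.T, rng.standard_normal(n_free), lower=False, check_finite=False
        )
        mu_out[i] = _expand_mu(mu_free)
        resid = post.y - post.X @ mu_free
        mean = A @ cho_solve((c, low), resid, check_finite=False)
        cov = A - A @ cho_solve((c, low), A, check_finite=False)
        cov[np.diag_indices(n)] += 10 * jit
        L = cholesky(cov, lower=True, check_finite=False)
        f_out[i] = mean + L @ rng.standard_normal(n)
    return mu_out, f_out


def fit_arrays(
    y_t: np.ndarray,
    r: np.ndarray,
    theta: np.ndarray,
    k_idx: np.ndarray,
    config: Optional[ModelConfig] = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the model to transformed outcomes given as plain arrays.

    This is the computational core of :func:`fit`; calibration experiments
    that simulate directly on the quarter-power scale call it as-is.
    """
    import emcee

    cfg = config or ModelConfig()
    y_t = np.asarray(y_t, dtype=float)
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    k_idx = np.asarray(k_idx, dtype=int)
    if cfg.likelihood and np.unique(np.column_stack([r, theta]), axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct locations")

    post = _Posterior(y_t, r, theta, k_idx, cfg)
    rng = np.random.default_rng(seed)

    if cfg.likelihood:
        x0 = _map_start(post, rng)
    else:
        x0 = np.log([0.5 * cfg.alpha_sd, 0.5 * cfg.rho_r_sd,
                     0.5 * cfg.rho_theta_sd, 0.5 * cfg.sigma_sd])
    nw = max(cfg.n_walkers, 2 * _Posterior.NDIM + 2)
    init = x0[None, :] + 0.2 * rng.standard_normal((nw, _Posterior.NDIM))

    # differential-evolution moves handle the correlated (alpha, rho, sigma)
    # posterior much better than the default stretch move
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, _Posterior.NDIM, post, moves=moves)
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    n_steps = cfg.steps if cfg.steps is not None else cfg.iterations
    sampler.run_mcmc(init, n_steps, progress=False)

    chain = sampler.get_chain(discard=int(round(n_steps * cfg.warmup_frac)))
    diagnostics = _diagnose(chain)
    diagnostics["mean_acceptance"] = float(np.mean(sampler.acceptance_fraction))
    max_rhat = max(diagnostics["rhat"].values())
    min_ess = min(diagnostics["ess"].values())
    diagnostics["max_rhat"] = max_rhat
    diagnostics["min_ess"] = min_ess
    if max_rhat > cfg.rhat_max or min_ess < cfg.ess_min:
        raise ConvergenceError(
            f"chains did not mix: max R-hat {max_rhat:.3f} "
            f"(limit {cfg.rhat_max}), min ESS {min_ess:.0f} (floor {cfg.ess_min:.0f})",
            diagnostics,
        )

    flat = chain.reshape(-1, _Posterior.NDIM)  # step-major: adjacent rows ~ independent walkers
    m = min(cfg.n_retained, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, m).round().astype(int)
    x_ret = flat[idx]

    mu, f = _draw_mu_f(x_ret, post, cfg, rng)
    scales = np.exp(x_ret)
    return PosteriorDraws(
        mu=mu,
        alpha=scales[:, 0],
        rho_r=scales[:, 1],
        rho_theta=scales[:, 2],
        sigma=scales[:, 3],
        f=f,
        r=r,
        theta=theta,
        y_t=y_t,
        k_idx=k_idx,
        diagnostics=diagnostics,
        jitter_frac=cfg.jitter_frac,
    )


def fit(
    samples: Sequence[SoilSample],
    config: Optional[ModelConfig] = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the hierarchical GP model to a survey.

    Applies the quarter-power transform to the Pb concentrations, maps soil
    types to indices in :data:`~plumefall.sample_io.SOIL_TYPES` order, and
    runs MCMC. Raises :class:`ConvergenceError` if the chains do not mix
    (max R-hat above the configured gate or any ESS below the floor).
    """
    y_t = quarter_transform(np.array([s.pb_mg_kg for s in samples]))
    r = np.array([s.polar.r for s in samples])
    theta = np.array([s.polar.theta for s in samples])
    k_idx = np.array([SOIL_TYPES.index(s.soil_type) for s in samples])
    return fit_arrays(y_t, r, theta, k_idx, config=config, seed=seed)
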
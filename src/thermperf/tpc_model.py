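"""Kumaraswamy-kernel thermal performance curves and their hierarchical fit.

The performance curve maps temperature ``x`` to expected performance (here,
scaled relative growth rate). With critical limits ``lower < upper`` and
``z = (x - lower) / (upper - lower)``, the kernel

    k(z) = z**(a - 1) * (1 - z**a)**(b - 1),      0 < z < 1,

is the Kumaraswamy density up to a constant. We normalize by its value at the
mode ``z* = ((a - 1) / (a*b - 1))**(1/a)`` so that the curve's maximum equals
an explicit ``stretch`` parameter:

    P(x) = stretch * k(z) / k(z*)   for lower < x < upper,   else 0.

Peak normalization makes ``stretch`` the maximum performance and gives the
thermal optimum in closed form, ``T_opt = lower + (upper - lower) * z*``.
An interior mode requires a > 1 and b > 1; validation enforces both.

The hierarchical model treats each population's five curve parameters as draws
from shared Gaussian hyper-distributions in an unconstrained space
(support midpoint, ``log width``, ``log(a-1)``, ``log(b-1)``, ``log stretch``), with a
zero-truncated Normal likelihood for the observed scaled genotype-mean RGR:

    y_i ~ Normal(P(x_i; theta_pop(i)), sigma)  truncated to y >= 0.

Sampling is by adaptive Metropolis-within-Gibbs: componentwise random-walk
updates of population parameters (vectorized across populations, which are
conditionally independent given the hyper-parameters), conjugate Gibbs updates
for hyper-means and hyper-variances, and a random-walk update of log sigma.
Proposal scales adapt only during warmup, so retained draws form a Markov
chain with the correct stationary distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .config import MCMCConfig
from .errors import ConfigError, DataError
from .preprocess import ScaledDataset

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

#: order of natural-scale curve parameters throughout the package
PARAM_NAMES = ("lower", "upper", "shape_a", "shape_b", "stretch")

#: small floor added to sigma so the likelihood stays proper on noise-free data
SIGMA_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# Curve


@dataclass(frozen=True)
class TPCParams:
    """Natural-scale parameters of one population's curve (one draw)."""

    lower: float
    upper: float
    shape_a: float
    shape_b: float
    stretch: float

    def validate(self) -> None:
        if not self.upper > self.lower:
            raise ConfigError(f"upper ({self.upper}) must exceed lower ({self.lower})")
        if not self.shape_a > 1.0:
            raise ConfigError(f"shape_a must be > 1 for an interior maximum, got {self.shape_a}")
        if not self.shape_b > 1.0:
            raise ConfigError(f"shape_b must be > 1 for an interior maximum, got {self.shape_b}")
        if not self.stretch > 0.0:
            raise ConfigError(f"stretch must be > 0, got {self.stretch}")


def kumaraswamy_mode(shape_a: float, shape_b: float):
    """Mode ``z*`` of the Kumaraswamy kernel on the unit interval."""
    return ((shape_a - 1.0) / (shape_a * shape_b - 1.0)) ** (1.0 / shape_a)


def _kernel(z, a, b):
    return z ** (a - 1.0) * (1.0 - z**a) ** (b - 1.0)


def performance_curve(x, params: TPCParams):
    """Evaluate the peak-normalized curve at temperature(s) ``x``.

    Returns 0 outside the open support ``(lower, upper)``; the maximum, equal
    to ``params.stretch``, is attained at the analytic mode.
    """
    params.validate()
    return performance_curve_array(
        np.asarray(x, dtype=float),
        params.lower,
        params.upper,
        params.shape_a,
        params.shape_b,
        params.stretch,
    )


def performance_curve_array(x, lower, upper, shape_a, shape_b, stretch):
    """Vectorized curve evaluation; all parameter arguments broadcast with x."""
    x = np.asarray(x, dtype=float)
    width = np.asarray(upper, dtype=float) - lower
    z = (x - lower) / width
    inside = (z > 0.0) & (z < 1.0)
    zc = np.where(inside, z, 0.5)  # safe placeholder outside support
    zstar = kumaraswamy_mode(np.asarray(shape_a, dtype=float), shape_b)
    peak = _kernel(zstar, shape_a, shape_b)
    val = stretch * _kernel(zc, shape_a, shape_b) / peak
    return np.where(inside, val, 0.0)


# ---------------------------------------------------------------------------
# Likelihood


def truncnorm_logpdf(y, mu, sigma):
    """Log-density of Normal(mu, sigma) truncated below at zero, at y >= 0."""
    y = np.asarray(y, dtype=float)
    zscore = (y - mu) / sigma
    return -0.5 * zscore**2 - np.log(sigma) - 0.5 * _LOG_2PI - log_ndtr(mu / sigma)


def truncnorm_logpdf_grad(y, mu, sigma):
    """Analytic gradient of :func:`truncnorm_logpdf` wrt (mu, sigma).

    Used to verify the likelihood's log-density against finite differences.
    """
    y = np.asarray(y, dtype=float)
    r = (y - mu) / sigma
    alpha = mu / sigma
    # hazard of the lower truncation point: phi(alpha) / Phi(alpha)
    lam = np.exp(-0.5 * alpha**2 - 0.5 * _LOG_2PI - log_ndtr(alpha))
    d_mu = r / sigma - lam / sigma
    d_sigma = (r**2 - 1.0) / sigma + lam * alpha / sigma
    return d_mu, d_sigma


# ---------------------------------------------------------------------------
# Transformed parameter space

# transformed order: support midpoint, log width, log(a - 1), log(b - 1),
# log stretch. The midpoint/width pairing keeps the sampler's coordinates
# aligned with the posterior's soft directions (translating vs stretching the
# support), which mixes far better than (lower, width) updates.
N_PARAM = 5


def transformed_to_natural(theta: np.ndarray) -> np.ndarray:
    """Map (..., 5) unconstrained parameters to natural scale (centered temps)."""
    out = np.empty_like(theta)
    half = 0.5 * np.exp(theta[..., 1])
    out[..., 0] = theta[..., 0] - half
    out[..., 1] = theta[..., 0] + half
    out[..., 2] = 1.0 + np.exp(theta[..., 2])
    out[..., 3] = 1.0 + np.exp(theta[..., 3])
    out[..., 4] = np.exp(theta[..., 4])
    return out


def _mu_rows(theta: np.ndarray, x: np.ndarray, pop: np.ndarray) -> np.ndarray:
    """Expected scaled RGR for every data row given per-population theta."""
    nat = transformed_to_natural(theta)
    return performance_curve_array(
        x, nat[pop, 0], nat[pop, 1], nat[pop, 2], nat[pop, 3], nat[pop, 4]
    )


# ---------------------------------------------------------------------------
# Priors


@dataclass
class PriorConfig:
    """Weakly informative priors, centered on the observed data span.

    Hyper-means are Normal(m0, s0); hyper-variances Inv-Gamma(a0, b0); sigma
    Half-Normal(sigma_scale). All on the transformed parameter scale.
    """

    m0: np.ndarray = field(default=None)  # type: ignore[assignment]
    s0: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau2_a0: float = 3.0
    tau2_b0: float = 0.5
    sigma_scale: float = 0.5

    @classmethod
    def from_data(cls, x: np.ndarray, y: np.ndarray) -> "PriorConfig":
        span = float(x.max() - x.min())
        ymax = float(max(y.max(), 0.1))
        m0 = np.array(
            [
                0.5 * float(x.min() + x.max()),  # support midpoint near data middle
                math.log(1.5 * span),  # width: support wider than treatments
                math.log(1.5),  # a ~ 2.5
                math.log(2.5),  # b ~ 3.5
                math.log(ymax),  # stretch near observed peak
            ]
        )
        s0 = np.array([0.5 * span, 0.6, 0.75, 0.75, 0.5])
        return cls(m0=m0, s0=s0)


# ---------------------------------------------------------------------------
# Posterior containers


@dataclass
class PosteriorDraws:
    """Retained posterior draws on the natural (un-centered, un-scaled) scale.

    ``params`` is indexed (draw, population, parameter) with parameters in
    :data:`PARAM_NAMES` order. ``sigma`` is the residual sd in scaled-RGR
    units (shared across populations).
    """

    params: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    populations: list
    range_labels: list
    grand_mean_rgr: float
    temp_center: float

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    @property
    def n_pops(self) -> int:
        return self.params.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (draw, chain, population, parameter, value)."""
        n_d, n_p, n_k = self.params.shape
        draw_idx = np.repeat(np.arange(n_d), n_p * n_k)
        chain_idx = np.repeat(self.chain, n_p * n_k)
        pop_idx = np.tile(np.repeat(np.arange(n_p), n_k), n_d)
        par_idx = np.tile(np.arange(n_k), n_d * n_p)
        return pd.DataFrame(
            {
                "draw": draw_idx,
                "chain": chain_idx,
                "population_id": np.asarray(self.populations)[pop_idx],
                "range_label": np.asarray(self.range_labels)[pop_idx],
                "parameter": np.asarray(PARAM_NAMES)[par_idx],
                "value": self.params.reshape(-1),
            }
        )


@dataclass
class ConvergenceDiagnostics:
    rhat: dict
    ess: dict
    converged: bool
    warnings: list

    @property
    def max_rhat(self) -> float:
        vals = np.concatenate([np.ravel(v) for v in self.rhat.values()])
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")

    @property
    def min_ess(self) -> float:
        vals = np.concatenate([np.ravel(v) for v in self.ess.values()])
        vals = vals[np.isfinite(vals)]
        return float(vals.min()) if vals.size else float("nan")


@dataclass
class PPCResult:
    per_population: dict
    overall: float


# ---------------------------------------------------------------------------
# Sampler


def _log_lik_rows(theta, x, y, pop, sigma):
    mu = _mu_rows(theta, x, pop)
    return truncnorm_logpdf(y, mu, sigma)


def _pop_log_lik(theta, x, y, pop, sigma, n_pops):
    rows = _log_lik_rows(theta, x, y, pop, sigma)
    return np.bincount(pop, weights=rows, minlength=n_pops)


def _run_chain(x, y, pop, n_pops, mcmc: MCMCConfig, prior: PriorConfig, seed_seq):
    rng = np.random.default_rng(seed_seq)
    n_iter = mcmc.iterations_per_chain
    n_warm = mcmc.n_warmup
    n_keep = n_iter - n_warm

    span = float(x.max() - x.min())
    # data-informed start, jittered per chain
    base = np.array(
        [
            0.5 * float(x.min() + x.max()),
            math.log(1.3 * span),
            math.log(1.5),
            math.log(2.5),
            math.log(max(float(y.max()), 0.1)),
        ]
    )
    theta = base[None, :] + 0.1 * rng.standard_normal((n_pops, N_PARAM))
    mu_h = base.copy()
    tau2 = np.full(N_PARAM, 0.25)
    u = math.log(0.1) + 0.1 * rng.standard_normal()  # sigma = floor + exp(u)

    scales = np.full((n_pops, N_PARAM), 0.1)
    scale_u = 0.1
    # per-population joint adaptive-Metropolis state (empirical covariance
    # learned during warmup; handles the support/shape ridge the
    # componentwise kernel mixes slowly along)
    lam = np.full(n_pops, 0.3)
    run_mean = theta.copy()
    run_cov = np.tile(0.01 * np.eye(N_PARAM), (n_pops, 1, 1))
    run_count = 1
    eye_jitter = 1e-9 * np.eye(N_PARAM)

    def sigma_of(u_):
        return SIGMA_FLOOR + math.exp(u_)

    cur_ll = _pop_log_lik(theta, x, y, pop, sigma_of(u), n_pops)

    keep_theta = np.empty((n_keep, n_pops, N_PARAM))
    keep_sigma = np.empty(n_keep)
    keep_mu = np.empty((n_keep, N_PARAM))
    keep_tau2 = np.empty((n_keep, N_PARAM))

    for t in range(n_iter):
        gamma = min(0.3, 3.0 / math.sqrt(t + 1.0)) if t < n_warm else 0.0
        sig = sigma_of(u)

        # componentwise random-walk updates, vectorized across populations
        for j in range(N_PARAM):
            prop = theta.copy()
            prop[:, j] = theta[:, j] + scales[:, j] * rng.standard_normal(n_pops)
            prop_ll = _pop_log_lik(prop, x, y, pop, sig, n_pops)
            d_prior = (
                (theta[:, j] - mu_h[j]) ** 2 - (prop[:, j] - mu_h[j]) ** 2
            ) / (2.0 * tau2[j])
            log_alpha = prop_ll - cur_ll + d_prior
            accept = np.log(rng.random(n_pops)) < log_alpha
            theta[accept, j] = prop[accept, j]
            cur_ll = np.where(accept, prop_ll, cur_ll)
            if gamma:
                scales[:, j] *= np.exp(gamma * (accept.astype(float) - 0.44))

        # joint proposals from the adapted covariance (all five components);
        # repeated a few times per sweep to traverse the support/shape ridge
        if t >= 50:
            try:
                chol = np.linalg.cholesky(run_cov + eye_jitter)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(
                    run_cov + 1e-6 * np.eye(N_PARAM)
                )
            for _rep in range(4):
                step = np.einsum(
                    "pij,pj->pi", chol, rng.standard_normal((n_pops, N_PARAM))
                )
                prop = theta + lam[:, None] * step
                prop_ll = _pop_log_lik(prop, x, y, pop, sig, n_pops)
                d_prior = (
                    ((theta - mu_h[None, :]) ** 2 - (prop - mu_h[None, :]) ** 2)
                    / (2.0 * tau2[None, :])
                ).sum(axis=1)
                log_alpha = prop_ll - cur_ll + d_prior
                accept = np.log(rng.random(n_pops)) < log_alpha
                theta[accept] = prop[accept]
                cur_ll = np.where(accept, prop_ll, cur_ll)
                if gamma:
                    lam *= np.exp(gamma * (accept.astype(float) - 0.23))
        if t < n_warm:
            run_count += 1
            d = theta - run_mean
            run_mean += d / run_count
            run_cov += (
                np.einsum("pi,pj->pij", d, theta - run_mean) - run_cov
            ) / run_count

        # residual sd (log-scale random walk; half-normal prior + Jacobian)
        u_prop = u + scale_u * rng.standard_normal()
        sig_prop = sigma_of(u_prop)
        ll_prop = _pop_log_lik(theta, x, y, pop, sig_prop, n_pops)
        lp_cur = -sig**2 / (2.0 * prior.sigma_scale**2) + u
        lp_prop = -sig_prop**2 / (2.0 * prior.sigma_scale**2) + u_prop
        log_alpha = ll_prop.sum() - cur_ll.sum() + lp_prop - lp_cur
        acc = math.log(rng.random()) < log_alpha
        if acc:
            u, cur_ll = u_prop, ll_prop
        if gamma:
            scale_u *= math.exp(gamma * (float(acc) - 0.44))

        # conjugate hyper-parameter updates
        prec = 1.0 / prior.s0**2 + n_pops / tau2
        mean = (prior.m0 / prior.s0**2 + theta.sum(axis=0) / tau2) / prec
        mu_h = mean + rng.standard_normal(N_PARAM) / np.sqrt(prec)
        resid2 = ((theta - mu_h[None, :]) ** 2).sum(axis=0)
        tau2 = (prior.tau2_b0 + 0.5 * resid2) / rng.gamma(
            prior.tau2_a0 + 0.5 * n_pops, 1.0, size=N_PARAM
        )
        tau2 = np.maximum(tau2, 1e-8)

        if t >= n_warm:
            k = t - n_warm
            keep_theta[k] = theta
            keep_sigma[k] = sigma_of(u)
            keep_mu[k] = mu_h
            keep_tau2[k] = tau2

    return keep_theta, keep_sigma, keep_mu, keep_tau2


def fit_tpc(
    data: ScaledDataset,
    mcmc: MCMCConfig,
    prior: Optional[PriorConfig] = None,
):
    """Fit the hierarchical TPC model; returns (PosteriorDraws, diagnostics).

    Populations share Gaussian hyper-distributions over their transformed
    curve parameters (partial pooling). Draws are returned on the natural
    scale: temperatures un-centered, stretch multiplied back by the grand
    mean RGR. Non-convergence (any R-hat > 1.05) is flagged and logged; draws
    are still returned.
    """
    df = data.df
    x = df["centered_temp"].to_numpy(dtype=float)
    y = df["scaled_rgr"].to_numpy(dtype=float)
    pop = df["pop_index"].to_numpy(dtype=int)
    n_pops = len(data.populations)

    per_pop_temps = df.groupby("pop_index")["centered_temp"].nunique()
    if len(per_pop_temps) < n_pops or (per_pop_temps < 2).any():
        raise DataError("every population needs >= 2 distinct temperatures")

    if prior is None:
        prior = PriorConfig.from_data(x, y)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    per_chain = [
        _run_chain(x, y, pop, n_pops, mcmc, prior, s) for s in seeds
    ]
    theta = np.stack([c[0] for c in per_chain])  # (chain, draw, pop, 5)
    sigma = np.stack([c[1] for c in per_chain])
    mu_h = np.stack([c[2] for c in per_chain])
    tau2 = np.stack([c[3] for c in per_chain])

    diagnostics = _diagnostics(theta, sigma, mu_h, tau2)
    if not diagnostics.converged:
        logger.warning("MCMC convergence flagged: %s", "; ".join(diagnostics.warnings))

    nat = transformed_to_natural(theta)
    nat[..., 0] += data.temp_center
    nat[..., 1] += data.temp_center
    nat[..., 4] *= data.grand_mean_rgr

    n_chains, n_keep = sigma.shape
    draws = PosteriorDraws(
        params=nat.reshape(n_chains * n_keep, n_pops, N_PARAM),
        sigma=sigma.reshape(-1),
        chain=np.repeat(np.arange(n_chains), n_keep),
        populations=list(data.populations),
        range_labels=list(data.range_labels),
        grand_mean_rgr=data.grand_mean_rgr,
        temp_center=data.temp_center,
    )
    assert draws.n_draws == mcmc.n_retained
    return draws, diagnostics


def _diagnostics(theta, sigma, mu_h, tau2) -> ConvergenceDiagnostics:
    import arviz as az

    data = {
        "center": theta[..., 0],
        "log_width": theta[..., 1],
        "log_am1": theta[..., 2],
        "log_bm1": theta[..., 3],
        "log_stretch": theta[..., 4],
        "sigma": sigma,
        "hyper_mean": mu_h,
        "hyper_var": tau2,
    }
    ds = az.convert_to_dataset(data)
    rhat_ds = az.rhat(ds)
    ess_ds = az.ess(ds)
    rhat = {k: np.atleast_1d(np.asarray(rhat_ds[k])) for k in data}
    ess = {k: np.atleast_1d(np.asarray(ess_ds[k])) for k in data}
    warnings = []
    for k, v in rhat.items():
        finite = v[np.isfinite(v)]
        if finite.size == 0:  # single-chain runs have no split-R-hat
            continue
        worst = float(np.max(finite))
        if worst > 1.05:
            warnings.append(f"R-hat {worst:.3f} for {k} exceeds 1.05")
        elif worst > 1.01:
            warnings.append(f"R-hat {worst:.3f} for {k} exceeds 1.01 (warn)")
    converged = not any("exceeds 1.05" in w for w in warnings)
    return ConvergenceDiagnostics(rhat=rhat, ess=ess, converged=converged, warnings=warnings)


# ---------------------------------------------------------------------------
# Posterior predictive check


def posterior_predictive_pvalue(
    draws: PosteriorDraws,
    data: ScaledDataset,
    seed: int = 0,
    max_draws: int = 500,
) -> PPCResult:
    """Bayesian p-value: P(y_rep > y_obs) under the posterior predictive.

    For each retained draw (subsampled to ``max_draws`` for tractability) a
    replicate dataset is simulated from the zero-truncated Normal likelihood;
    the p-value averages the exceedance indicator over draws and rows.
    Values near 0.5 indicate adequate fit.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x77C)))
    df = data.df
    x = df["centered_temp"].to_numpy(dtype=float)
    y = df["scaled_rgr"].to_numpy(dtype=float)
    pop = df["pop_index"].to_numpy(dtype=int)

    n = draws.n_draws
    idx = (
        np.arange(n)
        if n <= max_draws
        else rng.choice(n, size=max_draws, replace=False)
    )
    exceed = np.zeros(len(x))
    for i in idx:
        p = draws.params[i]
        mu = performance_curve_array(
            x + draws.temp_center, p[pop, 0], p[pop, 1], p[pop, 2], p[pop, 3], p[pop, 4]
        ) / draws.grand_mean_rgr
        sigma = draws.sigma[i]
        # inverse-cdf sampling of Normal(mu, sigma) truncated below at 0
        lo = ndtr(-mu / sigma)
        uu = lo + (1.0 - lo) * rng.random(len(x))
        y_rep = mu + sigma * ndtri(np.clip(uu, 1e-12, 1.0 - 1e-12))
        exceed += (y_rep > y).astype(float)
    exceed /= len(idx)

    per_pop = {}
    for k, name in enumerate(draws.populations):
        mask = pop == k
        per_pop[name] = float(exceed[mask].mean())
    return PPCResult(per_population=per_pop, overall=float(exceed.mean()))
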
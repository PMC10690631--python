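"""Bayesian linear mixed regression of mean response times on arrival-time
predictors, the engagement-time scan, and PSIS-LOO model comparison.

Model
-----
For subject i and condition j,

    rt_ij = (beta0 + b0_i) + (beta1 + b1_i) * P_j [+ beta2 * O_j] + eps_ij

with (b0_i, b1_i) ~ N(0, Sigma) a correlated random intercept/slope pair,
eps_ij ~ N(0, sigma²). P_j is a gravity predictor (fixed + random effect);
any further predictor (the optical column) enters as a fixed effect only.

Priors: Normal(0, 1) on each fixed slope; Student-t(3, median(y), s_y) on
the intercept and half-Student-t(3, 0, s_y) on the random-effect SDs and
the residual SD, with s_y = max(2.5 * mad_sd(y), 10) by default (the
conventional weakly-informative location/scale defaults for this model
family); uniform on the intercept-slope correlation (LKJ(1) for a 2x2
correlation matrix).

Computation
-----------
The random effects are marginalised in closed form — with a balanced
design every subject shares the 12 x 2 random-effect design Z, so the
marginal likelihood is a product of identical-covariance multivariate
normals, V = Z Sigma Z' + sigma² I. The resulting 7-8 dimensional
hyperparameter posterior is sampled with emcee's affine-invariant ensemble;
walkers are regrouped into pseudo-chains for split-Rhat/ESS diagnostics.
Per retained draw the subject random effects are then drawn exactly from
their conditional Gaussian posterior, giving the pointwise log-likelihood
(for PSIS-LOO via arviz), the Bayesian R² and posterior predictive draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .predictors import DEFAULT_ENGAGEMENT_GRID_MS, engagement_column

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "MixedFitResult",
    "ScanResult",
    "fit_mixed",
    "bayes_r2",
    "scan_engagement_times",
    "compare_loo",
]

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-8  # permits exactly noise-free data without a singular V


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters.

    ``location``/``scale`` default to median(y) and max(2.5*mad_sd(y), 10),
    the data-dependent weakly-informative convention for this model family.
    """

    slope_sd: float = 1.0
    t_df: float = 3.0
    location: float | None = None
    scale: float | None = None

    def resolved(self, y: np.ndarray) -> "PriorConfig":
        loc = self.location if self.location is not None else float(np.median(y))
        scale = self.scale
        if scale is None:
            mad_sd = float(stats.median_abs_deviation(y, scale="normal"))
            scale = max(2.5 * mad_sd, 10.0)
        return replace(self, location=loc, scale=scale)


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    Defaults give 4 pseudo-chains x 1000 retained draws (4000 total). The
    differential-evolution ensemble mixes markedly better with many
    walkers, and the batched likelihood makes walkers cheap, so the
    default ensemble is wide and the chain short.
    """

    n_walkers: int = 128
    n_steps: int = 1200
    n_burn: int = 500
    n_chains: int = 4
    n_draws: int = 4000
    seed: int = 0
    compute_loo: bool = True

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_steps:
            raise ValueError("n_burn must be smaller than n_steps")
        if self.n_draws % self.n_chains:
            raise ValueError("n_draws must be divisible by n_chains")
        if self.n_walkers % self.n_chains:
            raise ValueError("n_walkers must be divisible by n_chains")
        kept = (self.n_steps - self.n_burn) * self.n_walkers
        if kept < self.n_draws:
            raise ValueError("not enough post-burn samples for n_draws")

    def replace(self, **kwargs) -> "SamplerConfig":
        return replace(self, **kwargs)


@dataclass
class MixedFitResult:
    """Posterior summaries and diagnostics for one mixed-model fit."""

    predictor_columns: tuple[str, ...]
    param_names: tuple[str, ...]
    summary: pd.DataFrame
    idata: az.InferenceData
    draws: int
    converged: bool
    max_rhat: float
    bayes_r2_draws: np.ndarray
    sigma_draws: np.ndarray
    y: np.ndarray
    mu_mean: np.ndarray
    obs_index: pd.MultiIndex
    loo: object | None = None

    @property
    def bayes_r2_mean(self) -> float:
        return float(self.bayes_r2_draws.mean())

    @property
    def sigma2(self) -> float:
        """Expected error variance: posterior mean of sigma² (ms²)."""
        return float(np.mean(self.sigma_draws**2))

    @property
    def elpd_loo(self) -> float:
        if self.loo is None:
            raise ValueError("fit was run with compute_loo=False")
        return float(self.loo.elpd_loo)

    def posterior_predictive(self, seed: int = 0, n_draws: int | None = None) -> np.ndarray:
        """Replicated-data draws (n_draws x n_obs) from the fitted model."""
        mu = self.idata.posterior["mu"].to_numpy().reshape(-1, len(self.y))
        sigma = self.sigma_draws.reshape(-1)
        if n_draws is not None and n_draws < mu.shape[0]:
            keep = np.linspace(0, mu.shape[0] - 1, n_draws).round().astype(int)
            mu, sigma = mu[keep], sigma[keep]
        rng = np.random.default_rng(seed)
        return mu + sigma[:, None] * rng.standard_normal(mu.shape)


@dataclass
class ScanResult:
    """Fit-quality profile over gravity-prior engagement times."""

    profile: pd.DataFrame  # engagement_ms, bayes_r2, sigma2, converged
    best_time: int

    @property
    def grid_ms(self) -> np.ndarray:
        return self.profile["engagement_ms"].to_numpy()


# ---------------------------------------------------------------------------
# Data layout

def _design(summaries: pd.DataFrame, predictors: pd.DataFrame, columns: Sequence[str]):
    """Condition-level design X (p x k), shared Z (p x 2), and Y (p x n)."""
    cond_index = predictors.index
    pivot = summaries.pivot_table(
        index=["label", "duration_s"], columns="subject_id", values="mean_rt"
    )
    pivot.index.names = ["label", "duration"]
    missing = cond_index.difference(pivot.index)
    if len(missing) or pivot.isna().any().any():
        raise ValueError("summary table must be balanced over all conditions")
    pivot = pivot.loc[cond_index]
    for c in columns:
        if c not in predictors.columns:
            raise ValueError(f"predictor column {c!r} not in the table")
    p_mat = predictors.loc[cond_index, list(columns)].to_numpy()
    x = np.column_stack([np.ones(len(cond_index)), p_mat])
    z = x[:, :2]  # random intercept + random slope on the first predictor
    return x, z, pivot.to_numpy(), cond_index


def _to_theta(phi: np.ndarray, k: int) -> np.ndarray:
    """Map unconstrained sampling coordinates to model parameters.

    phi = (beta, log tau0, log tau1, atanh rho, log sigma).
    """
    theta = phi.copy()
    theta[..., k] = np.exp(phi[..., k])
    theta[..., k + 1] = np.exp(phi[..., k + 1])
    theta[..., k + 2] = np.tanh(phi[..., k + 2])
    theta[..., k + 3] = np.exp(phi[..., k + 3])
    return theta


def _log_prob_phi(phi, x, z, y_mat, prior: PriorConfig):
    """Log posterior in unconstrained coordinates (with Jacobian)."""
    k = x.shape[1]
    out = np.full(phi.shape[0], -np.inf)
    # hard box keeps exp/tanh well away from overflow/saturation under
    # wild ensemble proposals
    ok = np.all(np.abs(phi[:, k:]) < 18.0, axis=1) & np.all(
        np.abs(phi[:, :k]) < 1e8, axis=1
    )
    if not ok.any():
        return out
    theta = _to_theta(phi[ok], k)
    jac = (
        phi[ok, k]
        + phi[ok, k + 1]
        + phi[ok, k + 3]
        + np.log1p(-theta[:, k + 2] ** 2)
    )
    out[ok] = _log_prob_batch(theta, x, z, y_mat, prior) + jac
    return out


def _log_prob_batch(theta, x, z, y_mat, prior: PriorConfig):
    """Vectorised log posterior of the marginal model for (m, d) params."""
    m = theta.shape[0]
    k = x.shape[1]
    p, n = y_mat.shape
    beta = theta[:, :k]
    tau0, tau1, rho, sigma = theta[:, k], theta[:, k + 1], theta[:, k + 2], theta[:, k + 3]
    valid = (
        (tau0 > 0)
        & (tau1 > 0)
        & (np.abs(rho) < 1)
        & (sigma > _SIGMA_FLOOR)
        & np.all(np.isfinite(theta), axis=1)
        & (tau0 < 1e8)
        & (tau1 < 1e8)
        & (sigma < 1e8)
    )
    out = np.full(m, -np.inf)
    if not valid.any():
        return out
    t0, t1, r, s = tau0[valid], tau1[valid], rho[valid], sigma[valid]
    b = beta[valid]

    lp = stats.t.logpdf(b[:, 0], prior.t_df, prior.location, prior.scale)
    if k > 1:
        lp += stats.norm.logpdf(b[:, 1:], 0.0, prior.slope_sd).sum(axis=1)
    for comp in (t0, t1, s):
        lp += stats.t.logpdf(comp, prior.t_df, 0.0, prior.scale) + np.log(2.0)
    lp += -np.log(2.0)  # uniform correlation density on (-1, 1)

    sig = np.empty((len(t0), 2, 2))
    sig[:, 0, 0] = t0**2
    sig[:, 1, 1] = t1**2
    sig[:, 0, 1] = sig[:, 1, 0] = r * t0 * t1
    v = np.einsum("pa,mab,qb->mpq", z, sig, z)
    v[:, np.arange(p), np.arange(p)] += s[:, None] ** 2
    chol, good = _batch_cholesky(v)
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    mu = b @ x.T  # (m_valid, p)
    resid = y_mat[None, :, :] - mu[:, :, None]
    w = np.linalg.solve(chol, resid)  # triangular systems solved densely
    quad = np.einsum("mpn,mpn->m", w, w)
    ll = -0.5 * (n * p * _LOG2PI + n * logdet + quad)
    ll[~good] = -np.inf
    out[valid] = lp + ll
    out[~np.isfinite(out)] = -np.inf
    return out


def _batch_cholesky(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky of a stack of matrices; flags non-PD items instead of raising."""
    try:
        return np.linalg.cholesky(v), np.ones(len(v), dtype=bool)
    except np.linalg.LinAlgError:
        pass
    chol = np.empty_like(v)
    good = np.ones(len(v), dtype=bool)
    eye = np.eye(v.shape[-1])
    for i in range(len(v)):
        try:
            chol[i] = np.linalg.cholesky(v[i])
        except np.linalg.LinAlgError:
            chol[i] = eye
            good[i] = False
    return chol, good


def _initial_walkers(x, z, y_mat, k, settings, rng):
    """Unconstrained walker cloud around per-subject least-squares moments."""
    p, n = y_mat.shape
    coef, *_ = np.linalg.lstsq(z, y_mat, rcond=None)  # (2, n): per-subject int/slope
    beta0 = np.zeros(k)
    beta0[:2] = coef.mean(axis=1)
    if k > 2:
        pooled, *_ = np.linalg.lstsq(x, y_mat.mean(axis=1), rcond=None)
        beta0 = pooled
    tau = np.array([1.0, 1e-2])
    if n > 1:
        tau = np.maximum(coef.std(axis=1, ddof=1), [1e-2, 1e-4])
    rho0 = 0.0
    if n > 2:
        rho0 = float(np.clip(np.corrcoef(coef)[0, 1], -0.9, 0.9))
        if not np.isfinite(rho0):
            rho0 = 0.0
    resid = y_mat - z @ coef
    sigma0 = max(float(resid.std(ddof=1)), 1e-6)
    center = np.concatenate(
        [beta0, [np.log(tau[0]), np.log(tau[1]), np.arctanh(rho0), np.log(sigma0)]]
    )
    d = k + 4
    walkers = center[None, :] + 0.1 * rng.standard_normal((settings.n_walkers, d))
    walkers[:, :k] = beta0[None, :] * (
        1.0 + 0.05 * rng.standard_normal((settings.n_walkers, k))
    ) + 1e-4 * rng.standard_normal((settings.n_walkers, k))
    return walkers


def _pseudo_chains(chain: np.ndarray, settings: SamplerConfig) -> np.ndarray:
    """(steps, walkers, d) -> (n_chains, per_chain, d) by walker groups."""
    steps, walkers, d = chain.shape
    per_chain = settings.n_draws // settings.n_chains
    gsize = walkers // settings.n_chains
    out = np.empty((settings.n_chains, per_chain, d))
    for c in range(settings.n_chains):
        flat = chain[:, c * gsize : (c + 1) * gsize, :].reshape(steps * gsize, d)
        idx = np.linspace(0, flat.shape[0] - 1, per_chain).round().astype(int)
        out[c] = flat[idx]
    return out


def _posterior_quantities(post, x, z, y_mat, k, rng):
    """Random-effect draws, fitted means, pointwise log-lik, Bayesian R²."""
    nc, nd, _ = post.shape
    theta = post.reshape(nc * nd, -1)
    beta = theta[:, :k]
    tau0, tau1, rho, sigma = theta[:, k], theta[:, k + 1], theta[:, k + 2], theta[:, k + 3]
    p, n = y_mat.shape
    m = theta.shape[0]

    sig = np.empty((m, 2, 2))
    sig[:, 0, 0] = tau0**2
    sig[:, 1, 1] = tau1**2
    sig[:, 0, 1] = sig[:, 1, 0] = rho * tau0 * tau1
    v = np.einsum("pa,mab,qb->mpq", z, sig, z)
    v[:, np.arange(p), np.arange(p)] += sigma[:, None] ** 2

    mu_fixed = beta @ x.T  # (m, p)
    resid = y_mat[None, :, :] - mu_fixed[:, :, None]  # (m, p, n)
    a = np.linalg.solve(v, np.broadcast_to(z, (m, p, 2)))  # V^-1 Z
    zva = np.einsum("pa,mpb->mab", z, a)  # Z' V^-1 Z
    cond_cov = sig - sig @ zva @ sig
    atr = np.einsum("mpa,mpn->man", a, resid)  # Z' V^-1 r_i
    cond_mean = np.einsum("mab,mbn->man", sig, atr)  # (m, 2, n)
    # PSD square root via eigh: the subtraction above can leave tiny
    # negative eigenvalues when the conditional covariance degenerates
    w, q = np.linalg.eigh(cond_cov)
    chol = q * np.sqrt(np.clip(w, 0.0, None))[:, None, :]
    eps = rng.standard_normal((m, 2, n))
    b_draws = cond_mean + np.einsum("mab,mbn->man", chol, eps)

    mu = mu_fixed[:, :, None] + np.einsum("pa,man->mpn", z, b_draws)  # (m, p, n)
    flat_mu = mu.reshape(m, p * n)
    err = (y_mat[None] - mu).reshape(m, p * n)
    log_lik = -0.5 * (_LOG2PI + 2 * np.log(sigma)[:, None]) - err**2 / (2 * sigma[:, None] ** 2)
    var_mu = flat_mu.var(axis=1, ddof=1)
    r2 = var_mu / (var_mu + sigma**2)
    return (
        flat_mu.reshape(nc, nd, p * n),
        log_lik.reshape(nc, nd, p * n),
        r2.reshape(nc, nd),
    )


def fit_mixed(
    summaries: pd.DataFrame,
    predictors: pd.DataFrame,
    columns: Sequence[str] = ("g_450",),
    priors: PriorConfig | None = None,
    settings: SamplerConfig | None = None,
) -> MixedFitResult:
    """Fit the hierarchical regression of mean RT on the given predictors.

    The first column receives fixed + random (per-subject) effects; any
    further columns enter as fixed effects only.
    """
    priors = priors or PriorConfig()
    settings = settings or SamplerConfig()
    x, z, y_mat, cond_index = _design(summaries, predictors, columns)
    k = x.shape[1]
    y_flat = y_mat.reshape(-1)
    priors = priors.resolved(y_flat)
    rng = np.random.default_rng(settings.seed)

    sampler = emcee.EnsembleSampler(
        settings.n_walkers,
        k + 4,
        _log_prob_phi,
        args=(x, z, y_mat, priors),
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    p0 = _initial_walkers(x, z, y_mat, k, settings, rng)
    sampler.run_mcmc(p0, settings.n_steps, progress=False)
    chain = sampler.get_chain(discard=settings.n_burn)
    post = _to_theta(_pseudo_chains(chain, settings), k)

    names = ["b_Intercept"] + [f"b_{c}" for c in columns] + [
        "sd_Intercept",
        "sd_slope",
        "cor_Intercept_slope",
        "sigma",
    ]
    posterior = {nm: post[:, :, i] for i, nm in enumerate(names)}
    mu, log_lik, r2 = _posterior_quantities(post, x, z, y_mat, k, rng)
    posterior["mu"] = mu
    obs = pd.MultiIndex.from_tuples(
        [(lab, dur, s) for (lab, dur) in cond_index for s in range(y_mat.shape[1])],
        names=["label", "duration", "subject"],
    )
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"mean_rt": log_lik},
        observed_data={"mean_rt": y_flat},
        dims={"mu": ["obs"], "mean_rt": ["obs"]},
        coords={"obs": np.arange(len(y_flat))},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = az.summary(idata, var_names=names, round_to=None)
    max_rhat = float(summary["r_hat"].max())
    sigma_draws = posterior["sigma"]

    loo = None
    if settings.compute_loo:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
        if np.any(np.asarray(loo.pareto_k) > 0.7):
            warnings.warn("PSIS-LOO: some Pareto-k diagnostics exceed 0.7", stacklevel=2)

    return MixedFitResult(
        predictor_columns=tuple(columns),
        param_names=tuple(names),
        summary=summary,
        idata=idata,
        draws=settings.n_draws,
        converged=bool(max_rhat < 1.01),
        max_rhat=max_rhat,
        bayes_r2_draws=r2,
        sigma_draws=sigma_draws,
        y=y_flat,
        mu_mean=mu.reshape(-1, len(y_flat)).mean(axis=0),
        obs_index=obs,
        loo=loo,
    )


def bayes_r2(fit: MixedFitResult) -> dict:
    """Posterior summary of the Bayesian R².

    Per draw, R² = Var(fitted values) / (Var(fitted values) + sigma²_draw),
    the residual-variance formulation of the posterior-draw R².
    """
    draws = fit.bayes_r2_draws.reshape(-1)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }


def scan_engagement_times(
    summaries: pd.DataFrame,
    predictors: pd.DataFrame,
    grid_ms: Sequence[int] | None = None,
    priors: PriorConfig | None = None,
    settings: SamplerConfig | None = None,
) -> ScanResult:
    """One mixed fit per gravity-prior engagement time.

    Returns the Bayesian R² / expected-error-variance profile over the grid
    and the best engagement time (highest R²; ties go to the lower time).
    """
    settings = settings or SamplerConfig()
    if grid_ms is None:
        grid_ms = [t for t in DEFAULT_ENGAGEMENT_GRID_MS
                   if engagement_column(t) in predictors.columns]
    rows = []
    for i, t_ms in enumerate(grid_ms):
        fit = fit_mixed(
            summaries,
            predictors,
            columns=(engagement_column(t_ms),),
            priors=priors,
            settings=settings.replace(seed=settings.seed + i, compute_loo=False),
        )
        rows.append(
            {
                "engagement_ms": int(t_ms),
                "bayes_r2": fit.bayes_r2_mean,
                "sigma2": fit.sigma2,
                "converged": fit.converged,
            }
        )
    profile = pd.DataFrame(rows)
    best = int(profile.loc[profile["bayes_r2"].idxmax(), "engagement_ms"])
    return ScanResult(profile=profile, best_time=best)


def compare_loo(fit_base: MixedFitResult, fit_augmented: MixedFitResult) -> dict:
    """PSIS-LOO comparison of nested fits on identical data rows.

    ``significant`` follows the conventional rule: the ELPD difference in
    favour of the augmented model must exceed 4 and exceed its standard
    error (computed from the pointwise ELPD differences).
    """
    if fit_base.loo is None or fit_augmented.loo is None:
        raise ValueError("both fits must be run with compute_loo=True")
    if len(fit_base.y) != len(fit_augmented.y) or not np.allclose(
        fit_base.y, fit_augmented.y
    ):
        raise ValueError("fits must be on identical data rows")
    pw_base = np.asarray(fit_base.loo.loo_i).reshape(-1)
    pw_aug = np.asarray(fit_augmented.loo.loo_i).reshape(-1)
    diff = pw_aug - pw_base
    elpd_diff = float(diff.sum())
    se_diff = float(np.sqrt(len(diff) * diff.var(ddof=1)))
    for fit in (fit_base, fit_augmented):
        if np.any(np.asarray(fit.loo.pareto_k) > 0.7):
            warnings.warn("PSIS-LOO: some Pareto-k diagnostics exceed 0.7", stacklevel=2)
    return {
        "elpd_base": float(fit_base.loo.elpd_loo),
        "elpd_augmented": float(fit_augmented.loo.elpd_loo),
        "elpd_diff": elpd_diff,
        "se_diff": se_diff,
        "significant": bool(elpd_diff > 4.0 and elpd_diff > se_diff),
    }
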
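"""Bayesian hierarchical comparison of fold-level AUROC across models.

For one (task, availability) cell the fold-level metrics are modelled on the
logit scale as

    logit(AUROC_{m,i,j}) = beta_m + b_i + c_ij + eps_{m,i,j}

with a repeat intercept b_i ~ N(0, sigma_b^2), a fold-within-repeat intercept
c_ij ~ N(0, sigma_c^2) — both shared across models, which induces the
posterior correlation between model means that makes credible-interval
overlap an unreliable ranking test — and residual eps ~ N(0, sigma^2).
Weakly-informative priors: N(0, 5^2) on each beta, half-Normal(0, 2) on the
three scales.

The random effects are marginalized analytically (everything is Gaussian on
the link scale, so the marginal likelihood is a block-structured multivariate
normal, block-diagonal by repeat), leaving a posterior over
(beta_1..beta_M, sigma_b, sigma_c, sigma) that is sampled with an affine-
invariant ensemble sampler (emcee). Model ranking is then read off the joint
response-scale draws of inverse-logit(beta_m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

import emcee

__all__ = [
    "PerformanceModelSpec",
    "PosteriorDraws",
    "fit_performance_model",
    "p_best",
    "summarize",
]


@dataclass
class PerformanceModelSpec:
    beta_prior_sd: float = 5.0
    sigma_prior_sd: float = 2.0
    clamp: float = 1e-4
    max_missing: float = 0.10
    rhat_bound: float = 1.05


@dataclass
class PosteriorDraws:
    """Joint response-scale draws of mean AUROC per model + diagnostics."""

    draws: np.ndarray  # (S, M) in (0, 1)
    model_ids: list[str]
    beta_draws: np.ndarray  # (S, M) on the logit scale
    sigma_draws: np.ndarray  # (S, 3): sigma_b, sigma_c, sigma
    rhat: float
    ess: float
    converged: bool


def _prepare(table: pd.DataFrame, spec: PerformanceModelSpec):
    """Pivot to y[m, i, j] on the logit scale, listwise-dropping missing cells."""
    models = sorted(table["model_id"].unique())
    repeats = sorted(table["repeat"].unique())
    folds = sorted(table["fold"].unique())
    M, I, J = len(models), len(repeats), len(folds)
    y = np.full((M, I, J), np.nan)
    for _, row in table.iterrows():
        m = models.index(row["model_id"])
        i = repeats.index(row["repeat"])
        j = folds.index(row["fold"])
        y[m, i, j] = row["auroc"]
    missing_frac = np.isnan(y).mean()
    if missing_frac > spec.max_missing:
        raise ValueError(
            f"{missing_frac:.0%} of cells missing exceeds {spec.max_missing:.0%}"
        )
    cell_ok = ~np.isnan(y).any(axis=0)  # (I, J): listwise across models
    z = logit(np.clip(y, spec.clamp, 1 - spec.clamp))
    return models, z, cell_ok


def _make_loglik(z: np.ndarray, cell_ok: np.ndarray, spec: PerformanceModelSpec):
    M, I, J = z.shape
    # per repeat: stacked vector over (fold j, model m) for retained cells.
    # Repeats sharing a cell pattern share a covariance matrix, so group them
    # and factor once per pattern per likelihood call.
    groups: dict[bytes, dict] = {}
    for i in range(I):
        js = np.where(cell_ok[i])[0]
        if js.size == 0:
            continue
        vec = np.concatenate([z[:, i, j] for j in js])  # j-major, m-minor
        fold_idx = np.repeat(np.arange(js.size), M)
        model_pattern = np.tile(np.arange(M), js.size)
        same_fold = (fold_idx[:, None] == fold_idx[None, :]).astype(float)
        key = same_fold.tobytes()
        g = groups.setdefault(
            key, {"same_fold": same_fold, "pattern": model_pattern, "vecs": []}
        )
        g["vecs"].append(vec)
    grouped = [
        (g["same_fold"], g["pattern"], np.stack(g["vecs"]))
        for g in groups.values()
    ]
    beta_var = spec.beta_prior_sd**2
    sig_var = spec.sigma_prior_sd**2

    def log_prob(params: np.ndarray) -> float:
        beta = params[:M]
        log_sig = params[M:]
        if np.any(log_sig > 5) or np.any(log_sig < -12):
            return -np.inf
        sb, sc, se = np.exp(log_sig)
        lp = -0.5 * np.sum(beta**2) / beta_var
        # half-normal on the sds + log-Jacobian of the log transform
        lp += np.sum(-0.5 * np.exp(2 * log_sig) / sig_var + log_sig)
        for same_fold, model_pattern, vecs in grouped:
            d = same_fold.shape[0]
            C = sb**2 + sc**2 * same_fold + se**2 * np.eye(d)
            try:
                cf = cho_factor(C, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf
            resid = vecs - beta[model_pattern]  # (n_repeats_in_group, d)
            sol = cho_solve(cf, resid.T)
            quad = float(np.sum(resid.T * sol))
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            lp += -0.5 * (quad + vecs.shape[0] * (logdet + d * np.log(2 * np.pi)))
        return float(lp)

    return log_prob, M


def fit_performance_model(
    table: pd.DataFrame,
    spec: PerformanceModelSpec | None = None,
    n_chains: int = 2,
    n_draws: int = 2000,
    seed: int = 0,
    n_steps: int = 900,
    n_burn: int = 500,
) -> PosteriorDraws:
    """Sample the hierarchical model for one (task, availability) table.

    ``table`` needs columns model_id, repeat, fold, auroc for >= 2 models.
    ``n_draws`` is the number of retained posterior draws per chain; chains
    are independent seeded ensemble runs, and split-Rhat across them must stay
    below the spec bound or the result is flagged unconverged.
    """
    spec = spec or PerformanceModelSpec()
    models, z, cell_ok = _prepare(table, spec)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    log_prob, M = _make_loglik(z, cell_ok, spec)
    ndim = M + 3
    nwalkers = max(2 * ndim + 2, 16)
    # moment-based start: per-model means, crude variance split
    beta0 = np.nanmean(z, axis=(1, 2))
    resid0 = z - beta0[:, None, None]
    s0 = max(float(np.nanstd(resid0)), 0.05)
    start = np.concatenate([beta0, np.log([s0, s0, s0])])
    chains_beta, chains_sigma = [], []
    for ci in range(n_chains):
        rng = np.random.default_rng([seed, ci])
        p0 = start + 0.02 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob,
            moves=emcee.moves.StretchMove(),
        )
        sampler.random_state = np.random.RandomState(
            np.random.SeedSequence([seed, ci, 7]).generate_state(1)[0]
        ).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        flat = sampler.get_chain(discard=n_burn)  # (steps, walkers, ndim)
        flat = flat.reshape(-1, ndim)
        if flat.shape[0] < n_draws:
            raise ValueError("n_steps too small for requested n_draws")
        keep = flat[-n_draws:]
        chains_beta.append(keep[:, :M])
        chains_sigma.append(np.exp(keep[:, M:]))
    beta_arr = np.stack(chains_beta)  # (chains, draws, M)
    sigma_arr = np.stack(chains_sigma)
    if n_chains == 1:  # split the single chain so split-Rhat is defined
        half = beta_arr.shape[1] // 2
        diag_beta = np.stack([beta_arr[0, :half], beta_arr[0, half : 2 * half]])
        diag_sigma = np.stack([sigma_arr[0, :half], sigma_arr[0, half : 2 * half]])
    else:
        diag_beta, diag_sigma = beta_arr, sigma_arr
    idata = az.from_dict(posterior={"beta": diag_beta, "sigma": diag_sigma})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(idata)["beta"].max())
        ess = float(az.ess(idata)["beta"].min())
    converged = bool(rhat < spec.rhat_bound)
    if not converged:
        warnings.warn(f"split-Rhat {rhat:.3f} exceeds {spec.rhat_bound}; "
                      "treat posterior summaries with caution")
    beta_flat = beta_arr.reshape(-1, M)
    return PosteriorDraws(
        draws=expit(beta_flat),
        model_ids=models,
        beta_draws=beta_flat,
        sigma_draws=sigma_arr.reshape(-1, 3),
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


def p_best(draws: PosteriorDraws, focal: str) -> float:
    """Posterior probability the focal model's mean AUROC is the largest.

    Counts draws where the focal value is strictly greatest; exact ties are
    split uniformly among the tied models.
    """
    if focal not in draws.model_ids:
        raise KeyError(focal)
    vals = draws.draws
    if vals.shape[0] < 1 or vals.shape[1] < 2:
        raise ValueError("need >= 1 draw and >= 2 models")
    fi = draws.model_ids.index(focal)
    row_max = vals.max(axis=1)
    is_max = vals[:, fi] == row_max
    n_tied = (vals == row_max[:, None]).sum(axis=1)
    return float(np.mean(np.where(is_max, 1.0 / n_tied, 0.0)))


def summarize(
    pbest: pd.DataFrame, availability_cutoff: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Task x availability matrix of P(best) plus per-task median and IQR
    across availabilities >= the cutoff.

    ``pbest`` is long-format with columns task, availability, p_best.
    """
    if pbest.empty:
        raise ValueError("no cells to summarize")
    wide = pbest.pivot(index="task", columns="availability", values="p_best")
    rows = []
    for task, grp in pbest.groupby("task"):
        sel = grp[grp["availability"] >= availability_cutoff]["p_best"]
        if sel.empty:
            sel = grp["p_best"]
        rows.append(
            {
                "task": task,
                "median_p_best": float(sel.median()),
                "iqr_low": float(sel.quantile(0.25)),
                "iqr_high": float(sel.quantile(0.75)),
            }
        )
    return wide, pd.DataFrame(rows)
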
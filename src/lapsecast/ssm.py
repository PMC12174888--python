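"""Person-specific linear-Gaussian state space models for lapse risk.

Each participant is modelled with a k-dimensional latent state (k=2 by
default) evolving as

    x_{t+1} = B x_t + w_t,          w_t ~ N(0, I)

observed through ten channels — nine morning-EMA items rescaled to [0, 1]
plus a binary lapse indicator treated as a linear-Gaussian channel —

    y_t = A x_t + c + v_t,          v_t ~ N(0, diag(r))

Identifiability conventions (linear-Gaussian SSMs are invariant to latent
rotations): the process noise covariance is fixed to the identity, B is
diagonal with entries in (-1, 1) sorted descending, the transition offset is
fixed to zero (absorbed into c), and each latent's loading column is
sign-flipped so its column sum is non-negative. The initial state is the
stationary law N(0, diag(1/(1-B_jj^2))).

Fitting is by MLE or MAP (Kalman-filter likelihood, plus cohort-derived
empirical priors for MAP) over an unconstrained transformed parameter vector;
risk is read out by propagating the filtered state forward and computing the
Gaussian exceedance probability of the lapse channel at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.stats import norm

from .cohort import Cohort, ParticipantSeries

N_CHANNELS = 10
LAPSE_CHANNEL = 9  # index of the lapse channel in the 10-vector
VAR_FLOOR = 1e-6
# A {0,1} channel observed through a Gaussian cannot meaningfully claim less
# residual noise than a low-rate Bernoulli: windows with no lapses would
# otherwise drive the variance to zero and flatten the risk readout. 0.02 is
# the Bernoulli variance at a ~2% daily lapse rate.
LAPSE_VAR_FLOOR = 0.02
_B_SCALE = 0.995  # |B_jj| < _B_SCALE keeps the chain comfortably stationary

__all__ = [
    "N_CHANNELS",
    "LAPSE_CHANNEL",
    "VAR_FLOOR",
    "SsmParams",
    "SsmObservation",
    "FilterResult",
    "FitResult",
    "PriorSpec",
    "kalman_filter",
    "mle_fit",
    "map_fit",
    "fit_mle_obs",
    "fit_map_obs",
    "build_priors",
    "predict_risk",
    "series_to_obs",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class SsmParams:
    """Model parameters: loadings A (n x k), offsets c, obs-noise variances r
    (diagonal of R), transition diagonal b. Q = I, d = 0, mu0 = 0 are fixed."""

    A: np.ndarray
    c: np.ndarray
    r: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.c = np.asarray(self.c, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        n, k = self.A.shape
        if self.c.shape != (n,) or self.r.shape != (n,) or self.b.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if (self.r <= 0).any():
            raise ValueError("observation-noise variances must be positive")
        if (np.abs(self.b) >= 1).any():
            raise ValueError("|B_jj| must be < 1")

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    def stationary_var(self) -> np.ndarray:
        """Diagonal of the stationary latent covariance (Q = I, B diagonal)."""
        return 1.0 / (1.0 - self.b**2)

    def canonicalize(self) -> "SsmParams":
        """Sort latents by b descending; flip signs so A column sums are >= 0."""
        order = np.argsort(-self.b, kind="stable")
        A = self.A[:, order].copy()
        b = self.b[order].copy()
        for j in range(A.shape[1]):
            if A[:, j].sum() < 0:
                A[:, j] = -A[:, j]
        return SsmParams(A=A, c=self.c.copy(), r=self.r.copy(), b=b)

    def simulate(
        self, T: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw latent trajectory (T, k) and continuous observations (T, n)."""
        k, n = self.k, self.n_channels
        x = np.empty((T, k))
        x[0] = rng.normal(0.0, np.sqrt(self.stationary_var()))
        for t in range(1, T):
            x[t] = self.b * x[t - 1] + rng.standard_normal(k)
        y = x @ self.A.T + self.c + rng.normal(0.0, np.sqrt(self.r), size=(T, n))
        return x, y

    # -- flat transformed vector used by the optimizer ---------------------
    def to_vector(self) -> np.ndarray:
        u_r = np.log(np.maximum(self.r - VAR_FLOOR, 1e-300))
        u_b = np.arctanh(np.clip(self.b / _B_SCALE, -1 + 1e-12, 1 - 1e-12))
        return np.concatenate([self.A.ravel(), self.c, u_r, u_b])

    @classmethod
    def from_vector(cls, theta: np.ndarray, n: int, k: int) -> "SsmParams":
        nA = n * k
        A = theta[:nA].reshape(n, k)
        c = theta[nA : nA + n]
        r = VAR_FLOOR + np.exp(theta[nA + n : nA + 2 * n])
        b = _B_SCALE * np.tanh(theta[nA + 2 * n :])
        return cls(A=A, c=c, r=r, b=b)

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "c": self.c.tolist(),
            "r": self.r.tolist(),
            "b": self.b.tolist(),
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SsmParams":
        return cls(A=np.array(d["A"]), c=np.array(d["c"]), r=np.array(d["r"]),
                   b=np.array(d["b"]))


@dataclass(frozen=True)
class SsmObservation:
    """One day's 10-channel observation with a per-channel missingness mask."""

    y: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if y.shape != mask.shape:
            raise ValueError("y and mask must have the same shape")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "mask", mask)


@dataclass
class FilterResult:
    """Per-day predicted / filtered state moments and total log-likelihood."""

    pred_mean: np.ndarray
    pred_cov: np.ndarray
    filt_mean: np.ndarray
    filt_cov: np.ndarray
    loglik: float


@dataclass
class FitResult:
    """Fitted parameters plus the achieved objective and a convergence flag."""

    params: SsmParams
    loglik: float
    logpost: float
    converged: bool


# ---------------------------------------------------------------------------
# Numba filter kernels (diagonal R -> sequential scalar updates)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _loglik_core(b, A, c, rvar, y, mask):  # pragma: no cover - numba
    T, n = y.shape
    k = b.shape[0]
    m = np.zeros(k)
    P = np.zeros((k, k))
    for j in range(k):
        P[j, j] = 1.0 / (1.0 - b[j] * b[j])
    ll = 0.0
    log2pi = 1.8378770664093453
    Pa = np.empty(k)
    for t in range(T):
        if t > 0:
            for i in range(k):
                m[i] = b[i] * m[i]
            for i in range(k):
                for j in range(k):
                    P[i, j] = b[i] * b[j] * P[i, j]
                P[i, i] += 1.0
        for ch in range(n):
            if mask[t, ch]:
                yhat = c[ch]
                for i in range(k):
                    yhat += A[ch, i] * m[i]
                for i in range(k):
                    s = 0.0
                    for j in range(k):
                        s += P[i, j] * A[ch, j]
                    Pa[i] = s
                svar = rvar[ch]
                for i in range(k):
                    svar += A[ch, i] * Pa[i]
                if svar <= 0.0:
                    return np.nan
                e = y[t, ch] - yhat
                ll += -0.5 * (log2pi + np.log(svar) + e * e / svar)
                for i in range(k):
                    m[i] += Pa[i] * e / svar
                for i in range(k):
                    for j in range(k):
                        P[i, j] -= Pa[i] * Pa[j] / svar
    return ll


@njit(cache=True)
def _filter_core(b, A, c, rvar, y, mask):  # pragma: no cover - numba
    T, n = y.shape
    k = b.shape[0]
    m = np.zeros(k)
    P = np.zeros((k, k))
    for j in range(k):
        P[j, j] = 1.0 / (1.0 - b[j] * b[j])
    pred_mean = np.empty((T, k))
    pred_cov = np.empty((T, k, k))
    filt_mean = np.empty((T, k))
    filt_cov = np.empty((T, k, k))
    ll = 0.0
    log2pi = 1.8378770664093453
    Pa = np.empty(k)
    err_day = -1
    for t in range(T):
        if t > 0:
            for i in range(k):
                m[i] = b[i] * m[i]
            for i in range(k):
                for j in range(k):
                    P[i, j] = b[i] * b[j] * P[i, j]
                P[i, i] += 1.0
        pred_mean[t] = m
        pred_cov[t] = P
        for ch in range(n):
            if mask[t, ch]:
                yhat = c[ch]
                for i in range(k):
                    yhat += A[ch, i] * m[i]
                for i in range(k):
                    s = 0.0
                    for j in range(k):
                        s += P[i, j] * A[ch, j]
                    Pa[i] = s
                svar = rvar[ch]
                for i in range(k):
                    svar += A[ch, i] * Pa[i]
                if svar <= 0.0:
                    err_day = t
                    return ll, pred_mean, pred_cov, filt_mean, filt_cov, err_day
                e = y[t, ch] - yhat
                ll += -0.5 * (log2pi + np.log(svar) + e * e / svar)
                for i in range(k):
                    m[i] += Pa[i] * e / svar
                for i in range(k):
                    for j in range(k):
                        P[i, j] -= Pa[i] * Pa[j] / svar
        filt_mean[t] = m
        filt_cov[t] = P
    return ll, pred_mean, pred_cov, filt_mean, filt_cov, err_day


@njit(cache=True)
def _negobj_core(theta, n, k, y, mask, use_prior,
                 am, asd, cm, csd, bm, bsd, blog, lrm, lrsd
                 ):  # pragma: no cover - numba
    """-(loglik + log prior) with the parameter transform inlined.

    The optimizer calls this tens of thousands of times per protocol run
    (finite-difference gradients), so the whole objective lives in one kernel.
    """
    nA = n * k
    A = theta[:nA].copy().reshape(n, k)
    c = theta[nA : nA + n]
    rvar = np.empty(n)
    logr = np.empty(n)
    for ch in range(n):
        rv = 1e-6 + np.exp(theta[nA + n + ch])
        rvar[ch] = rv
        logr[ch] = np.log(rv)
    b = np.empty(k)
    for j in range(k):
        b[j] = 0.995 * np.tanh(theta[nA + 2 * n + j])
    ll = _loglik_core(b, A, c, rvar, y, mask)
    if not np.isfinite(ll):
        return 1e12
    if use_prior:
        halflog2pi = 0.9189385332046727
        for ch in range(n):
            for j in range(k):
                zz = (A[ch, j] - am[ch, j]) / asd[ch, j]
                ll += -0.5 * zz * zz - np.log(asd[ch, j]) - halflog2pi
            zz = (c[ch] - cm[ch]) / csd[ch]
            ll += -0.5 * zz * zz - np.log(csd[ch]) - halflog2pi
            zz = (logr[ch] - lrm[ch]) / lrsd[ch]
            ll += -0.5 * zz * zz - np.log(lrsd[ch]) - halflog2pi
        for j in range(k):
            zz = (b[j] - bm[j]) / bsd[j]
            ll += -0.5 * zz * zz - np.log(bsd[j]) - halflog2pi - blog[j]
        if not np.isfinite(ll):
            return 1e12
    return -ll


@njit(cache=True)
def _negobj_grad_core(theta, n, k, y, mask, use_prior,
                      am, asd, cm, csd, bm, bsd, blog, lrm, lrsd
                      ):  # pragma: no cover - numba
    """Objective plus central-difference gradient in a single kernel call."""
    f0 = _negobj_core(theta, n, k, y, mask, use_prior,
                      am, asd, cm, csd, bm, bsd, blog, lrm, lrsd)
    g = np.empty(theta.size)
    th = theta.copy()
    for i in range(theta.size):
        h = 3.0e-6 * max(1.0, abs(theta[i]))
        th[i] = theta[i] + h
        fp = _negobj_core(th, n, k, y, mask, use_prior,
                          am, asd, cm, csd, bm, bsd, blog, lrm, lrsd)
        th[i] = theta[i] - h
        fm = _negobj_core(th, n, k, y, mask, use_prior,
                          am, asd, cm, csd, bm, bsd, blog, lrm, lrsd)
        th[i] = theta[i]
        g[i] = (fp - fm) / (2.0 * h)
    return f0, g


_DUMMY1 = np.zeros(1)
_DUMMY2 = np.zeros((1, 1))


def _obs_to_arrays(
    obs: Sequence[SsmObservation] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obs, tuple) and len(obs) == 2:
        y, mask = obs
        return np.asarray(y, dtype=float), np.asarray(mask, dtype=bool)
    y = np.stack([o.y for o in obs]).astype(float)
    mask = np.stack([o.mask for o in obs]).astype(bool)
    return y, mask


def kalman_filter(
    params: SsmParams,
    obs: Sequence[SsmObservation] | tuple[np.ndarray, np.ndarray],
) -> FilterResult:
    """Gaussian filtering restricted each day to the unmasked channels.

    Fully-missing days contribute zero log-likelihood and simply propagate the
    state prior. With diagonal R the vector update factors into sequential
    scalar updates, which is what the kernel does.
    """
    y, mask = _obs_to_arrays(obs)
    if y.ndim != 2 or y.shape[0] < 1:
        raise ValueError("need at least one day of observations")
    ynum = np.where(mask, y, 0.0)  # masked entries never read, but keep finite
    ll, pm, pc, fm, fc, err_day = _filter_core(
        params.b, params.A, params.c, params.r, ynum, mask
    )
    if err_day >= 0:
        raise FloatingPointError(
            f"non-positive innovation variance at day index {err_day}"
        )
    return FilterResult(pred_mean=pm, pred_cov=pc, filt_mean=fm, filt_cov=fc,
                        loglik=float(ll))


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Per-parameter empirical prior: Gaussian for A and c entries, Gaussian
    truncated to (-1, 1) for the B diagonal, log-normal for the R diagonal.

    Scales are floored at ``sd_floor`` when built from data; hand-built specs
    may use any positive scales (e.g. for flat- or tight-prior limits).
    """

    a_mean: np.ndarray
    a_sd: np.ndarray
    c_mean: np.ndarray
    c_sd: np.ndarray
    b_mean: np.ndarray
    b_sd: np.ndarray
    logr_mean: np.ndarray
    logr_sd: np.ndarray
    sd_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_mean", "a_sd", "c_mean", "c_sd", "b_mean", "b_sd",
                     "logr_mean", "logr_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.a_sd <= 0).any() or (self.c_sd <= 0).any() or \
           (self.b_sd <= 0).any() or (self.logr_sd <= 0).any():
            raise ValueError("prior scales must be positive")
        # truncated-normal normalizing constants for the b components
        lo = norm.cdf((-1.0 - self.b_mean) / self.b_sd)
        hi = norm.cdf((1.0 - self.b_mean) / self.b_sd)
        self._b_lognorm = np.log(np.maximum(hi - lo, 1e-300))

    def logpdf(self, params: SsmParams) -> float:
        """Log prior density at ``params`` in the declared coordinates
        (natural scale for A, c, b; log scale for the variances)."""
        lp = norm.logpdf(params.A, self.a_mean, self.a_sd).sum()
        lp += norm.logpdf(params.c, self.c_mean, self.c_sd).sum()
        lp += (
            norm.logpdf(params.b, self.b_mean, self.b_sd) - self._b_lognorm
        ).sum()
        lp += norm.logpdf(np.log(params.r), self.logr_mean, self.logr_sd).sum()
        return float(lp)

    def mean_params(self) -> SsmParams:
        b = np.clip(self.b_mean, -_B_SCALE + 1e-6, _B_SCALE - 1e-6)
        return SsmParams(
            A=self.a_mean.copy(), c=self.c_mean.copy(),
            r=VAR_FLOOR + np.exp(self.logr_mean), b=b,
        ).canonicalize()

    def scaled(self, factor: float) -> "PriorSpec":
        """Same centres, all scales multiplied by ``factor``."""
        return PriorSpec(
            a_mean=self.a_mean, a_sd=self.a_sd * factor,
            c_mean=self.c_mean, c_sd=self.c_sd * factor,
            b_mean=self.b_mean, b_sd=self.b_sd * factor,
            logr_mean=self.logr_mean, logr_sd=self.logr_sd * factor,
            sd_floor=0.0,
        )

    @classmethod
    def around(cls, params: SsmParams, scale: float) -> "PriorSpec":
        """Prior centred at ``params`` with a common scale (testing aid)."""
        n, k = params.n_channels, params.k
        return cls(
            a_mean=params.A, a_sd=np.full((n, k), scale),
            c_mean=params.c, c_sd=np.full(n, scale),
            b_mean=params.b, b_sd=np.full(k, scale),
            logr_mean=np.log(params.r), logr_sd=np.full(n, scale),
        )

    def to_dict(self) -> dict:
        return {
            "a_mean": self.a_mean.tolist(), "a_sd": self.a_sd.tolist(),
            "c_mean": self.c_mean.tolist(), "c_sd": self.c_sd.tolist(),
            "b_mean": self.b_mean.tolist(), "b_sd": self.b_sd.tolist(),
            "logr_mean": self.logr_mean.tolist(), "logr_sd": self.logr_sd.tolist(),
            "sd_floor": self.sd_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**{k: (np.array(v) if isinstance(v, list) else v)
                      for k, v in d.items()})


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def series_to_obs(
    series: ParticipantSeries,
    ema_window: tuple[int, int],
    lapse_window: tuple[int, int],
    ordinal_scale: tuple[int, int] = (1, 5),
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (T_w, 10) observation matrix + mask for a fitting window.

    ``ema_window`` and ``lapse_window`` are inclusive 1-based day ranges; in
    the rolling protocol the lapse window ends one day before the EMA window,
    masking the to-be-predicted day's label. EMA items are rescaled to [0,1].
    """
    lo, hi = ema_window
    if not (1 <= lo <= hi <= series.study_length):
        raise ValueError("ema_window outside 1..T")
    llo, lhi = lapse_window
    smin, smax = ordinal_scale
    raw = series.ema_matrix()[lo - 1 : hi]
    T_w = hi - lo + 1
    y = np.zeros((T_w, N_CHANNELS))
    mask = np.zeros((T_w, N_CHANNELS), dtype=bool)
    ema_obs = ~np.isnan(raw)
    y[:, :LAPSE_CHANNEL] = np.where(ema_obs, (raw - smin) / (smax - smin), 0.0)
    mask[:, :LAPSE_CHANNEL] = ema_obs
    days = np.arange(lo, hi + 1)
    in_lapse = (days >= llo) & (days <= lhi)
    y[:, LAPSE_CHANNEL] = np.where(in_lapse, series.lapse[lo - 1 : hi], 0.0)
    mask[:, LAPSE_CHANNEL] = in_lapse
    return y, mask


def _neg_objective(theta, n, k, y, mask, prior):
    if prior is None:
        return _negobj_core(theta, n, k, y, mask, False,
                            _DUMMY2, np.ones((1, 1)), _DUMMY1, np.ones(1),
                            _DUMMY1, np.ones(1), _DUMMY1, _DUMMY1, np.ones(1))
    return _negobj_core(theta, n, k, y, mask, True,
                        prior.a_mean, prior.a_sd, prior.c_mean, prior.c_sd,
                        prior.b_mean, prior.b_sd, prior._b_lognorm,
                        prior.logr_mean, prior.logr_sd)


_U_BOUND = 25.0  # bound on transformed coords keeps exp/tanh well-behaved


def _default_init(y, mask, k, rng) -> np.ndarray:
    """Data-driven start: per-channel moments, small random loadings."""
    n = y.shape[1]
    c0 = np.zeros(n)
    v0 = np.full(n, 0.05)
    for ch in range(n):
        obs = y[mask[:, ch], ch]
        if obs.size:
            c0[ch] = obs.mean()
            v0[ch] = max(float(obs.var()), 1e-4)
    A0 = rng.normal(0.0, 0.05, size=(n, k))
    b0 = np.clip(
        np.sort(rng.normal([0.6, 0.2][:k] + [0.0] * max(0, k - 2), 0.1))[::-1],
        -0.9, 0.9,
    )
    return SsmParams(A=A0, c=c0, r=v0, b=b0).to_vector()


def _fun_and_grad(theta, n, k, y, mask, prior):
    if prior is None:
        return _negobj_grad_core(
            theta, n, k, y, mask, False,
            _DUMMY2, np.ones((1, 1)), _DUMMY1, np.ones(1),
            _DUMMY1, np.ones(1), _DUMMY1, _DUMMY1, np.ones(1))
    return _negobj_grad_core(
        theta, n, k, y, mask, True,
        prior.a_mean, prior.a_sd, prior.c_mean, prior.c_sd,
        prior.b_mean, prior.b_sd, prior._b_lognorm,
        prior.logr_mean, prior.logr_sd)


def _resolve_r_lower(r_lower, n):
    """Per-channel variance lower bounds; "auto" floors a 10-channel model's
    lapse channel at the Bernoulli scale."""
    if r_lower is None:
        return np.full(n, VAR_FLOOR)
    if isinstance(r_lower, str) and r_lower == "auto":
        out = np.full(n, VAR_FLOOR)
        if n == N_CHANNELS:
            out[LAPSE_CHANNEL] = LAPSE_VAR_FLOOR
        return out
    out = np.asarray(r_lower, dtype=float)
    if out.shape != (n,):
        raise ValueError("r_lower must have one entry per channel")
    return out


def _optimize(theta0, n, k, y, mask, prior, maxiter, r_lower):
    lo = np.full(theta0.size, -_U_BOUND)
    hi = np.full(theta0.size, _U_BOUND)
    nA = n * k
    lo[nA + n : nA + 2 * n] = np.log(np.maximum(r_lower - VAR_FLOOR, 1e-12))
    res = minimize(
        _fun_and_grad,
        np.clip(theta0, lo, hi),
        args=(n, k, y, mask, prior),
        method="L-BFGS-B",
        jac=True,
        bounds=list(zip(lo, hi)),
        options={"maxiter": maxiter, "gtol": 1e-6, "maxfun": 200000},
    )
    return res


def fit_mle_obs(
    y: np.ndarray,
    mask: np.ndarray,
    k: int = 2,
    init: SsmParams | None = None,
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 150,
    r_lower="auto",
) -> FitResult:
    """Maximum-likelihood fit on raw (y, mask) arrays (see :func:`mle_fit`)."""
    return _fit_obs(y, mask, k, None, init, seed, n_restarts, maxiter, r_lower)


def fit_map_obs(
    y: np.ndarray,
    mask: np.ndarray,
    priors: PriorSpec,
    k: int = 2,
    init: SsmParams | None = None,
    seed: int = 0,
    n_restarts: int = 1,
    maxiter: int = 150,
    r_lower="auto",
) -> FitResult:
    """MAP fit on raw (y, mask) arrays (see :func:`map_fit`)."""
    if priors is None:
        raise ValueError("map fit requires a PriorSpec")
    return _fit_obs(y, mask, k, priors, init, seed, n_restarts, maxiter, r_lower)


def _fit_obs(y, mask, k, prior, init, seed, n_restarts, maxiter, r_lower="auto"):
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    y = np.where(mask, y, 0.0)
    n = y.shape[1]
    r_lo = _resolve_r_lower(r_lower, n)
    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(init.to_vector())
    elif prior is not None:
        starts.append(prior.mean_params().to_vector())
    while len(starts) < max(1, n_restarts):
        starts.append(_default_init(y, mask, k, rng))
    best = None
    for theta0 in starts:
        res = _optimize(theta0, n, k, y, mask, prior, maxiter, r_lo)
        if best is None or res.fun < best.fun:
            best = res
    params = SsmParams.from_vector(best.x, n, k).canonicalize()
    ll = float(_loglik_core(params.b, params.A, params.c, params.r, y, mask))
    logpost = ll + (prior.logpdf(params) if prior is not None else 0.0)
    return FitResult(params=params, loglik=ll, logpost=float(logpost),
                     converged=bool(best.success))


def mle_fit(
    series: ParticipantSeries,
    ema_window: tuple[int, int] | None = None,
    lapse_window: tuple[int, int] | None = None,
    ordinal_scale: tuple[int, int] = (1, 5),
    k: int = 2,
    init: SsmParams | None = None,
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 150,
) -> FitResult:
    """Maximize the Kalman-filter log-likelihood for one participant window.

    Windows default to the full trajectory. Optimization runs on the
    transformed scale (log variances, scaled tanh for the transition diagonal)
    with seeded quasi-Newton restarts; the returned parameters are
    canonicalized. Non-convergence is flagged on the result, which still
    carries the best parameters found.
    """
    if ema_window is None:
        ema_window = (1, series.study_length)
    if lapse_window is None:
        lapse_window = (1, series.study_length)
    y, mask = series_to_obs(series, ema_window, lapse_window, ordinal_scale)
    return fit_mle_obs(y, mask, k=k, init=init, seed=seed,
                       n_restarts=n_restarts, maxiter=maxiter)


def map_fit(
    series: ParticipantSeries,
    priors: PriorSpec,
    ema_window: tuple[int, int] | None = None,
    lapse_window: tuple[int, int] | None = None,
    ordinal_scale: tuple[int, int] = (1, 5),
    k: int = 2,
    init: SsmParams | None = None,
    seed: int = 0,
    n_restarts: int = 1,
    maxiter: int = 150,
) -> FitResult:
    """Maximize likelihood + log prior (MAP); defaults start at the prior mode.

    With very diffuse priors this coincides with :func:`mle_fit`; with very
    tight priors it returns (numerically) the prior centre. MAP is what lets a
    lapse-relevant model exist before the participant has ever lapsed.
    """
    if ema_window is None:
        ema_window = (1, series.study_length)
    if lapse_window is None:
        lapse_window = (1, series.study_length)
    y, mask = series_to_obs(series, ema_window, lapse_window, ordinal_scale)
    return fit_map_obs(y, mask, priors, k=k, init=init, seed=seed,
                       n_restarts=n_restarts, maxiter=maxiter)


def build_priors(
    training: Cohort,
    sd_floor: float = 0.05,
    k: int = 2,
    seed: int = 0,
    mle_cache: dict[str, SsmParams] | None = None,
) -> PriorSpec:
    """Empirical priors from MLE fits on training participants' full series.

    Each training participant is fit by MLE on their complete trajectory; the
    canonicalized estimates are pooled and each scalar parameter's declared
    family is fit by moment matching (log-moments for the variances). Scales
    are floored at ``sd_floor``. ``mle_cache`` (participant_id -> SsmParams)
    lets a cross-validation driver reuse fits across folds, since a
    participant's full-trajectory MLE does not depend on the fold split.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training participants")
    fits: list[SsmParams] = []
    for p in training:
        if mle_cache is not None and p.participant_id in mle_cache:
            fits.append(mle_cache[p.participant_id])
            continue
        try:
            res = mle_fit(p, ordinal_scale=training.ordinal_scale, k=k, seed=seed)
        except (FloatingPointError, ValueError):
            continue
        fits.append(res.params)
        if mle_cache is not None:
            mle_cache[p.participant_id] = res.params
    if not fits:
        raise RuntimeError("all training MLE fits failed")
    A = np.stack([f.A for f in fits])
    c = np.stack([f.c for f in fits])
    b = np.stack([f.b for f in fits])
    logr = np.log(np.stack([f.r for f in fits]))

    def _sd(x):
        return np.maximum(x.std(axis=0, ddof=1) if x.shape[0] > 1 else 0.0,
                          sd_floor)

    # Variance estimates pinned at the optimizer's lower bound (constant
    # channels, e.g. the lapse channel of never-lapsed participants) are
    # boundary artefacts, not interior MLEs; folding their logs into the
    # log-normal moments would drag the prior toward degenerate noise. Use
    # interior estimates per channel when at least two exist.
    lrm, lrs = interior_log_moments(logr, sd_floor)
    return PriorSpec(
        a_mean=A.mean(axis=0), a_sd=_sd(A),
        c_mean=c.mean(axis=0), c_sd=_sd(c),
        b_mean=np.clip(b.mean(axis=0), -0.99, 0.99), b_sd=_sd(b),
        logr_mean=lrm, logr_sd=lrs,
        sd_floor=sd_floor,
    )


def interior_log_moments(
    logr: np.ndarray, sd_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/SD of log-variance estimates, excluding boundary fits."""
    bound = np.log(10 * VAR_FLOOR)
    n = logr.shape[1]
    mean = np.empty(n)
    sd = np.empty(n)
    for ch in range(n):
        pool = logr[:, ch]
        interior = pool[pool > bound]
        use = interior if interior.size >= 2 else pool
        mean[ch] = use.mean()
        sd[ch] = max(use.std(ddof=1) if use.size > 1 else 0.0, sd_floor)
    return mean, sd


# ---------------------------------------------------------------------------
# Risk prediction
# ---------------------------------------------------------------------------


def predict_risk(
    params: SsmParams,
    state_mean: np.ndarray,
    state_cov: np.ndarray,
    k: int,
    method: str = "analytic",
    n_rollouts: int = 1000,
    seed: int | None = None,
) -> float:
    """Window lapse risk from the filtered state by playing the model forward.

    For each day s in the horizon the lapse channel is predicted as Gaussian
    with mean m_s and SD sigma_s; the per-day score is the exceedance
    probability p_s = Phi((m_s - 0.5) / sigma_s). ``analytic`` combines days as
    1 - prod(1 - p_s) (exact when B = 0); ``monte_carlo`` simulates seeded
    rollouts of the transition equation and scores the fraction with any day's
    lapse-channel draw above 0.5. k = 0 reduces to p_t for both methods.
    """
    if k < 0:
        raise ValueError("horizon k must be >= 0")
    a_l = params.A[LAPSE_CHANNEL]
    c_l = params.c[LAPSE_CHANNEL]
    r_l = params.r[LAPSE_CHANNEL]
    m = np.asarray(state_mean, dtype=float).copy()
    P = np.asarray(state_cov, dtype=float).copy()
    if method == "analytic":
        log_surv = 0.0
        for _ in range(k + 1):
            mu = a_l @ m + c_l
            sd = math.sqrt(max(a_l @ P @ a_l + r_l, 1e-300))
            p = norm.cdf((mu - 0.5) / sd)
            p = min(max(p, 1e-15), 1 - 1e-15)
            log_surv += math.log1p(-p)
            m = params.b * m
            P = np.outer(params.b, params.b) * P + np.eye(params.k)
        return float(-np.expm1(log_surv))
    if method == "monte_carlo":
        if n_rollouts < 1:
            raise ValueError("n_rollouts must be >= 1")
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(P + 1e-12 * np.eye(params.k))
        x = m + rng.standard_normal((n_rollouts, params.k)) @ L.T
        hit = np.zeros(n_rollouts, dtype=bool)
        for s in range(k + 1):
            y_l = x @ a_l + c_l + rng.normal(0.0, math.sqrt(r_l), size=n_rollouts)
            hit |= y_l > 0.5
            if s < k:
                x = x * params.b + rng.standard_normal((n_rollouts, params.k))
        return float(hit.mean())
    raise ValueError(f"unknown method {method!r}")
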
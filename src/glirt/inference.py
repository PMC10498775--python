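"""Posterior sampling, convergence diagnostics, and posterior summaries.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme that
exploits the conditional-independence structure of item response models:
given the item parameters, the person abilities are mutually independent
(and vice versa), so every block updates all of its coordinates in one
vectorized proposal, and all chains advance simultaneously as a leading
array dimension.  Per-coordinate proposal scales are tuned toward a 0.44
acceptance rate by Robbins-Monro adaptation during burn-in and frozen
afterwards, so the retained draws come from a fixed, valid Markov kernel.

Sampled blocks by family:
  glogit_free            theta, beta, lambda1, lambda2, sigma_beta, sigma_lambda
  rasch / pno_glogit /
  cllm_glogit            theta, beta, sigma_beta (shapes fixed)
  pno_exact / cllm_exact theta, beta, sigma_beta
  threepl / fourpl       theta, beta, log alpha, c (, d), sigma_beta

Priors follow the model's hierarchical specification: theta ~ N(0,1) (which
anchors the latent scale), beta ~ N(0, sigma_beta^2), shapes
~ N(0, sigma_lambda^2) truncated to (-1, inf), scales ~ half-Cauchy(0, 5);
for the 3PL/4PL, log alpha ~ N(0,1), c ~ U(0, 0.5) and d ~ U(0.5, 1), the
latter read as a uniform prior on the slipping probability 1 - d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, log_ndtr

from .io import ResponseMatrix
from .models import (
    GLOGIT_FAMILIES,
    ModelSpec,
    _h_upper,
    log_half_cauchy,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "sample_posterior",
    "compute_rhat",
    "hpdi",
    "posterior_summary",
]

_EXP_CAP = 700.0
_TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random-walk updates
_SHAPE_SWEEPS = 3      # shape-block refreshes per iteration (free model)


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.  Defaults follow the reference study design:
    4 chains x 3000 iterations with a 2000-iteration burn-in."""

    n_chains: int = 4
    n_iterations: int = 3000
    n_burnin: int = 2000
    seed: int = 0
    init: str = "prior_draw"  # or "near_zero"
    store_pointwise: bool = True
    fixed_sigma_beta: Optional[float] = None  # fix the beta prior scale (oracles)

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.init not in ("prior_draw", "near_zero"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class FitResult:
    """Posterior draws plus diagnostics.

    ``draws`` maps block names to arrays of shape (chains, retained, dim)
    (scalars: (chains, retained)).  ``pointwise_loglik`` has one row per
    pooled retained draw and one column per observed cell, in row-major
    (person, item) order of the observed cells.
    """

    draws: Dict[str, np.ndarray]
    rhat: pd.Series
    pointwise_loglik: Optional[np.ndarray]
    config: FitConfig
    model: ModelSpec
    n_persons: int
    n_items: int
    obs_mask: np.ndarray                 # True where observed
    mean_point: Dict[str, np.ndarray]    # posterior means, back-transformed
    deviance_at_mean: float
    acceptance: Dict[str, float] = field(default_factory=dict)

    def pooled(self, name: str) -> np.ndarray:
        """Draws of a block pooled across chains: (chains*retained, dim)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_names(self):
        for name, a in self.draws.items():
            if a.ndim == 2:
                yield name
            else:
                for k in range(a.shape[2]):
                    yield f"{name}[{k + 1}]"


# --------------------------------------------------------------------------
# likelihood kernels: (C, N, J) log-lik cells, missing cells zeroed
# --------------------------------------------------------------------------

def _h_raw(eta, lam1, lam2):
    pos = eta > 0
    up = _h_upper(np.where(pos, eta, 0.0), lam1)
    lo = -_h_upper(np.where(pos, 0.0, -eta), lam2)
    return np.where(pos, up, lo)


def _cells_glogit(x, obs, theta, beta, lam1, lam2, sgn=None):
    # sgn = 2x - 1 lets one log_expit call serve both response values:
    # loglik = log_expit((2x-1) * h)
    if sgn is None:
        sgn = 2.0 * x - 1.0
    eta = theta[:, :, None] - beta[:, None, :]
    if np.all(lam1 == 0.0) and np.all(lam2 == 0.0):
        h = eta  # logit special case (Rasch)
    else:
        h = _h_raw(eta, lam1[:, None, :], lam2[:, None, :])
    return log_expit(sgn * h) * obs


def _cells_pno(x, obs, theta, beta, sgn=None):
    if sgn is None:
        sgn = 2.0 * x - 1.0
    eta = theta[:, :, None] - beta[:, None, :]
    return log_ndtr(sgn * eta) * obs


def _cells_cllm(x, obs, theta, beta, sgn=None):
    eta = theta[:, :, None] - beta[:, None, :]
    g = np.exp(np.minimum(eta, 30.0))
    logp = np.log(np.maximum(-np.expm1(-g), 1e-300))
    cells = np.where(x, logp, -g)
    return cells * obs


def _cells_pl(x, obs, theta, beta, alpha, c, d, sgn=None):
    eta = theta[:, :, None] - beta[:, None, :]
    p = c[:, None, :] + (d - c)[:, None, :] * expit(alpha[:, None, :] * eta)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    cells = np.where(x, np.log(p), np.log1p(-p))
    return cells * obs


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, init_scale):
        self.log_s = np.full(shape, np.log(init_scale))
        self.accepted = 0.0
        self.proposed = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accept_prob, t):
        gamma = (t + 1.0) ** -0.6
        self.log_s += gamma * (accept_prob - _TARGET_ACCEPT)

    def track(self, accepted):
        self.accepted += float(np.mean(accepted))
        self.proposed += 1


def sample_posterior(model: ModelSpec, data: ResponseMatrix,
                     config: FitConfig) -> FitResult:
    """Draw from the joint posterior of ``model`` given ``data``.

    Deterministic for a fixed (model, data, config): the same seed yields
    identical draws.  Raises on persons/items with no observed responses.
    """
    x = data.values.astype(bool)
    obs = ~data.mask
    n, j = data.values.shape
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("at least one person has no observed responses")
    if (obs.sum(axis=0) == 0).any():
        raise ValueError("at least one item has no observed responses")

    C = config.n_chains
    total, burn = config.n_iterations, config.n_burnin
    retained = total - burn
    rng = np.random.default_rng(config.seed)
    obs_f = obs.astype(float)

    family = model.family
    free = family == "glogit_free"
    is_glogit = family in GLOGIT_FAMILIES
    is_pl = family in ("threepl", "fourpl")
    fourpl = family == "fourpl"

    # ---- state initialization -------------------------------------------
    if config.init == "prior_draw":
        theta = rng.normal(0.0, 1.0, (C, n))
        beta = rng.normal(0.0, 1.0, (C, j))
        ls_beta = np.log(rng.uniform(0.5, 1.5, C))
        ls_lam = np.log(rng.uniform(0.5, 1.5, C))
        log_alpha = rng.normal(0.0, 0.5, (C, j))
        c = rng.uniform(0.05, 0.45, (C, j))
        d = rng.uniform(0.55, 0.95, (C, j)) if fourpl else np.ones((C, j))
    else:
        theta = 0.01 * rng.standard_normal((C, n))
        beta = 0.01 * rng.standard_normal((C, j))
        ls_beta = np.zeros(C)
        ls_lam = np.zeros(C)
        log_alpha = np.zeros((C, j))
        c = np.full((C, j), 0.2)
        d = np.full((C, j), 0.8) if fourpl else np.ones((C, j))
    # shapes start at 0: every chain begins at the logit special case
    if free:
        lam1 = np.zeros((C, j))
        lam2 = np.zeros((C, j))
    elif is_glogit:
        s = model.fixed_shape
        lam1 = np.full((C, j), s.lambda1)
        lam2 = np.full((C, j), s.lambda2)
    if config.fixed_sigma_beta is not None:
        ls_beta = np.full(C, np.log(config.fixed_sigma_beta))

    sgn = 2.0 * x.astype(float) - 1.0

    def cells(th, be, l1=None, l2=None, la=None, cc=None, dd=None):
        if is_glogit:
            return _cells_glogit(x, obs_f, th, be,
                                 l1 if l1 is not None else lam1,
                                 l2 if l2 is not None else lam2, sgn)
        if family == "pno_exact":
            return _cells_pno(x, obs_f, th, be, sgn)
        if family == "cllm_exact":
            return _cells_cllm(x, obs_f, th, be, sgn)
        return _cells_pl(x, obs_f, th, be,
                         np.exp(la if la is not None else log_alpha),
                         cc if cc is not None else c,
                         dd if dd is not None else d, sgn)

    L = cells(theta, beta)

    # ---- adaptive proposal scales ---------------------------------------
    ad = {
        "theta": _Adapt((C, n), 0.8),
        "beta": _Adapt((C, j), 0.5),
        "shift": _Adapt(C, 0.1),
    }
    if free:
        ad["lam1"] = _Adapt((C, j), 0.5)
        ad["lam2"] = _Adapt((C, j), 0.5)
        ad["sigma_lambda"] = _Adapt(C, 0.3)
    if config.fixed_sigma_beta is None:
        ad["sigma_beta"] = _Adapt(C, 0.3)
    if is_pl:
        ad["log_alpha"] = _Adapt((C, j), 0.3)
        ad["c"] = _Adapt((C, j), 0.1)
        if fourpl:
            ad["d"] = _Adapt((C, j), 0.1)

    # ---- storage ---------------------------------------------------------
    store: Dict[str, np.ndarray] = {
        "theta": np.empty((C, retained, n)),
        "beta": np.empty((C, retained, j)),
    }
    if free:
        store["lambda1"] = np.empty((C, retained, j))
        store["lambda2"] = np.empty((C, retained, j))
        store["sigma_lambda"] = np.empty((C, retained))
    if config.fixed_sigma_beta is None:
        store["sigma_beta"] = np.empty((C, retained))
    if is_pl:
        store["alpha"] = np.empty((C, retained, j))
        store["c"] = np.empty((C, retained, j))
        if fourpl:
            store["d"] = np.empty((C, retained, j))
    obs_flat = obs.ravel()
    m_obs = int(obs_flat.sum())
    pointwise = (np.empty((C, retained, m_obs), dtype=np.float32)
                 if config.store_pointwise else None)

    sum_b2 = (beta ** 2).sum(axis=1)

    for t in range(total):
        sb2 = np.exp(2.0 * ls_beta)  # sigma_beta^2 per chain

        # -- theta ---------------------------------------------------------
        a = ad["theta"]
        prop = theta + a.scale * rng.standard_normal((C, n))
        Lp = cells(prop, beta)
        logr = (Lp - L).sum(axis=2) + 0.5 * (theta ** 2 - prop ** 2)
        acc = np.log(rng.random((C, n))) < logr
        theta = np.where(acc, prop, theta)
        L = np.where(acc[:, :, None], Lp, L)
        if t < burn:
            a.update(np.exp(np.minimum(logr, 0.0)), t)
        else:
            a.track(acc)

        # -- beta ----------------------------------------------------------
        a = ad["beta"]
        prop = beta + a.scale * rng.standard_normal((C, j))
        Lp = cells(theta, prop)
        logr = ((Lp - L).sum(axis=1)
                + 0.5 * (beta ** 2 - prop ** 2) / sb2[:, None])
        acc = np.log(rng.random((C, j))) < logr
        beta = np.where(acc, prop, beta)
        L = np.where(acc[:, None, :], Lp, L)
        if t < burn:
            a.update(np.exp(np.minimum(logr, 0.0)), t)
        else:
            a.track(acc)

        # -- joint location shift ------------------------------------------
        # The likelihood only sees theta - beta, so the common location is
        # identified by the priors alone and mixes slowly under single-site
        # updates; this likelihood-invariant shift (theta+c, beta+c) fixes it.
        a = ad["shift"]
        cshift = a.scale * rng.standard_normal(C)
        logr = (-0.5 * (2.0 * cshift * theta.sum(axis=1)
                        + n * cshift ** 2)
                - 0.5 * (2.0 * cshift * beta.sum(axis=1)
                         + j * cshift ** 2) / sb2)
        acc = np.log(rng.random(C)) < logr
        theta = theta + np.where(acc, cshift, 0.0)[:, None]
        beta = beta + np.where(acc, cshift, 0.0)[:, None]
        if t < burn:
            a.update(np.exp(np.minimum(logr, 0.0)), t)
        else:
            a.track(acc)
        sum_b2 = (beta ** 2).sum(axis=1)

        # -- shapes (free model) --------------------------------------------
        # the shapes are the slowest-mixing block (they trade off against
        # both beta and the tail thetas), so they get several refresh
        # sweeps between each theta/beta update
        if free:
            sl2 = np.exp(2.0 * ls_lam)
            for nm, which in (("lam1", 0), ("lam2", 1)) * _SHAPE_SWEEPS:
                a = ad[nm]
                cur = lam1 if which == 0 else lam2
                prop = cur + a.scale * rng.standard_normal((C, j))
                safe = np.maximum(prop, -1.0 + 1e-12)
                Lp = (cells(theta, beta, l1=safe, l2=lam2) if which == 0
                      else cells(theta, beta, l1=lam1, l2=safe))
                # truncation normalizer depends only on sigma_lambda: cancels
                logr = ((Lp - L).sum(axis=1)
                        + 0.5 * (cur ** 2 - prop ** 2) / sl2[:, None])
                logr = np.where(prop > -1.0, logr, -np.inf)
                acc = np.log(rng.random((C, j))) < logr
                if which == 0:
                    lam1 = np.where(acc, prop, lam1)
                else:
                    lam2 = np.where(acc, prop, lam2)
                L = np.where(acc[:, None, :], Lp, L)
                if t < burn:
                    a.update(np.exp(np.minimum(logr, 0.0)), t)
                else:
                    a.track(acc)

            # sigma_lambda: log-scale RW; normalizer 2J*log Phi(1/sigma)
            a = ad["sigma_lambda"]
            sum_l2 = (lam1 ** 2).sum(axis=1) + (lam2 ** 2).sum(axis=1)

            def _target_sl(u):
                sig = np.exp(u)
                return (-2.0 * j * u - 0.5 * sum_l2 * np.exp(-2.0 * u)
                        - 2.0 * j * log_ndtr(1.0 / sig)
                        + log_half_cauchy(sig) + u)

            prop = ls_lam + a.scale * rng.standard_normal(C)
            logr = _target_sl(prop) - _target_sl(ls_lam)
            acc = np.log(rng.random(C)) < logr
            ls_lam = np.where(acc, prop, ls_lam)
            if t < burn:
                a.update(np.exp(np.minimum(logr, 0.0)), t)
            else:
                a.track(acc)

        # -- 3PL / 4PL item blocks -----------------------------------------
        if is_pl:
            a = ad["log_alpha"]
            prop = log_alpha + a.scale * rng.standard_normal((C, j))
            Lp = cells(theta, beta, la=prop)
            logr = ((Lp - L).sum(axis=1)
                    + 0.5 * (log_alpha ** 2 - prop ** 2))
            acc = np.log(rng.random((C, j))) < logr
            log_alpha = np.where(acc, prop, log_alpha)
            L = np.where(acc[:, None, :], Lp, L)
            if t < burn:
                a.update(np.exp(np.minimum(logr, 0.0)), t)
            else:
                a.track(acc)

            a = ad["c"]
            prop = c + a.scale * rng.standard_normal((C, j))
            Lp = cells(theta, beta, cc=np.clip(prop, 1e-9, 0.5))
            logr = (Lp - L).sum(axis=1)  # uniform prior
            logr = np.where((prop > 0.0) & (prop < 0.5), logr, -np.inf)
            acc = np.log(rng.random((C, j))) < logr
            c = np.where(acc, prop, c)
            L = np.where(acc[:, None, :], Lp, L)
            if t < burn:
                a.update(np.exp(np.minimum(logr, 0.0)), t)
            else:
                a.track(acc)

            if fourpl:
                a = ad["d"]
                prop = d + a.scale * rng.standard_normal((C, j))
                Lp = cells(theta, beta, dd=np.clip(prop, 0.5, 1.0 - 1e-9))
                logr = (Lp - L).sum(axis=1)
                logr = np.where((prop > 0.5) & (prop < 1.0), logr, -np.inf)
                acc = np.log(rng.random((C, j))) < logr
                d = np.where(acc, prop, d)
                L = np.where(acc[:, None, :], Lp, L)
                if t < burn:
                    a.update(np.exp(np.minimum(logr, 0.0)), t)
                else:
                    a.track(acc)

        # -- sigma_beta ------------------------------------------------------
        if config.fixed_sigma_beta is None:
            a = ad["sigma_beta"]

            def _target_sb(u):
                return (-j * u - 0.5 * sum_b2 * np.exp(-2.0 * u)
                        + log_half_cauchy(np.exp(u)) + u)

            prop = ls_beta + a.scale * rng.standard_normal(C)
            logr = _target_sb(prop) - _target_sb(ls_beta)
            acc = np.log(rng.random(C)) < logr
            ls_beta = np.where(acc, prop, ls_beta)
            if t < burn:
                a.update(np.exp(np.minimum(logr, 0.0)), t)
            else:
                a.track(acc)

        # -- record ----------------------------------------------------------
        if t >= burn:
            s = t - burn
            store["theta"][:, s] = theta
            store["beta"][:, s] = beta
            if free:
                store["lambda1"][:, s] = lam1
                store["lambda2"][:, s] = lam2
                store["sigma_lambda"][:, s] = np.exp(ls_lam)
            if config.fixed_sigma_beta is None:
                store["sigma_beta"][:, s] = np.exp(ls_beta)
            if is_pl:
                store["alpha"][:, s] = np.exp(log_alpha)
                store["c"][:, s] = c
                if fourpl:
                    store["d"][:, s] = d
            if pointwise is not None:
                pointwise[:, s] = L.reshape(C, -1)[:, obs_flat]

    # ---- posterior mean point (unconstrained scale) ----------------------
    mean_point: Dict[str, np.ndarray] = {
        "theta": store["theta"].mean(axis=(0, 1)),
        "beta": store["beta"].mean(axis=(0, 1)),
    }
    if free:
        mean_point["lambda1"] = np.expm1(
            np.log1p(store["lambda1"]).mean(axis=(0, 1)))
        mean_point["lambda2"] = np.expm1(
            np.log1p(store["lambda2"]).mean(axis=(0, 1)))
        mean_point["sigma_lambda"] = float(
            np.exp(np.log(store["sigma_lambda"]).mean()))
    if config.fixed_sigma_beta is None:
        mean_point["sigma_beta"] = float(
            np.exp(np.log(store["sigma_beta"]).mean()))
    if is_pl:
        mean_point["alpha"] = np.exp(
            np.log(store["alpha"]).mean(axis=(0, 1)))
        mean_point["c"] = store["c"].mean(axis=(0, 1))
        if fourpl:
            mean_point["d"] = store["d"].mean(axis=(0, 1))

    th_m = mean_point["theta"][None, :]
    be_m = mean_point["beta"][None, :]
    if is_glogit:
        if free:
            l1m = mean_point["lambda1"][None, :]
            l2m = mean_point["lambda2"][None, :]
        else:
            l1m, l2m = lam1[:1], lam2[:1]
        cells_m = _cells_glogit(x, obs_f, th_m, be_m, l1m, l2m)
    elif family == "pno_exact":
        cells_m = _cells_pno(x, obs_f, th_m, be_m)
    elif family == "cllm_exact":
        cells_m = _cells_cllm(x, obs_f, th_m, be_m)
    else:
        dd_m = mean_point["d"][None, :] if fourpl else np.ones((1, j))
        cells_m = _cells_pl(x, obs_f, th_m, be_m,
                            mean_point["alpha"][None, :],
                            mean_point["c"][None, :], dd_m)
    deviance_at_mean = float(-2.0 * cells_m.sum())

    # ---- diagnostics ------------------------------------------------------
    rhat_entries = {}
    for name, arr in store.items():
        if C >= 2 and retained >= 4:
            r = compute_rhat(arr)
        else:
            r = np.full(arr.shape[2:] or (), np.nan)
        if arr.ndim == 2:
            rhat_entries[name] = float(r)
        else:
            for k in range(arr.shape[2]):
                rhat_entries[f"{name}[{k + 1}]"] = float(np.asarray(r)[k])
    rhat = pd.Series(rhat_entries, dtype=float)

    acceptance = {nm: (a.accepted / a.proposed if a.proposed else np.nan)
                  for nm, a in ad.items()}
    low = {nm: r for nm, r in acceptance.items()
           if np.isfinite(r) and not 0.05 < r < 0.95}
    if low:
        warnings.warn(f"extreme post-burn-in acceptance rates: {low}",
                      RuntimeWarning, stacklevel=2)

    pw = pointwise.reshape(-1, m_obs) if pointwise is not None else None
    return FitResult(
        draws=store, rhat=rhat, pointwise_loglik=pw, config=config,
        model=model, n_persons=n, n_items=j, obs_mask=obs,
        mean_point=mean_point, deviance_at_mean=deviance_at_mean,
        acceptance=acceptance,
    )


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------

def compute_rhat(draws: np.ndarray) -> np.ndarray:
    """Classic split potential scale reduction factor (Brooks-Gelman).

    ``draws`` has shape (chains, iterations) or (chains, iterations, K);
    each chain is split in half, and R-hat is the square root of the
    weighted between/within variance ratio.  Values near 1 indicate
    convergence.
    """
    a = np.asarray(draws, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
        squeeze = True
    else:
        squeeze = False
    n_chains, n_iter = a.shape[:2]
    if n_chains < 2:
        raise ValueError("split R-hat requires at least 2 chains")
    half = n_iter // 2
    if half < 2:
        raise ValueError("split R-hat requires at least 4 iterations")
    split = np.concatenate([a[:, :half], a[:, n_iter - half:]], axis=0)
    w = split.var(axis=1, ddof=1).mean(axis=0)            # within
    means = split.mean(axis=1)
    b_over_n = means.var(axis=0, ddof=1)                  # B / n
    var_plus = (half - 1) / half * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    r = np.where((w == 0) & (b_over_n == 0), 1.0, r)
    return r[..., 0] if squeeze and r.ndim else r


def hpdi(samples: np.ndarray, mass: float = 0.95):
    """Shortest interval containing ``mass`` of the pooled draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    m = s.size
    k = max(1, int(np.ceil(mass * m)))
    if k >= m:
        return float(s[0]), float(s[-1])
    widths = s[k:] - s[: m - k]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k])


def posterior_summary(fit: FitResult, mass: float = 0.95,
                      params: Optional[list] = None) -> pd.DataFrame:
    """Per-parameter posterior mean, SD, HPDI, and R-hat.

    Columns follow the standard reporting layout: Estimate, SD, HPDI lower
    and upper bounds, and R-hat.  ``params`` restricts to named blocks.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    rows = []
    for name, arr in fit.draws.items():
        if params is not None and name not in params:
            continue
        pooled = arr.reshape(-1, *arr.shape[2:])
        if pooled.ndim == 1:
            pooled = pooled[:, None]
            labels = [name]
        else:
            labels = [f"{name}[{k + 1}]" for k in range(pooled.shape[1])]
        for k, label in enumerate(labels):
            col = pooled[:, k]
            lo, hi = hpdi(col, mass)
            rows.append({
                "parameter": label,
                "Estimate": float(col.mean()),
                "SD": float(col.std(ddof=1)) if col.size > 1 else 0.0,
                "HPDI_lower": lo,
                "HPDI_upper": hi,
                "R-hat": float(fit.rhat.get(label, np.nan)),
            })
    return pd.DataFrame(rows).set_index("parameter")
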
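"""Bayesian model-assessment criteria from the pointwise log-likelihood.

All four criteria operate on a matrix of per-draw, per-observation Bernoulli
log-likelihood values (rows = retained posterior draws S, columns = observed
response cells M):

* DIC   = Dbar + p_DIC with the plug-in effective-parameter count
          p_DIC = Dbar - D(posterior mean); deviance scale, smaller better.
* LPML  = sum of log conditional predictive ordinates (CPO), each CPO the
          harmonic mean of the cell's likelihood over draws; a log score,
          larger better (reported as-is, negative for real data).
* WAIC  = -2 * (lppd - p_WAIC), p_WAIC the summed posterior variance of the
          pointwise log-likelihood; deviance scale.
* LOO   = Pareto-smoothed importance-sampling leave-one-out cross-validation
          on the deviance scale (-2 * elpd_loo), with per-cell Pareto-k
          diagnostics.  The generalized-Pareto tail smoothing is delegated
          to arviz's ``psislw``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CriteriaReport",
    "dic",
    "dic_from_parts",
    "lpml",
    "waic",
    "loo_psis",
    "compute_criteria",
]

_MIN_DRAWS_FOR_PSIS = 100


@dataclass
class CriteriaReport:
    """One row of a model-comparison table (deviance scale except LPML)."""

    dic: float
    p_dic: float
    lpml: float
    waic: float
    p_waic: float
    loo: float
    pareto_k_max: float

    def as_dict(self):
        return {
            "DIC": self.dic, "p_DIC": self.p_dic, "LPML": self.lpml,
            "WAIC": self.waic, "p_WAIC": self.p_waic, "LOO": self.loo,
            "pareto_k_max": self.pareto_k_max,
        }


def _clean(pw: np.ndarray) -> np.ndarray:
    pw = np.asarray(pw, dtype=float)
    if pw.ndim != 2:
        raise ValueError("pointwise log-likelihood must be 2-D (draws x cells)")
    bad = ~np.isfinite(pw).all(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} draws with non-finite log-likelihood",
            RuntimeWarning, stacklevel=3,
        )
        pw = pw[~bad]
    if pw.shape[0] == 0:
        raise ValueError("no finite draws in pointwise log-likelihood")
    return pw


def dic_from_parts(pw: np.ndarray, deviance_at_mean: float):
    """(DIC, p_DIC) from a pointwise matrix and the plug-in deviance."""
    pw = _clean(pw)
    dbar = float(np.mean(-2.0 * pw.sum(axis=1)))
    p_dic = dbar - float(deviance_at_mean)
    return dbar + p_dic, p_dic


def dic(fit, model=None, data=None):
    """Deviance information criterion (plug-in form) as (DIC, p_DIC).

    Dbar is the posterior mean deviance; the plug-in deviance is evaluated
    at the posterior mean of the parameters (means taken on the sampling
    scale, i.e. the log scale for positive parameters and log(1+lambda) for
    the truncated shapes, then back-transformed).  The plug-in deviance is
    computed by ``sample_posterior`` at fit time; ``model``/``data`` are
    accepted for signature compatibility and consistency checking.
    """
    if fit.pointwise_loglik is None:
        raise ValueError("fit was run without pointwise log-likelihood storage")
    if data is not None and data.n_observed != fit.pointwise_loglik.shape[1]:
        raise ValueError("data does not match the fitted pointwise matrix")
    return dic_from_parts(fit.pointwise_loglik, fit.deviance_at_mean)


def lpml(pw: np.ndarray) -> float:
    """Log pseudo-marginal likelihood: sum of log CPO over observed cells.

    CPO_i is the harmonic mean of the likelihood over draws, computed in log
    space: log CPO_i = log S - logsumexp(-loglik_i).
    """
    pw = _clean(pw)
    s = pw.shape[0]
    if s < 2:
        raise ValueError("LPML needs at least 2 draws")
    with np.errstate(over="ignore"):
        log_cpo = np.log(s) - logsumexp(-pw, axis=0)
    if not np.isfinite(log_cpo).all():
        warnings.warn("some CPO values are zero (all draws at -inf likelihood)",
                      RuntimeWarning, stacklevel=2)
    return float(log_cpo.sum())


def waic(pw: np.ndarray):
    """Widely applicable information criterion as (WAIC, p_WAIC).

    lppd_i = log mean_s exp(loglik_si); p_WAIC_i = var_s(loglik_si) with the
    unbiased (S-1) denominator; WAIC = -2 * (lppd - p_WAIC).
    """
    pw = _clean(pw)
    s = pw.shape[0]
    if s < 2:
        raise ValueError("WAIC needs at least 2 draws")
    lppd = float((logsumexp(pw, axis=0) - np.log(s)).sum())
    p_w = float(pw.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_w), p_w


def loo_psis(pw: np.ndarray):
    """PSIS leave-one-out cross-validation as (LOO, pareto_k per cell).

    Importance ratios exp(-loglik) are tail-smoothed per cell by a
    generalized-Pareto fit on the largest 20% of ratios; the criterion is
    reported on the deviance scale, -2 * sum_i elpd_loo_i.  Falls back to
    raw importance sampling (k = nan) when there are too few draws for a
    stable tail fit.
    """
    pw = _clean(pw)
    s, m = pw.shape
    if s < _MIN_DRAWS_FOR_PSIS:
        warnings.warn(
            f"only {s} draws: PSIS tail fit skipped, raw importance sampling",
            RuntimeWarning, stacklevel=2,
        )
        elpd = np.log(s) - logsumexp(-pw, axis=0)  # harmonic-mean estimator
        return float(-2.0 * elpd.sum()), np.full(m, np.nan)
    from arviz.stats import psislw

    # psislw expects log-ratios with the sample dimension last
    log_weights, k = psislw(-pw.T)
    log_weights = np.asarray(log_weights)
    k = np.asarray(k, dtype=float)
    # psislw returns self-normalized log weights: elpd_i = lse(lw_i + ll_i)
    elpd = logsumexp(log_weights + pw.T, axis=1)
    return float(-2.0 * elpd.sum()), k


def compute_criteria(fit, model=None, data=None) -> CriteriaReport:
    """All four criteria for one fit, as a CriteriaReport row."""
    pw = fit.pointwise_loglik
    if pw is None:
        raise ValueError("fit was run without pointwise log-likelihood storage")
    d, p_d = dic(fit, model, data)
    w, p_w = waic(pw)
    lo, k = loo_psis(pw)
    with np.errstate(invalid="ignore"):
        k_max = float(np.nanmax(k)) if np.isfinite(k).any() else float("nan")
    return CriteriaReport(
        dic=d, p_dic=p_d, lpml=lpml(pw), waic=w, p_waic=p_w, loo=lo,
        pareto_k_max=k_max,
    )
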
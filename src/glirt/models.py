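"""Link functions, item characteristic curves, and log densities.

The central object is the two-shape-parameter generalized logit link of
Stukel.  A response probability is ``mu(h(eta))`` where ``eta = theta - beta``
is the latent-trait linear predictor, ``mu`` the standard logistic CDF, and
``h`` a strictly increasing transform indexed by shapes ``(lambda1, lambda2)``
that control how fast the item characteristic curve (ICC) approaches its
upper and lower asymptotes.  Setting both shapes to 0 recovers the Rasch
(logit) model; (0.165, 0.165) approximates the probit link and hence the
one-parameter normal-ogive (1PNO) model; (0.62, -0.037) approximates the
complementary log-log link (CLLM).  The exact probit and cloglog ICCs are
also provided, since the fixed-shape approximations agree with them only up
to an affine rescaling of ``eta``.

All functions broadcast over numpy arrays and are overflow-safe: response
probabilities are never materialized when a log-likelihood is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit, log_ndtr
from scipy.stats import norm

__all__ = [
    "ShapeParams",
    "ItemParams",
    "ModelSpec",
    "Hyperparams",
    "GLOGIT_FAMILIES",
    "FIXED_SHAPE_FAMILIES",
    "PL_FAMILIES",
    "FAMILIES",
    "fixed_shape_constants",
    "h_lambda",
    "icc",
    "loglik_point",
    "log_prior",
    "log_posterior_unnorm",
]

# |lambda| below this is treated as exactly 0 (the linear limit of the
# transform); avoids 0/0 while staying far inside float64 accuracy.
LAMBDA_LINEAR_EPS = 1e-8
# cap on lambda*eta inside exp() so h stays finite (expit saturates anyway)
_EXP_CAP = 700.0

GLOGIT_FAMILIES = ("glogit_free", "rasch", "pno_glogit", "cllm_glogit")
FIXED_SHAPE_FAMILIES = ("rasch", "pno_glogit", "cllm_glogit")
EXACT_LINK_FAMILIES = ("pno_exact", "cllm_exact")
PL_FAMILIES = ("threepl", "fourpl")
FAMILIES = GLOGIT_FAMILIES + EXACT_LINK_FAMILIES + PL_FAMILIES


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Shape pair (lambda1, lambda2) of the generalized logit link.

    ``lambda1`` governs the approach to the upper asymptote (eta > 0 tail),
    ``lambda2`` the lower asymptote.  Both must exceed -1 for the posterior
    to be proper.
    """

    lambda1: float
    lambda2: float

    def __post_init__(self):
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("shape parameters must be finite")
        # the transform itself is well defined at the boundary value -1
        # (useful for plotting limit curves); the Bayesian model keeps the
        # support strictly above -1 for posterior propriety.
        if self.lambda1 < -1 or self.lambda2 < -1:
            raise ValueError(
                f"shape parameters must be >= -1, got "
                f"({self.lambda1}, {self.lambda2})"
            )


@dataclass(frozen=True)
class ItemParams:
    """Per-item parameters.

    ``beta`` is the difficulty (latent-trait units).  ``alpha`` (discrimination),
    ``c`` (lower asymptote / guessing) and ``d`` (upper asymptote; 1 - d is
    the slipping probability) apply to the 3PL/4PL families only; ``shape``
    applies to the generalized-logit families only.
    """

    beta: float
    alpha: float = 1.0
    c: float = 0.0
    d: float = 1.0
    shape: Optional[ShapeParams] = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0.0 <= self.c < self.d <= 1.0):
            raise ValueError(
                f"need 0 <= c < d <= 1, got c={self.c}, d={self.d}"
            )


class ConfigurationError(ValueError):
    """Family / parameter mismatch."""


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus, for the fixed-shape reductions, its shape pair.

    Families:
      glogit_free   generalized logit, shapes free per item
      rasch         glogit with (0, 0) == logit link
      pno_glogit    glogit with (0.165, 0.165), probit-like
      cllm_glogit   glogit with (0.62, -0.037), cloglog-like
      pno_exact     exact normal-ogive (probit) ICC
      cllm_exact    exact complementary log-log ICC
      threepl       3PL: c + (1-c) * logistic(alpha * eta)
      fourpl        4PL: c + (d-c) * logistic(alpha * eta)
    """

    family: str
    fixed_shape: Optional[ShapeParams] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family in FIXED_SHAPE_FAMILIES and self.fixed_shape is None:
            object.__setattr__(
                self, "fixed_shape", fixed_shape_constants(self.family)
            )
        elif self.family not in FIXED_SHAPE_FAMILIES and self.fixed_shape is not None:
            raise ConfigurationError(
                f"fixed_shape only applies to {FIXED_SHAPE_FAMILIES}"
            )

    @property
    def is_glogit(self) -> bool:
        return self.family in GLOGIT_FAMILIES

    @property
    def is_pl(self) -> bool:
        return self.family in PL_FAMILIES


@dataclass(frozen=True)
class Hyperparams:
    """Prior scales: beta_j ~ N(0, sigma_beta^2), lambda ~ N(0, sigma_lambda^2)I(-1,inf)."""

    sigma_beta: float = 1.0
    sigma_lambda: float = 1.0

    def __post_init__(self):
        if self.sigma_beta <= 0 or self.sigma_lambda <= 0:
            raise ValueError("hyperparameter scales must be strictly positive")


_FIXED_SHAPES = {
    "rasch": ShapeParams(0.0, 0.0),
    "pno_glogit": ShapeParams(0.165, 0.165),
    "cllm_glogit": ShapeParams(0.62, -0.037),
    # additional named reductions from the Stukel family
    "loglog_glogit": ShapeParams(-0.037, 0.62),
    "laplace_glogit": ShapeParams(-0.077, -0.077),
}


def fixed_shape_constants(family: str) -> ShapeParams:
    """Shape pair of a named fixed-shape reduction of the generalized logit."""
    try:
        return _FIXED_SHAPES[family]
    except KeyError:
        raise ConfigurationError(
            f"no fixed shape constants for family {family!r}"
        ) from None


# --------------------------------------------------------------------------
# the generalized logit transform
# --------------------------------------------------------------------------

def _h_upper(a, lam):
    """Positive-tail branch evaluated at a >= 0 for shape lam.

    lam < 0: -log(1 - lam*a)/lam;  lam = 0: a;  lam > 0: (exp(lam*a)-1)/lam.
    """
    a = np.asarray(a, dtype=float)
    lam = np.asarray(lam, dtype=float)
    linear = np.abs(lam) < LAMBDA_LINEAR_EPS
    safe = np.where(linear, 1.0, lam)
    arg = 1.0 - safe * a
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        neg_val = -np.log(np.maximum(arg, 1e-300)) / safe
        pos_val = np.expm1(np.minimum(safe * a, _EXP_CAP)) / safe
    return np.where(linear, a, np.where(lam < 0, neg_val, pos_val))


def h_lambda(eta, shape_or_lambda1, lambda2=None):
    """Stukel transform h_lambda(eta).

    For eta > 0 the lambda1 branch applies; for eta <= 0 the lambda2 branch
    applies to |eta| with a sign flip.  Strictly increasing, h(0) = 0, and
    continuous in each shape at 0 (the lambda -> 0 limit is the identity).

    Accepts either ``h_lambda(eta, ShapeParams)`` or
    ``h_lambda(eta, lambda1, lambda2)`` with broadcasting arrays.
    """
    if lambda2 is None:
        shape = shape_or_lambda1
        lam1, lam2 = shape.lambda1, shape.lambda2
    else:
        lam1, lam2 = shape_or_lambda1, lambda2
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if np.any(np.asarray(lam1) < -1) or np.any(np.asarray(lam2) < -1):
        raise ValueError("shape parameters must be >= -1")
    pos = eta > 0
    up = _h_upper(np.where(pos, eta, 0.0), lam1)
    lo = -_h_upper(np.where(pos, 0.0, -eta), lam2)
    out = np.where(pos, up, lo)
    return out if out.ndim else float(out)


def _glogit_prob(eta, lam1, lam2):
    return expit(h_lambda(eta, lam1, lam2))


def _pl_prob(eta, alpha, c, d):
    return c + (d - c) * expit(alpha * eta)


# --------------------------------------------------------------------------
# item characteristic curves
# --------------------------------------------------------------------------

def icc(model: ModelSpec, theta, item: ItemParams):
    """P(x = 1 | theta) for one item under ``model``.

    Strictly inside (0, 1) for finite theta (for 3PL/4PL, inside (c, d)),
    monotone nondecreasing in theta, and shift-invariant in (theta, beta)
    for the generalized-logit families.
    """
    theta = np.asarray(theta, dtype=float)
    eta = theta - item.beta
    if model.is_glogit:
        if model.family == "glogit_free":
            if item.shape is None:
                raise ConfigurationError(
                    "glogit_free items need per-item shape parameters"
                )
            shape = item.shape
        else:
            shape = model.fixed_shape
        out = _glogit_prob(eta, shape.lambda1, shape.lambda2)
    elif model.family == "pno_exact":
        out = norm.cdf(eta)
    elif model.family == "cllm_exact":
        out = -np.expm1(-np.exp(np.minimum(eta, _EXP_CAP)))
    elif model.family == "threepl":
        if item.d != 1.0:
            raise ConfigurationError("threepl requires d = 1")
        out = _pl_prob(eta, item.alpha, item.c, 1.0)
    elif model.family == "fourpl":
        out = _pl_prob(eta, item.alpha, item.c, item.d)
    else:  # pragma: no cover - exhaustive above
        raise ConfigurationError(model.family)
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# log densities
# --------------------------------------------------------------------------

def loglik_point(x, p):
    """Bernoulli log-likelihood x*log(p) + (1-x)*log(1-p).

    Returns -inf (not an exception) when p is 0 or 1 and contradicts x.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x == 1, np.log(p), np.log1p(-p))
    return out if out.ndim else float(out)


def bernoulli_loglik_from_h(x, h):
    """log-lik from the transformed predictor h, never forming p = expit(h).

    Stable for |h| up to the exp cap: log_expit(-700) is just -700.
    """
    return np.where(x == 1, log_expit(h), log_expit(-h))


_HALF_CAUCHY_SCALE = 5.0


def log_half_cauchy(sigma, scale=_HALF_CAUCHY_SCALE):
    """log density of the half-Cauchy(0, scale) prior; -inf for sigma <= 0."""
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            sigma >= 0,
            math.log(2.0 / (math.pi * scale)) - np.log1p((sigma / scale) ** 2),
            -np.inf,
        )
    return out if out.ndim else float(out)


def log_truncnorm_lower(x, sd, lower=-1.0):
    """log density of N(0, sd^2) truncated to (lower, inf), with normalizer."""
    x = np.asarray(x, dtype=float)
    # P(X > lower) = Phi(-lower/sd); log via log_ndtr for stability
    log_z = log_ndtr(-lower / sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > lower,
            norm.logpdf(x, scale=sd) - log_z,
            -np.inf,
        )
    return out if out.ndim else float(out)


def log_prior(
    theta,
    beta,
    hyper: Hyperparams,
    lambda1=None,
    lambda2=None,
    sigma_included: bool = True,
):
    """Joint log prior of the generalized-logit IRT model.

    theta_i ~ N(0,1); beta_j ~ N(0, sigma_beta^2);
    lambda_{1j}, lambda_{2j} ~ N(0, sigma_lambda^2) truncated to (-1, inf);
    sigma_beta, sigma_lambda ~ half-Cauchy(0, 5) (included when
    ``sigma_included``).  Returns -inf outside the support.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    total = float(np.sum(norm.logpdf(theta)))
    total += float(np.sum(norm.logpdf(beta, scale=hyper.sigma_beta)))
    if lambda1 is not None:
        lp = log_truncnorm_lower(np.asarray(lambda1), hyper.sigma_lambda)
        lp2 = log_truncnorm_lower(np.asarray(lambda2), hyper.sigma_lambda)
        total += float(np.sum(lp)) + float(np.sum(lp2))
    if sigma_included:
        total += float(log_half_cauchy(hyper.sigma_beta))
        if lambda1 is not None:
            total += float(log_half_cauchy(hyper.sigma_lambda))
    return total


def log_posterior_unnorm(
    theta,
    beta,
    hyper: Hyperparams,
    responses,
    mask=None,
    lambda1=None,
    lambda2=None,
    sigma_included: bool = True,
):
    """Unnormalized joint log posterior: observed-cell log-lik + log prior.

    ``responses`` is an N x J 0/1 array; ``mask`` marks missing cells (True =
    missing, skipped).  -inf from the prior propagates.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = np.atleast_2d(np.asarray(responses))
    if x.size and (x.shape[0] != theta.shape[0] or x.shape[1] != beta.shape[0]):
        raise ValueError(
            f"responses shape {x.shape} does not match "
            f"N={theta.shape[0]} persons, J={beta.shape[0]} items"
        )
    lp = log_prior(
        theta, beta, hyper,
        lambda1=lambda1, lambda2=lambda2, sigma_included=sigma_included,
    )
    if not np.isfinite(lp):
        return -np.inf
    if x.size == 0:
        return lp
    eta = theta[:, None] - beta[None, :]
    if lambda1 is None:
        l1 = np.zeros(beta.shape[0])
        l2 = np.zeros(beta.shape[0])
    else:
        l1 = np.asarray(lambda1, dtype=float)
        l2 = np.asarray(lambda2, dtype=float)
    h = h_lambda(eta, l1[None, :], l2[None, :])
    cells = bernoulli_loglik_from_h(x, h)
    if mask is not None:
        cells = np.where(np.atleast_2d(mask), 0.0, cells)
    return lp + float(np.sum(cells))
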
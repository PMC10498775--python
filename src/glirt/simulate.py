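"""True-parameter generation and response simulation for every model family.

Study conditions: abilities theta ~ N(0,1) and difficulties beta ~ N(0,1);
for the free generalized-logit model the per-item shapes are
N(0, 0.5^2) truncated below at -1 (sampled by rejection; the acceptance
probability is about 0.977 so this is cheap and exact); for the 3PL/4PL
families alpha ~ U(0.5, 2), c ~ Beta(5, 17), d ~ Beta(17, 5) (d = 1 for the
3PL).  Responses are independent Bernoulli draws from the ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .io import ResponseMatrix
from .models import (
    FIXED_SHAPE_FAMILIES,
    ItemParams,
    ModelSpec,
    ShapeParams,
    fixed_shape_constants,
    h_lambda,
)
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimulationDesign",
    "TrueParameterSet",
    "draw_true_parameters",
    "simulate_responses",
    "make_fixture",
    "FIXTURE_NAMES",
]

TRUE_LAMBDA_SD = 0.5   # shape truth scale, truncated below at -1
LAMBDA_LOWER = -1.0


@dataclass(frozen=True)
class SimulationDesign:
    """Replicated-study design: N persons x J items x R replications."""

    n_persons: int
    n_items: int
    n_reps: int = 1
    true_family: ModelSpec = field(default_factory=lambda: ModelSpec("rasch"))
    base_seed: int = 0

    def __post_init__(self):
        if min(self.n_persons, self.n_items, self.n_reps) < 1:
            raise ValueError("all design counts must be >= 1")

    def rep_seed(self, rep: int) -> int:
        # reproducible yet independent replications
        return self.base_seed + rep


@dataclass
class TrueParameterSet:
    theta: np.ndarray
    items: List[ItemParams]

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta truths must be finite")

    @property
    def beta(self) -> np.ndarray:
        return np.array([it.beta for it in self.items])

    @property
    def lambda1(self) -> np.ndarray:
        return np.array([it.shape.lambda1 for it in self.items])

    @property
    def lambda2(self) -> np.ndarray:
        return np.array([it.shape.lambda2 for it in self.items])


def _draw_truncated_normal(rng, size, sd=TRUE_LAMBDA_SD, lower=LAMBDA_LOWER):
    """Rejection sampler for N(0, sd^2) restricted to (lower, inf)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(0.0, sd, size=size - filled)
        keep = draw[draw > lower]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def draw_true_parameters(design: SimulationDesign,
                         rng: np.random.Generator) -> TrueParameterSet:
    """Draw generating parameters for the design's true family."""
    model = design.true_family
    n, j = design.n_persons, design.n_items
    theta = rng.normal(0.0, 1.0, size=n)
    beta = rng.normal(0.0, 1.0, size=j)
    items: List[ItemParams] = []
    if model.family == "glogit_free":
        lam1 = _draw_truncated_normal(rng, j)
        lam2 = _draw_truncated_normal(rng, j)
        items = [ItemParams(beta=b, shape=ShapeParams(a, c))
                 for b, a, c in zip(beta, lam1, lam2)]
    elif model.family in FIXED_SHAPE_FAMILIES:
        shape = fixed_shape_constants(model.family)
        items = [ItemParams(beta=b, shape=shape) for b in beta]
    elif model.family in ("pno_exact", "cllm_exact"):
        items = [ItemParams(beta=b) for b in beta]
    elif model.family in ("threepl", "fourpl"):
        alpha = rng.uniform(0.5, 2.0, size=j)
        c = rng.beta(5, 17, size=j)
        if model.family == "fourpl":
            d = rng.beta(17, 5, size=j)
            d = np.maximum(d, c + 1e-9)  # Beta(17,5) < Beta(5,17) has ~0 mass
        else:
            d = np.ones(j)
        items = [ItemParams(beta=b, alpha=a, c=cc, d=dd)
                 for b, a, cc, dd in zip(beta, alpha, c, d)]
    else:  # pragma: no cover
        raise ValueError(model.family)
    return TrueParameterSet(theta=theta, items=items)


def _prob_matrix(truth: TrueParameterSet, model: ModelSpec) -> np.ndarray:
    theta = truth.theta
    beta = truth.beta
    eta = theta[:, None] - beta[None, :]
    if model.is_glogit:
        if model.family == "glogit_free":
            l1, l2 = truth.lambda1, truth.lambda2
        else:
            s = model.fixed_shape
            l1 = np.full(beta.size, s.lambda1)
            l2 = np.full(beta.size, s.lambda2)
        return expit(h_lambda(eta, l1[None, :], l2[None, :]))
    if model.family == "pno_exact":
        return norm.cdf(eta)
    if model.family == "cllm_exact":
        return -np.expm1(-np.exp(np.minimum(eta, 700.0)))
    alpha = np.array([it.alpha for it in truth.items])
    c = np.array([it.c for it in truth.items])
    d = np.array([it.d for it in truth.items])
    return c[None, :] + (d - c)[None, :] * expit(alpha[None, :] * eta)


def simulate_responses(truth: TrueParameterSet, model: ModelSpec,
                       rng: np.random.Generator) -> ResponseMatrix:
    """Independent Bernoulli responses x_ij ~ Bern(icc(theta_i, item_j))."""
    p = _prob_matrix(truth, model)
    x = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix.from_values(x)


# --------------------------------------------------------------------------
# packaged toy fixtures (generated deterministically, never stored on disk)
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("rasch_toy", "glogit_toy", "pisa_like")


def make_fixture(name: str):
    """Deterministic small datasets for tests and documentation.

    rasch_toy   50 persons x 5 items, Rasch truths.
    glogit_toy  80 persons x 6 items, free-shape truths.
    pisa_like   685 persons x 11 items simulated from a free-shape model,
                of which 76 rows carry missing codes (synthetic stand-in for
                a released large-scale assessment extract; the real data is
                not shipped).  Returned with codes already flagged in the
                mask; writing with ``write_response_matrix`` reproduces the
                coded file byte-identically.
    """
    if name == "rasch_toy":
        design = SimulationDesign(50, 5, true_family=ModelSpec("rasch"),
                                  base_seed=20230830)
        rng = np.random.default_rng(design.base_seed)
        truth = draw_true_parameters(design, rng)
        return simulate_responses(truth, design.true_family, rng), truth
    if name == "glogit_toy":
        design = SimulationDesign(80, 6, true_family=ModelSpec("glogit_free"),
                                  base_seed=20230831)
        rng = np.random.default_rng(design.base_seed)
        truth = draw_true_parameters(design, rng)
        return simulate_responses(truth, design.true_family, rng), truth
    if name == "pisa_like":
        design = SimulationDesign(685, 11, true_family=ModelSpec("glogit_free"),
                                  base_seed=20152015)
        rng = np.random.default_rng(design.base_seed)
        truth = draw_true_parameters(design, rng)
        rm = simulate_responses(truth, design.true_family, rng)
        # exactly 76 persons receive missing codes in a few of their cells
        miss_rows = rng.choice(685, size=76, replace=False)
        mask = np.zeros_like(rm.values, dtype=bool)
        vals = rm.values.astype(int)
        for row in miss_rows:
            k = 1 + int(rng.integers(0, 3))
            cols = rng.choice(11, size=k, replace=False)
            mask[row, cols] = True
        vals[mask] = np.where(rng.random(mask.sum()) < 0.5, 6, 9)
        out = ResponseMatrix(np.where(mask, 0, vals), mask,
                             rm.person_ids, rm.item_ids)
        out._coded_values = vals  # full coded grid, for byte-exact writing
        return out, truth
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
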
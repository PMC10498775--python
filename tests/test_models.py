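import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from glirt.models import (
    ConfigurationError,
    Hyperparams,
    ItemParams,
    ModelSpec,
    ShapeParams,
    fixed_shape_constants,
    h_lambda,
    icc,
    log_half_cauchy,
    log_posterior_unnorm,
    log_prior,
    loglik_point,
)

SHAPE_GRID = [
    (0.0, 0.0), (1.0, 1.0), (-0.9, -0.9), (1.0, -0.5), (-0.5, 1.0),
    (0.165, 0.165), (0.62, -0.037), (2.5, 0.3),
]


class TestLink:
    def test_zero_at_origin(self):
        for l1, l2 in SHAPE_GRID:
            assert h_lambda(0.0, ShapeParams(l1, l2)) == 0.0

    @pytest.mark.parametrize("eta,shape,expected", [
        (2.0, (1.0, 0.0), math.e ** 2 - 1),          # positive-shape branch
        (-4.0, (0.0, -1.0), -math.log(5.0)),          # negative-shape branch
        (3.0, (-0.25, 0.0), -math.log(1 + 0.25 * 3) / -0.25),
        (-2.0, (0.0, 0.5), -(math.exp(0.5 * 2) - 1) / 0.5),
    ])
    def test_branch_values(self, eta, shape, expected):
        assert h_lambda(eta, ShapeParams(*shape)) == pytest.approx(expected,
                                                                   rel=1e-12)

    def test_continuity_at_zero_shape(self):
        # tiny shape values must agree with the identity (linear limit)
        assert h_lambda(1.3, ShapeParams(1e-10, 0.0)) == pytest.approx(
            1.3, abs=1e-8)
        # the exact transform differs from the identity by ~lam*eta^2/2
        # (1.8e-5 at lam=1e-6, eta=6); check continuity at that Taylor rate
        eta = np.linspace(-6, 6, 121)
        for lam in (1e-6, -1e-6):
            diff = np.abs(h_lambda(eta, lam, lam) - eta)
            assert diff.max() < abs(lam) * 6 ** 2 / 2 * 1.01 + 1e-12

    @pytest.mark.parametrize("shape", SHAPE_GRID)
    def test_strictly_increasing(self, shape):
        eta = np.linspace(-8, 8, 400)
        h = h_lambda(eta, ShapeParams(*shape))
        assert np.all(np.diff(h) > 0)

    @given(st.floats(-0.95, 3.0), st.floats(-0.95, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_increasing_property(self, l1, l2):
        eta = np.linspace(-5, 5, 101)
        h = h_lambda(eta, l1, l2)
        assert np.all(np.diff(h) > 0)
        assert h_lambda(0.0, l1, l2) == 0.0

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            h_lambda(np.array([0.5, np.inf]), ShapeParams(0.0, 0.0))
        with pytest.raises(ValueError):
            h_lambda(0.5, -1.5, 0.0)
        with pytest.raises(ValueError):
            ShapeParams(-1.2, 0.0)


class TestIcc:
    def test_half_probability_at_difficulty(self):
        m = ModelSpec("glogit_free")
        for l1, l2 in SHAPE_GRID:
            item = ItemParams(beta=0.37, shape=ShapeParams(l1, l2))
            assert icc(m, 0.37, item) == pytest.approx(0.5, abs=1e-12)

    def test_slow_upper_tail(self):
        # shape (-1, 0): the curve only reaches ~5/6 at four logits above
        item = ItemParams(beta=0.0, shape=ShapeParams(-1.0, 0.0))
        assert icc(ModelSpec("glogit_free"), 4.0, item) == pytest.approx(
            5.0 / 6.0, abs=1e-9)

    def test_rasch_equivalence(self):
        theta = np.linspace(-4, 4, 81)
        item_g = ItemParams(beta=0.3, shape=ShapeParams(0.0, 0.0))
        via_glogit = icc(ModelSpec("glogit_free"), theta, item_g)
        via_rasch = icc(ModelSpec("rasch"), theta, ItemParams(beta=0.3))
        closed = expit(theta - 0.3)
        np.testing.assert_allclose(via_glogit, closed, rtol=0, atol=1e-15)
        np.testing.assert_allclose(via_rasch, closed, rtol=0, atol=1e-15)
        assert icc(ModelSpec("rasch"), 0.7, ItemParams(beta=0.0)) == \
            pytest.approx(1 / (1 + math.exp(-0.7)), rel=1e-12)

    def test_exact_cloglog_at_difficulty(self):
        assert icc(ModelSpec("cllm_exact"), 0.0, ItemParams(beta=0.0)) == \
            pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_symmetry_when_shapes_equal(self):
        m = ModelSpec("glogit_free")
        for lam in (0.0, 0.8, -0.6, 0.165):
            item = ItemParams(beta=0.5, shape=ShapeParams(lam, lam))
            for t in (0.3, 1.7, 4.0):
                assert icc(m, 0.5 + t, item) + icc(m, 0.5 - t, item) == \
                    pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance(self):
        m = ModelSpec("glogit_free")
        for c in (-1.3, 2.7):
            a = icc(m, 1.1 + c, ItemParams(beta=0.2 + c,
                                           shape=ShapeParams(0.9, -0.4)))
            b = icc(m, 1.1, ItemParams(beta=0.2, shape=ShapeParams(0.9, -0.4)))
            assert a == pytest.approx(b, rel=1e-12)

    def test_bounds_and_monotonicity(self):
        theta = np.linspace(-30, 30, 301)
        for fam, item in [
            ("glogit_free", ItemParams(beta=0.0, shape=ShapeParams(1.5, -0.8))),
            ("pno_exact", ItemParams(beta=0.0)),
            ("cllm_exact", ItemParams(beta=0.0)),
            ("threepl", ItemParams(beta=0.0, alpha=1.3, c=0.2)),
            ("fourpl", ItemParams(beta=0.0, alpha=1.3, c=0.2, d=0.8)),
        ]:
            p = icc(ModelSpec(fam), theta, item)
            assert np.all(np.diff(p) >= 0)
            assert np.all((p >= 0) & (p <= 1))
        p4 = icc(ModelSpec("fourpl"), theta,
                 ItemParams(beta=0.0, alpha=1.0, c=0.2, d=0.8))
        assert np.all((p4 > 0.2) & (p4 < 0.8))

    def test_family_param_mismatch(self):
        with pytest.raises(ConfigurationError):
            icc(ModelSpec("glogit_free"), 0.0, ItemParams(beta=0.0))
        with pytest.raises(ConfigurationError):
            icc(ModelSpec("threepl"), 0.0,
                ItemParams(beta=0.0, alpha=1.0, c=0.1, d=0.9))
        with pytest.raises(ValueError):
            ItemParams(beta=0.0, c=0.7, d=0.5)
        with pytest.raises(ConfigurationError):
            ModelSpec("nonesuch")


def test_fixed_shape_constants():
    assert fixed_shape_constants("rasch") == ShapeParams(0.0, 0.0)
    assert fixed_shape_constants("pno_glogit") == ShapeParams(0.165, 0.165)
    assert fixed_shape_constants("cllm_glogit") == ShapeParams(0.62, -0.037)
    with pytest.raises(ConfigurationError):
        fixed_shape_constants("logit7")


class TestDensities:
    def test_loglik_point(self):
        assert loglik_point(1, 0.5) == pytest.approx(math.log(0.5))
        assert loglik_point(0, 0.5) == pytest.approx(math.log(0.5))
        total = np.sum(loglik_point(np.array([0, 1, 1, 0]),
                                    np.full(4, 0.5)))
        assert total == pytest.approx(-4 * math.log(2))
        assert loglik_point(1, 0.0) == -np.inf
        assert loglik_point(0, 1.0) == -np.inf

    def test_half_cauchy(self):
        assert log_half_cauchy(0.0) == pytest.approx(
            math.log(2 / (5 * math.pi)))
        assert log_half_cauchy(-0.1) == -np.inf

    def test_log_prior_support(self):
        hyper = Hyperparams(sigma_beta=1.0, sigma_lambda=0.5)
        assert log_prior([0.0], [0.0], hyper, lambda1=[-1.5],
                         lambda2=[0.0]) == -np.inf
        # theta at its prior mode contributes the standard-normal constant
        base = log_prior([0.0], [], hyper)
        plus = log_prior([0.0, 0.0], [], hyper)
        assert plus - base == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_log_posterior_reduces_to_prior(self):
        hyper = Hyperparams()
        lp = log_prior([0.1, -0.2], [0.5], hyper)
        assert log_posterior_unnorm([0.1, -0.2], [0.5], hyper,
                                    np.zeros((2, 0))) == pytest.approx(lp)
        x = np.array([[1, 0], [0, 1]])
        all_missing = np.ones_like(x, dtype=bool)
        assert log_posterior_unnorm([0.0, 0.0], [0.0, 0.0], hyper, x,
                                    mask=all_missing) == pytest.approx(
            log_prior([0.0, 0.0], [0.0, 0.0], hyper))

    def test_log_posterior_theta_equals_beta(self):
        hyper = Hyperparams()
        x = np.array([[1, 0], [0, 1]])
        lp = log_posterior_unnorm([0.3, 0.3], [0.3, 0.3], hyper, x)
        prior = log_prior([0.3, 0.3], [0.3, 0.3], hyper)
        assert lp == pytest.approx(prior - 4 * math.log(2))

    def test_log_posterior_dimension_mismatch(self):
        with pytest.raises(ValueError):
            log_posterior_unnorm([0.0], [0.0, 0.0], Hyperparams(),
                                 np.zeros((2, 2)))
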
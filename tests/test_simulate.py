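import numpy as np
import pytest
from scipy.stats import truncnorm

from glirt import (
    ModelSpec,
    ShapeParams,
    SimulationDesign,
    draw_true_parameters,
    make_fixture,
    simulate_responses,
)
from glirt.models import ItemParams, icc
from glirt.simulate import TrueParameterSet, _draw_truncated_normal


class TestTruthDraws:
    def test_shape_truncation_support(self):
        rng = np.random.default_rng(0)
        draws = _draw_truncated_normal(rng, 100_000)
        assert draws.min() > -1.0

    def test_truncated_normal_moments(self):
        rng = np.random.default_rng(1)
        draws = _draw_truncated_normal(rng, 200_000)
        dist = truncnorm(a=-1.0 / 0.5, b=np.inf, loc=0.0, scale=0.5)
        mc_se = dist.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(dist.mean(), abs=4 * mc_se)
        assert draws.std() == pytest.approx(dist.std(), rel=0.01)

    def test_upper_asymptote_beta_mean(self):
        rng = np.random.default_rng(2)
        d = rng.beta(17, 5, size=100_000)
        mean, sd = 17 / 22, np.sqrt(17 * 5 / (22 ** 2 * 23))
        assert d.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(d.size))

    def test_pl_truth_ranges(self):
        design = SimulationDesign(10, 400, true_family=ModelSpec("fourpl"),
                                  base_seed=3)
        truth = draw_true_parameters(design, np.random.default_rng(3))
        alpha = np.array([it.alpha for it in truth.items])
        c = np.array([it.c for it in truth.items])
        d = np.array([it.d for it in truth.items])
        assert alpha.min() >= 0.5 and alpha.max() <= 2.0
        assert np.all((0 <= c) & (c < d) & (d <= 1))

    def test_fixed_family_shapes(self):
        design = SimulationDesign(5, 3, true_family=ModelSpec("cllm_glogit"),
                                  base_seed=4)
        truth = draw_true_parameters(design, np.random.default_rng(4))
        assert all(it.shape == ShapeParams(0.62, -0.037) for it in truth.items)

    def test_determinism(self):
        design = SimulationDesign(30, 4, true_family=ModelSpec("glogit_free"),
                                  base_seed=5)
        t1 = draw_true_parameters(design, np.random.default_rng(11))
        t2 = draw_true_parameters(design, np.random.default_rng(11))
        np.testing.assert_array_equal(t1.theta, t2.theta)
        assert t1.items == t2.items


class TestResponses:
    def test_forced_success(self):
        truth = TrueParameterSet(
            theta=np.full(20, 50.0),
            items=[ItemParams(beta=0.0, shape=ShapeParams(1.0, 0.0))
                   for _ in range(3)],
        )
        rm = simulate_responses(truth, ModelSpec("glogit_free"),
                                np.random.default_rng(0))
        assert rm.values.min() == 1

    def test_half_probability_grand_mean(self):
        n, j = 400, 10
        truth = TrueParameterSet(
            theta=np.zeros(n),
            items=[ItemParams(beta=0.0, shape=ShapeParams(0.3, -0.2))
                   for _ in range(j)],
        )
        rm = simulate_responses(truth, ModelSpec("glogit_free"),
                                np.random.default_rng(1))
        tol = 3 * np.sqrt(0.25 / (n * j))
        assert rm.values.mean() == pytest.approx(0.5, abs=tol)

    @pytest.mark.parametrize("family", [
        "glogit_free", "rasch", "pno_glogit", "cllm_glogit",
        "pno_exact", "cllm_exact", "threepl", "fourpl",
    ])
    def test_item_proportions_match_icc(self, family):
        design = SimulationDesign(3000, 5, true_family=ModelSpec(family),
                                  base_seed=6)
        rng = np.random.default_rng(6)
        truth = draw_true_parameters(design, rng)
        rm = simulate_responses(truth, design.true_family, rng)
        for jj, item in enumerate(truth.items):
            expected = np.mean(icc(design.true_family, truth.theta, item))
            se = np.sqrt(expected * (1 - expected) / design.n_persons)
            assert rm.values[:, jj].mean() == pytest.approx(
                expected, abs=4 * se + 1e-3)

    def test_determinism(self):
        design = SimulationDesign(50, 4, true_family=ModelSpec("rasch"),
                                  base_seed=7)
        truth = draw_true_parameters(design, np.random.default_rng(7))
        a = simulate_responses(truth, design.true_family,
                               np.random.default_rng(9))
        b = simulate_responses(truth, design.true_family,
                               np.random.default_rng(9))
        np.testing.assert_array_equal(a.values, b.values)


class TestFixtures:
    def test_rasch_toy(self):
        rm, truth = make_fixture("rasch_toy")
        assert rm.values.shape == (50, 5)
        assert set(np.unique(rm.values)) <= {0, 1}
        assert truth.theta.shape == (50,)

    def test_pisa_like_missing_rows(self):
        rm, _ = make_fixture("pisa_like")
        assert rm.values.shape == (685, 11)
        rows_with_missing = rm.mask.any(axis=1).sum()
        assert rows_with_missing == 76

    def test_fixtures_are_reproducible(self):
        a, _ = make_fixture("pisa_like")
        b, _ = make_fixture("pisa_like")
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a._coded_values, b._coded_values)

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            make_fixture("nope")
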
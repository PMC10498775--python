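import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from glirt import (
    FitConfig,
    ModelSpec,
    ResponseMatrix,
    compute_rhat,
    hpdi,
    posterior_summary,
    sample_posterior,
)


class TestSampler:
    def test_determinism(self, rasch_small):
        _, _, data = rasch_small
        cfg = FitConfig(n_chains=2, n_iterations=120, n_burnin=60, seed=3)
        f1 = sample_posterior(ModelSpec("rasch"), data, cfg)
        f2 = sample_posterior(ModelSpec("rasch"), data, cfg)
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_support_respected(self, glogit_small_fit):
        fit = glogit_small_fit
        assert fit.pooled("lambda1").min() > -1.0
        assert fit.pooled("lambda2").min() > -1.0
        assert fit.pooled("sigma_beta").min() > 0.0
        assert fit.pooled("sigma_lambda").min() > 0.0

    def test_pointwise_matches_observed_cells(self, rasch_small_fit,
                                              rasch_small):
        _, _, data = rasch_small
        pw = rasch_small_fit.pointwise_loglik
        assert pw.shape[1] == data.n_observed
        assert np.all(pw <= 0)

    def test_rejects_empty_rows(self):
        vals = np.array([[1, 0], [0, 1], [0, 0]])
        mask = np.array([[False, False], [False, False], [True, True]])
        data = ResponseMatrix(vals * ~mask, mask, list("abc"), ["i1", "i2"])
        with pytest.raises(ValueError, match="person"):
            sample_posterior(ModelSpec("rasch"), data,
                             FitConfig(n_chains=2, n_iterations=20,
                                       n_burnin=10, seed=0))

    def test_quadrature_oracle_single_cell(self):
        # one person, one item, one correct response; sigma_beta fixed at 1.
        # The exact posterior of (theta, beta) is a 2-D integral; the
        # sampler's E[beta - theta] must agree with dense-grid quadrature.
        data = ResponseMatrix.from_values(np.array([[1]]))
        # the contrast has posterior sd ~1.2, so 40k retained draws keep
        # the Monte-Carlo error of its mean well inside the tolerance
        cfg = FitConfig(n_chains=4, n_iterations=12000, n_burnin=2000,
                        seed=12, fixed_sigma_beta=1.0, store_pointwise=False)
        fit = sample_posterior(ModelSpec("rasch"), data, cfg)
        contrast = fit.pooled("beta")[:, 0] - fit.pooled("theta")[:, 0]

        g = np.linspace(-8, 8, 1201)
        th, be = np.meshgrid(g, g, indexing="ij")
        logpost = (norm.logpdf(th) + norm.logpdf(be)
                   + np.log(expit(th - be)))
        w = np.exp(logpost - logpost.max())
        exact = float(((be - th) * w).sum() / w.sum())
        assert contrast.mean() == pytest.approx(exact, abs=0.02)

    def test_degenerate_single_cell_runs(self):
        data = ResponseMatrix.from_values(np.array([[1]]))
        cfg = FitConfig(n_chains=2, n_iterations=50, n_burnin=20, seed=1)
        fit = sample_posterior(ModelSpec("rasch"), data, cfg)
        assert np.isfinite(fit.pooled("beta")).all()


class TestRhat:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        seq = rng.normal(size=500)
        chains = np.stack([seq, seq, seq, seq])
        assert compute_rhat(chains) <= 1 + 1e-6

    def test_gross_nonconvergence(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert compute_rhat(chains) > 1.05

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 1000))
        assert 0.99 <= compute_rhat(chains) <= 1.01

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(4, 200, 3))
        vec = compute_rhat(arr)
        for k in range(3):
            assert vec[k] == pytest.approx(compute_rhat(arr[:, :, k]))

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((1, 100)))

    def test_agrees_with_reference_implementation(self):
        import arviz as az
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(4, 400)) + rng.normal(
            size=(4, 1))  # chain offsets force R-hat > 1
        ours = compute_rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains),
                               method="split").x.values)
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSummaries:
    def test_hpdi_degenerate(self):
        lo, hi = hpdi(np.full(50, 3.3))
        assert (lo, hi) == (3.3, 3.3)

    def test_hpdi_normal(self):
        draws = np.random.default_rng(5).standard_normal(1_000_000)
        lo, hi = hpdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_hpdi_mass_validation(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(10.0), 1.5)

    def test_summary_layout(self, rasch_small_fit):
        table = posterior_summary(rasch_small_fit, params=["beta"])
        assert list(table.columns) == [
            "Estimate", "SD", "HPDI_lower", "HPDI_upper", "R-hat"]
        assert len(table) == 8
        assert (table["HPDI_lower"] <= table["Estimate"]).all()
        assert (table["Estimate"] <= table["HPDI_upper"]).all()

    def test_summary_mass_validation(self, rasch_small_fit):
        with pytest.raises(ValueError):
            posterior_summary(rasch_small_fit, mass=0.0)
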
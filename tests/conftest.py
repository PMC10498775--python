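import numpy as np
import pytest

from glirt import (
    FitConfig,
    ModelSpec,
    SimulationDesign,
    draw_true_parameters,
    sample_posterior,
    simulate_responses,
)


@pytest.fixture(scope="session")
def rasch_small():
    """Small Rasch dataset + truth shared across test modules."""
    design = SimulationDesign(200, 8, true_family=ModelSpec("rasch"),
                              base_seed=101)
    rng = np.random.default_rng(design.base_seed)
    truth = draw_true_parameters(design, rng)
    data = simulate_responses(truth, design.true_family, rng)
    return design, truth, data


@pytest.fixture(scope="session")
def rasch_small_fit(rasch_small):
    """A converged-enough small Rasch fit with pointwise log-likelihood."""
    _, _, data = rasch_small
    cfg = FitConfig(n_chains=2, n_iterations=700, n_burnin=300, seed=7)
    return sample_posterior(ModelSpec("rasch"), data, cfg)


@pytest.fixture(scope="session")
def glogit_small_fit():
    """Small free-shape fit exercising every sampled block."""
    design = SimulationDesign(150, 6, true_family=ModelSpec("glogit_free"),
                              base_seed=202)
    rng = np.random.default_rng(design.base_seed)
    truth = draw_true_parameters(design, rng)
    data = simulate_responses(truth, design.true_family, rng)
    cfg = FitConfig(n_chains=2, n_iterations=500, n_burnin=250, seed=8)
    return sample_posterior(ModelSpec("glogit_free"), data, cfg)
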
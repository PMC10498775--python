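# glirt

Bayesian one-parameter item response models with generalized (Stukel) logit
links: flexible asymmetric item characteristic curves, MCMC estimation,
model comparison (DIC / LPML / WAIC / PSIS-LOO), and replicated
parameter-recovery and model-selection simulation studies.

## The problem

Classical one-parameter item response theory (IRT) models — the Rasch
(logit) model, the one-parameter normal ogive (probit), the complementary
log-log model — force every item characteristic curve (ICC) to share one
fixed link, and the first two force it to be symmetric.  Real dichotomous
response data (educational assessments, patient-reported outcomes,
questionnaires) often show asymmetric behavior: guessing keeps the lower
tail of an item's curve above its nominal floor, slipping keeps the upper
tail below 1, and the two tails need not behave alike.

`glirt` models the probability that person `i` answers item `j` correctly as

    P(x_ij = 1 | θ_i, β_j, λ_j) = exp{h_λj(θ_i − β_j)} / (1 + exp{h_λj(θ_i − β_j)}),

where `θ_i` is the person's latent trait, `β_j` the item difficulty, and
`h_λ` the Stukel generalized-logit transform with per-item shape parameters
`λ_j = (λ1_j, λ2_j)` (both > −1) that separately control how fast the curve
approaches its upper and lower asymptotes.  Special cases: `λ = (0, 0)` is
exactly the Rasch model; `λ ≈ (0.165, 0.165)` approximates the probit link
(1PNO); `λ ≈ (0.62, −0.037)` approximates the complementary log-log link
(CLLM).  Every curve passes through probability 1/2 at `θ = β`.  The
package also provides the exact probit/cloglog variants and the 3PL/4PL
logistic models for comparison.

Inference is fully Bayesian: `θ_i ~ N(0,1)`, `β_j ~ N(0, σ_β²)`,
`λ ~ N(0, σ_λ²)` truncated to `(−1, ∞)`, half-Cauchy(0, 5) priors on the
scales, sampled by a vectorized adaptive Metropolis-within-Gibbs scheme
(see `docs/methods.md`).  It is aimed at psychometricians and applied
statisticians who want flexible one-parameter IRT fits with principled
model comparison, and at methodologists running recovery/selection
simulation studies.

## Worked example

Simulate from a free-shape model and compare it against the Rasch fit:

```python
import numpy as np
from glirt import (ModelSpec, SimulationDesign, FitConfig,
                   draw_true_parameters, simulate_responses,
                   sample_posterior, posterior_summary, compute_criteria)

design = SimulationDesign(n_persons=500, n_items=10,
                          true_family=ModelSpec("glogit_free"), base_seed=7)
rng = np.random.default_rng(design.base_seed)
truth = draw_true_parameters(design, rng)
data = simulate_responses(truth, design.true_family, rng)

cfg = FitConfig(n_chains=4, n_iterations=3000, n_burnin=2000, seed=1)
fit = sample_posterior(ModelSpec("glogit_free"), data, cfg)
print(posterior_summary(fit, params=["beta"]).round(4).head(4))
print("max R-hat over all parameters:",
      round(float(fit.rhat.max()), 3))

report = compute_criteria(fit, ModelSpec("glogit_free"), data)
rasch_fit = sample_posterior(ModelSpec("rasch"), data, cfg)
rasch_rep = compute_criteria(rasch_fit, ModelSpec("rasch"), data)
print("glogit_free WAIC %.1f   rasch WAIC %.1f" % (report.waic, rasch_rep.waic))
```

Output:

```
           Estimate      SD  HPDI_lower  HPDI_upper   R-hat
parameter
beta[1]     -0.2061  0.1510     -0.4925      0.0996  1.0167
beta[2]     -1.3190  0.1949     -1.6861     -0.9193  1.0137
beta[3]     -0.7839  0.1614     -1.0989     -0.4765  1.0045
beta[4]      1.0317  0.1770      0.7184      1.3999  1.0158
max R-hat over all parameters: 1.034
glogit_free WAIC 5934.3   rasch WAIC 5974.7
```

The per-item difficulty estimates track the generating values (true
`β[1..4] = −0.285, −1.506, −0.977, 1.386`, each inside its 95% HPDI), every
split R-hat is below 1.05 at the default chain settings, and WAIC correctly
prefers the generating free-shape family over the misspecified symmetric
Rasch fit (5934 vs 5975; smaller is better).

The same workflow is available from the shell:

```
glirt simulate --family glogit_free --n-persons 500 --n-items 10 --seed 7 --out-dir run1
glirt fit      --data run1/responses.csv --family glogit_free --seed 1 --out-dir run1
glirt recover  --family rasch --n-persons 1000 --n-items 20 --reps 5 --out-dir rec
glirt compare  --true glogit_free --reps 5 --out-dir cmp
```

Response matrices are plain CSV (header = item ids, first column = person
id, cells 0/1 plus configurable missing codes, default {6, 9}); persons
containing missing codes are dropped by default or their cells can be
skipped in the likelihood (`exclusion="keep"`).

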
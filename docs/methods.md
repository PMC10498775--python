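# Methods

## The model

`glirt` fits one-parameter item response models in which person `i` answers
item `j` correctly with probability

    P(x_ij = 1 | theta_i, beta_j) = mu( h_lambda( theta_i - beta_j ) ),

where `mu(z) = exp(z) / (1 + exp(z))` is the logistic CDF and `h_lambda` is
the two-shape-parameter generalized logit transform of Stukel.  For a
positive linear predictor `eta = theta - beta` the upper shape `lambda1`
applies:

    lambda1 < 0:  -log(1 - lambda1 * eta) / lambda1
    lambda1 = 0:   eta
    lambda1 > 0:  (exp(lambda1 * eta) - 1) / lambda1

and for `eta <= 0` the lower shape `lambda2` applies to `|eta|` with a sign
flip.  The transform is strictly increasing with `h(0) = 0`, so the curve
always passes through probability 1/2 at `theta = beta`; the shapes only
control how fast the item characteristic curve (ICC) approaches its upper
(`lambda1`) and lower (`lambda2`) asymptotes.  Larger shape values give
faster convergence to the asymptote; values near -1 give very heavy tails
that mimic guessing (lower tail) or slipping (upper tail).

Named reductions: `(0, 0)` is exactly the Rasch (logit) model;
`(0.165, 0.165)` approximates the probit link and hence the one-parameter
normal ogive (1PNO) model; `(0.62, -0.037)` approximates the complementary
log-log link (CLLM).  These constants make the *shape* of the link agree
with the target link; the agreement is up to an affine rescaling of `eta`,
so the fixed-shape curves do not coincide pointwise with the exact probit or
cloglog ICCs (for example the exact cloglog curve passes through
1 - 1/e ~= 0.632 at `theta = beta` while every generalized-logit curve
passes through 0.5).  The package therefore exposes both variants:
`pno_glogit`/`cllm_glogit` (the fixed-shape approximations, which are what
the simulation studies mean by "1PNO" and "CLLM") and
`pno_exact`/`cllm_exact` (the exact links), and never asserts pointwise
equality between them.

The 3PL and 4PL logistic models, `c + (d - c) * mu(alpha * eta)` with
discrimination `alpha`, guessing floor `c` and slipping ceiling `1 - d`
(`d = 1` for the 3PL), are included as comparison families; the 3PL is
implemented as a 4PL with `d` fixed at 1.

## Priors and identification

    theta_i  ~ N(0, 1)
    beta_j   ~ N(0, sigma_beta^2)
    lambda_1j, lambda_2j ~ N(0, sigma_lambda^2) truncated to (-1, inf)
    sigma_beta, sigma_lambda ~ half-Cauchy(0, 5)

The unit-scale prior on `theta` anchors both the location and the scale of
the latent trait; no further constraints are imposed.  Shapes at or below
-1 make the posterior improper, hence the truncation; its normalizing
constant `Phi(1/sigma_lambda)` is carried in the density so that
`sigma_lambda` updates are correct.  For the 3PL/4PL families,
`log alpha_j ~ N(0, 1)`, `c_j ~ U(0, 0.5)`, and `d_j ~ U(0.5, 1)` — i.e. a
uniform prior on the slipping probability `1 - d`, consistent with
generating values of `d` concentrated near 0.77.

## Posterior computation

No probabilistic-programming backend is used; the sampler is an adaptive
random-walk Metropolis-within-Gibbs scheme written directly against numpy,
exploiting the conditional-independence structure of IRT: given the item
parameters all abilities are conditionally independent (and vice versa), so
each block proposes all of its coordinates at once and accepts/rejects them
elementwise, and all chains advance together as a leading array dimension.
Blocks per iteration: `theta`, `beta`, a joint location shift, the shapes
(free model only, three sweeps), the 3PL/4PL item blocks where applicable,
and the prior scales on the log scale (with Jacobian).

Two blocks deserve comment:

* **Location shift.**  The likelihood depends on `theta - beta` only, so the
  common location of all parameters is identified solely by the priors and
  mixes very slowly under coordinatewise updates (empirically inflating the
  difficulty MSE by about 2x).  A Metropolis move that proposes
  `(theta + c, beta + c)` jointly leaves the likelihood invariant, costs no
  likelihood evaluation, and restores the expected error magnitudes.
* **Shape sweeps.**  The per-item shapes trade off against `beta` and the
  tail `theta` values and are the slowest-mixing block; they are refreshed
  three times per iteration in the free model, which brings the maximum
  split R-hat at the N=1000, J=20 reference condition from ~1.051 to ~1.043
  with 4 chains of 3000 iterations.

Proposal scales are tuned per coordinate toward a 0.44 acceptance rate by
Robbins-Monro updates during burn-in only; after burn-in the kernel is
frozen (so the retained draws target the exact posterior) and realized
acceptance rates are tracked and surfaced as warnings when extreme.
Shape proposals below -1 are rejected through the prior.  Chains start from
prior-style draws with all shapes at 0, i.e. every chain begins at the
logit special case; a `near_zero` initialization is available for
debugging.  Fits are exactly reproducible given (model, data, config):
all chains share one seeded generator.

Numerical choices: probabilities are never materialized in the likelihood —
the Bernoulli log-likelihood is `log_expit((2x - 1) * h)`, stable to
`|h| ~ 700`, and the exponent inside the positive-shape branch is capped at
700; shapes with `|lambda| < 1e-8` use the exact linear limit of the
transform, avoiding 0/0; the exact cloglog likelihood uses `expm1`/`log1p`
throughout.  Degenerate inputs (a single person and item) run and return
wide posteriors; persons or items with no observed responses are an error.

Correctness was checked two independent ways: posterior means against dense
two-dimensional grid quadrature on a single-cell toy (the shipped test
suite), and the full posterior against a JAGS fit of the identical
model/priors on an N=2000 Rasch dataset during development (posterior SD
0.0602 vs 0.0609, difficulty MSE 0.0061 vs 0.0062).

## Diagnostics and summaries

Convergence is monitored with the classic split potential scale reduction
factor (each chain halved, Brooks–Gelman between/within ratio, no rank
normalization), computed for every scalar parameter and cross-checked
against arviz's `method="split"` variant in the tests.  Posterior summaries
report the mean ("Estimate"), SD, shortest-interval HPDI at 95% mass, and
R-hat per parameter.

## Model comparison

All four criteria are computed from the matrix of per-draw, per-observation
log-likelihood values (observation level, one column per observed response):

* DIC with the plug-in effective-parameter count, the plug-in deviance
  evaluated at posterior means taken on the sampling scale (log scale for
  positive parameters, `log(1 + lambda)` for shapes) and back-transformed,
  so the plug-in point always lies in the support;
* LPML as the sum of log conditional predictive ordinates (harmonic means
  computed in log space), reported as a log score — negative, larger better;
* WAIC with the variance-based penalty (unbiased `S - 1` variance);
* PSIS-LOO on the deviance scale, with the generalized-Pareto tail
  smoothing delegated to arviz's `psislw` and per-cell Pareto-k diagnostics
  returned; below 100 draws the code falls back to raw importance sampling
  with a warning.

DIC/WAIC/LOO are "smaller is better"; LPML is maximized.  Selection counts
rank families per replication with ties broken by input order, and
replications with non-finite criteria are excluded pairwise.

## Simulation studies and the data generator

Generating conditions: `theta ~ N(0, 1)`, `beta ~ N(0, 1)`; free-model
shapes `N(0, 0.5^2)` truncated to `(-1, inf)` by rejection (acceptance
~0.977); 3PL/4PL truths `alpha ~ U(0.5, 2)`, `c ~ Beta(5, 17)`,
`d ~ Beta(17, 5)`.  Responses are independent Bernoulli draws from the ICC
— no testlet effects, no missingness (except the `pisa_like` fixture, which
plants missing codes 6/9 in 76 of 685 rows to exercise the exclusion
machinery), no response-time or position effects.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

Recovery is scored by Bias, MSE, SE (replication scatter), and SD (average
posterior SD), averaged over items (or persons for `theta`).  The MSE
column is the mean *squared* error: the exact identity `mse = se^2 + bias^2`
is asserted on every computation, and published recovery tables satisfy it
only under the squared-error reading; RMSE is exposed separately.

Two truth-handling designs are available.  The default draws the generating
parameters once per condition and redraws only the responses each
replication — this is the design under which the SE criterion (scatter of
the estimates around their replication mean) measures pure sampling error.
`redraw_truths=True` draws fresh truths every replication and scores each
against its own truth.  The difference matters because of a location
artifact: the likelihood sees only `theta - beta`, the fitted model anchors
the posterior ability mean near 0, and the sample mean of N generated
abilities is not exactly 0 (sd `1/sqrt(N)`, ~0.02 at N = 2000), so every
difficulty estimate absorbs the same random offset plus a comparable
response-noise wobble.  A fixed-truth condition inherits one draw of this
offset in its bias and MSE (about +0.0005-0.002 on the MSE at N = 2000,
occasionally more); redrawing truths averages it toward its expectation.
Reported difficulty-MSE values in recovery studies at this scale should
therefore be read with a ±30% band: they are one draw from a distribution
whose spread is dominated by the truth-draw luck (location offset and the
occasional |beta| > 2.5 item, whose estimate takes a large shrinkage hit),
not by the estimator.

Replication `r` of a study uses data seed `base_seed + r` and an offset fit
seed.  The reference chain settings are 4 chains x 3000 iterations with
2000 burn-in; the packaged studies default to reduced replication counts
(e.g. 10 rather than 50 replications for recovery, with the reduced sizes
stated wherever they are used) because the four accuracy criteria are
averages over 20-40 items and are already stable at that scale.

## Known limitations

* Random-walk Metropolis needs roughly an order of magnitude more
  iterations than a gradient-based sampler for the same effective sample
  size; the defaults compensate with vectorization, and all chain lengths
  are configurable.
* The free model's shapes are weakly identified per item (posterior SDs
  ~0.2-0.6 at N=1000); their recovery is intrinsically poorer than the
  difficulties', and shape-vs-ability trade-offs are the main source of
  residual autocorrelation.
* Dichotomous responses only; no polytomous/graded extensions, no
  multidimensional traits, no alternative link families beyond the Stukel
  class and the exact probit/cloglog references.
* DIC uses the plug-in penalty; variance-based p_D would shift values by a
  few units.
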
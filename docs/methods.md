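# Methods

## Model and assumptions

The package fits a normal-theory stable-isotope mixing model. For consumer
*i* and isotope *j* (J = 2 by default: δ¹³C, δ¹⁵N), the observed value is a
proportion-weighted mixture of source values shifted by a trophic
discrimination factor (TDF), plus residual error:

    X_ij = Σ_k p_k (s_jk + c_j) + ε_ij,
    s_jk ~ Normal(μ_jk, ω_jk²),  p ~ Dirichlet(α),  ε_ij ~ Normal(0, σ_j²).

Marginalising the source draws gives the likelihood actually evaluated:

    X_ij ~ Normal( Σ_k p_k (μ_jk + c_j),  Σ_k p_k² (ω_jk² + τ_j²) + σ_j² ).

Assumptions worth stating explicitly:

* **One TDF per isotope.** The offset `c_j` is shared across sources. The
  field reports TDFs this way (e.g. the red fox 2.6/3.4‰ pair applied to
  every prey), and a controlled-feeding dataset with a single consumer
  tissue cannot separate per-source offsets.
* **Independence across isotopes and consumers.** No covariance between
  δ¹³C and δ¹⁵N is modelled; consumers are exchangeable.
* **Source summaries, not source samples.** The model consumes per-source
  (mean, SD); `summarize_sources` produces these from raw tissue tables
  with n−1 SDs.
* **TDF uncertainty placement.** In diet mode the TDF SD `τ_j` enters the
  combined variance weighted by `p_k²` (the SIAR convention). Where the
  TDF should instead be a stochastic node, `tdf_as_node=True` samples
  `c_j ~ Normal(mean, τ_j²)` and removes `τ` from the variance; the default
  was chosen because the reference analysis supplies TDF SDs as data.
* **Residual term.** `ε_ij` is on by default (`include_residual=False`
  disables it). On the reference configuration the TDF estimates move by
  well under a tenth of a permil when it is dropped, which the test suite
  checks at a coarse tolerance.

## Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| `c_j` prior (TDF mode) | ‰ | Uniform(0, 10) | vague; positive discrimination is the norm for C and N. Note it truncates negative discrimination; retained deliberately. |
| `σ_j` prior | ‰ | Uniform(0, 10) | matches the vagueness of the `c` prior; the data scale is a few permil |
| diet prior | — | Dirichlet(1,…,1) | non-informative reference point of the sensitivity analysis |
| chains / burn-in / samples / thin | — | 3 / 50,000 / 15,000 / 15 | the full reference protocol; reduced budgets are explicit, never silent |
| PSRF threshold | — | 1.1 | standard Gelman–Rubin convergence gate |
| bootstrap B | — | 1,000 | reference bootstrap size; SDs of the diet proportions stabilise well before this |
| Dirichlet-MLE floor | — | 1e−6 | bootstrap draws can contain exact zeros for rare prey; the Dirichlet density is degenerate at the boundary |

## Sampler

Metropolis-within-Gibbs. The simplex is parameterised by softmax with the
first coordinate pinned to zero; the Dirichlet prior plus log-Jacobian
combine to `Σ_k α_k log p_k`, evaluated jointly with a Gaussian random-walk
proposal on the K−1 free coordinates. Each `c_j` and each `log σ_j` gets a
scalar random walk (the log transform contributes the `+log σ` Jacobian
under the uniform prior). Step sizes adapt every 50 iterations during
burn-in toward acceptance rates of 0.3 (block) / 0.44 (scalar) and are
frozen afterwards, so retained draws come from a fixed-kernel chain.
Initialisation: `p` at the prior mean, `c` at the prior midpoint (or the
TDF mean when it is a node), `σ` at 0.5, each jittered per chain for
overdispersed starts. The likelihood is evaluated through per-isotope
sufficient statistics (consumer mean and sum of squares), which is exact
for this Normal model and makes the full reference protocol run in seconds.

Convergence is the classic potential scale reduction factor
`sqrt(((n−1)/n·W + B/n)/W)` per scalar parameter, computed across chains
on the thinned draws (no rank-normalisation; the test suite cross-checks
against arviz on well-mixed chains). Breaches warn by default and can be
promoted to errors.

## Bootstrap diet and Dirichlet fit

Each feeding-record item receives a body mass drawn Uniform(min, max) for
its species *independently per item per iteration*; a diet draw is the
per-species mass fraction. Records after the hair-growth cutoff date are
excluded. Per-individual bootstraps run first and their 95% percentile CIs
are checked for overlap — a warning, not a failure, since pooling is the
analyst's call. All intervals in the package are percentile intervals.

The Dirichlet MLE uses Minka's fixed-point update
`α_k ← ψ⁻¹(ψ(Σα) + mean log p_k)` (monotone in likelihood, moment-matched
start) and switches to Newton steps on the structured Hessian
(`c·11ᵀ − diag(q)`, inverted by Sherman–Morrison) to reach a per-draw
gradient max-norm below 1e−8 — pure fixed-point stalls short of that for
concentrated fits. Near-zero-variance draw sets and diverging
concentrations raise a diagnostic error rather than returning nonsense.

## Equivalence test and prior search

A posterior is "equivalent" to a reference diet when, for every source,
the 95% percentile CI of 1,000 posterior-minus-reference differences
contains zero. Posterior draws are subsampled without replacement;
reference draws come from the Dirichlet (or are subsampled when a draw
matrix is supplied). Subtraction is between independently sampled sets,
not matched pairs.

The candidate schedule makes the stepwise search deterministic: phase 1
raises the leading α one integer at a time (others at 1) until it equals
the rounded ratio of the two largest reference means; phase 2 scales the
top pair at that ratio until the full ranking of means is reflected
(integer multiples); phase 3 scales the whole vector proportionally. Ties
for "most consumed" break by source order. The full trace (candidate,
CIs, pass flag) is returned so the minimality of the selection — the
preceding candidate fails — is auditable, and alternative schedules can be
passed in. Per-candidate MCMC may use a reduced budget (the search is the
expensive loop); fresh per-candidate seeds derive from the master seed.

## Evaluation metrics

Bias is the mean of n = 1,000 paired posterior-minus-reference
differences; variance is the n−1 sample variance of the posterior draws
themselves (not of the differences — the decomposition only closes on the
reference tables under this reading); MSE = variance + bias², asserted to
1e−9 at construction. `compare_models` differences each model's posterior
against a baseline model's posterior and reports the difference CI, bias,
variance difference (model minus baseline) and MSE per source.

## Synthetic data

The generator emulates exactly the structure the model assumes: consumers
drawn from the marginal Normal above, source samples drawn
Normal(μ, ω²), feeding items split as evenly as possible across
individuals (the controlled trial guaranteed equal access to food) with
uniform dates, and uniform per-item masses. This is deliberate: parameter
recovery on such data tests the inference machinery, not model
misspecification. What it does **not** emulate — isotopic covariance
between elements, tissue-turnover dynamics, digestibility differences
between prey, among-individual diet heterogeneity — means a passing
recovery suite says nothing about those failure modes on field data. One
scenario seed drives deterministic sub-streams per stage, so e.g. source
samples do not change when the consumer count does.

Where only consumer summary statistics are available (the reference wolf
hair data are published as mean ± SD of 10 animals), `simulate_consumers`
draws a synthetic consumer matrix from those summaries; reproduced
posterior quantities then carry that extra simulation noise, which is why
desk-scale checks average over ≥3 consumer replicates.

## Numerical choices and degenerate inputs

* States outside support (simplex violations, bounds, non-positive
  variance) have log-posterior −inf by contract; proposals there are
  rejected rather than erroring.
* A non-finite log posterior at initialisation (e.g. zero total variance
  with an exactly-fitting configuration removed) raises immediately.
* `n_samples` must be a multiple of `thin` so draws-per-chain is integral.
* Bootstrap with a single species returns proportion 1 with SD 0; the
  Dirichlet MLE refuses such degenerate draw sets.
* Acceptance of the equivalence test at the exact boundary (CI endpoint
  equal to zero) counts as overlap.

## Reduced budgets

Quantitative checks in the test suite and the acceptance script run the
MCMC at a five-fold reduction of the full protocol (burn-in 10,000, 3,000
sampling iterations thinned by 3, so the 1,000 kept draws per chain are
unchanged), which this low-dimensional posterior passes at PSRF < 1.1 with
margin; the prior search uses a smaller per-candidate budget (burn-in
3,000, 1,000 kept per chain) because it fits up to ~25 models per TDF set.
These sizes are package choices made once; the full protocol remains the
`MCMCConfig` default.

## Known limitations

* No concentration dependence, isotopic routing, time-varying diet or
  other MixSIAR-class extensions; no per-source TDFs.
* The uniform TDF prior excludes negative discrimination; change
  `tdf_bounds` if a tissue with negative offsets is analysed.
* The Dirichlet fitted to bootstrap diet draws inherits the bootstrap's
  narrowness; with pooled histories the implied SD can differ from the
  bootstrap SD itself, so the fitted α is best treated as an informative
  prior, not as the definitive diet uncertainty.
* The Gelman–Rubin statistic here is the classic PSRF; rank-normalised
  split-Rhat (arviz) is stricter on some pathologies.
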
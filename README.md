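# tdfmix

Bayesian stable-isotope mixing models (SIMMs) with explicit treatment of
the two inputs that dominate their behaviour: **trophic discrimination
factors (TDFs)** and **Dirichlet prior information**.

Stable isotope analysis infers what a consumer eats from the δ¹³C and δ¹⁵N
values of its tissues and of its candidate prey. `tdfmix` is aimed at
trophic ecologists who want to go beyond fitting a single mixing model: it
estimates TDFs directly from a controlled-feeding dataset, quantifies how
strongly the choice of prior and TDF set drives the posterior diet, and
finds the *minimum informative prior* — the vaguest Dirichlet under which
the model's diet estimate becomes statistically indistinguishable from an
independently known reference diet.

## The model

The isotope value of consumer *i* on isotope *j* mixes *K* sources:

```
X_ij = Σ_k p_k (s_jk + c_j) + ε_ij
s_jk ~ Normal(μ_jk, ω_jk²)     p ~ Dirichlet(α)     ε_ij ~ Normal(0, σ_j²)
var(X_ij) = Σ_k p_k² (ω_jk² + τ_j²) + σ_j²
```

where `p_k` are diet proportions, `c_j` the per-isotope discrimination
offset (with SD `τ_j` when supplied as data), and `σ_j` a residual SD.
One likelihood serves two modes:

* **diet mode** — estimate `p` given TDFs (`c_j` fixed, `τ_j` folded into
  the combined variance, SIAR-style), under any Dirichlet prior;
* **TDF mode** — estimate `c_j` given an informative diet Dirichlet from a
  controlled feeding trial, with vague Uniform(0, 10) priors.

Sampling is Metropolis-within-Gibbs (softmax-parameterised simplex,
random-walk `c` and `log σ`, burn-in-only adaptation), monitored with the
Gelman–Rubin PSRF (< 1.1). Around the model sit:

* a mass-based **bootstrap** of diet composition from feeding records, and
  a maximum-likelihood **Dirichlet fit** to the bootstrap draws;
* a 1,000-draw **equivalence test** (95% CIs of posterior − reference
  differences all overlapping zero) and a stepwise **prior search**;
* **bias / variance / MSE** evaluation (`MSE = var + bias²`) and a
  four-model prior × TDF comparison;
* a **synthetic-data generator** producing feeding records and isotope
  datasets with exactly the statistical structure the model assumes.

## Worked example

The bundled reference dataset (`tdfmix.datasets`) holds the summary
statistics of a captive feeding trial in which 10 gray wolves ate
white-tailed deer, beaver and Canada goose:

```python
import numpy as np
from tdfmix import MixingModel, MCMCConfig, bootstrap_diet, fit_dirichlet_mle
from tdfmix import generate_feeding_records
from tdfmix.datasets import (
    CAPTIVE_SOURCES, DIET_ALPHA, FEEDING_START, HAIR_GROWTH_CUTOFF,
    ITEM_COUNTS, MASS_RANGES_KG, WOLF_RUMP_MEAN, WOLF_RUMP_SD,
)
from tdfmix.synthetic import simulate_consumers

# 1. Diet by mass from the item counts (106 deer, 14 beaver, 121 geese)
records = generate_feeding_records(
    ITEM_COUNTS, FEEDING_START, HAIR_GROWTH_CUTOFF, 10, seed=17)
diet = bootstrap_diet(records, MASS_RANGES_KG, HAIR_GROWTH_CUTOFF,
                      B=1000, seed=17)
print(diet.summary().round(3))

# 2. Estimate wolf discrimination factors from that diet
wolves = simulate_consumers(WOLF_RUMP_MEAN, WOLF_RUMP_SD, 10, seed=1)
model = MixingModel(wolves, CAPTIVE_SOURCES, mode="tdf", prior=DIET_ALPHA)
cfg = MCMCConfig(burn_in=10_000, n_samples=3_000, thin=3)
print(model.fit(cfg, seed=1).summary().round(2))
```

prints

```
         mean     sd  ci_2.5%  ci_97.5%
source
deer    0.944  0.003    0.938     0.950
beaver  0.019  0.002    0.015     0.023
goose   0.037  0.001    0.034     0.040

             mean    sd  ci_2.5%  ci_97.5%  psrf
parameter
p[deer]      0.94  0.01     0.92      0.96   1.0
p[beaver]    0.02  0.01     0.01      0.03   1.0
p[goose]     0.04  0.01     0.03      0.06   1.0
c[d13C]      1.96  0.75     0.51      3.46   1.0
c[d15N]      3.01  0.33     2.36      3.65   1.0
sigma[d13C]  0.70  0.59     0.03      2.13   1.0
sigma[d15N]  0.30  0.25     0.01      0.92   1.0
```

Deer dominate the diet by mass (~0.94), and the recovered discrimination
factors are ≈2.0‰ for δ¹³C and ≈3.0‰ for δ¹⁵N — the posterior SD on the
carbon offset is large because deer muscle δ¹³C itself varies by 2.35‰.
Refitting in diet mode with a flat Dirichlet(1,1,1) prior then *fails* to
recover this diet (deer ≈ 0.54–0.66 depending on the TDF set), which is
precisely the prior-sensitivity phenomenon the package quantifies;
`minimum_informative_prior` walks a deterministic α-schedule until the
posterior first becomes equivalent to the bootstrap diet.

A `tdfmix` CLI wraps the same functions (`diet-bootstrap`, `simm`,
`prior-search`, `evaluate`, `synth`, `run-captive`, `run-field`).

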
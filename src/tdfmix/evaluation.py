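"""Bias, Monte-Carlo variance and MSE of posterior diet estimates.

Against a reference diet (a Dirichlet, a matrix of bootstrap draws, or a
baseline model's posterior), posterior quality per source is measured as

* bias: mean of n paired (posterior - reference) differences;
* variance (precision): sample variance of the n posterior draws themselves;
* MSE (accuracy): variance + bias^2 — smaller is more accurate.

The variance is deliberately that of the posterior draws, not of the
differences: this is the decomposition under which the MSE identity closes
on the reported tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DirichletSpec
from .mixing import MCMCConfig, MixingModel, MixingResults

__all__ = ["EvaluationMetrics", "evaluate_posterior", "compare_models"]


@dataclass(frozen=True)
class EvaluationMetrics:
    """Per-source bias, variance, MSE and difference CIs for one model."""

    sources: tuple[str, ...]
    bias: np.ndarray
    variance: np.ndarray
    mse: np.ndarray
    n: int
    ci_low: np.ndarray
    ci_high: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")
        if not np.allclose(self.mse, self.variance + self.bias**2, atol=1e-9):
            raise ValueError("MSE identity violated: mse != variance + bias^2")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bias": self.bias,
                "variance": self.variance,
                "mse": self.mse,
                "ci_2.5%": self.ci_low,
                "ci_97.5%": self.ci_high,
            },
            index=pd.Index(self.sources, name="source"),
        )


def _reference_draws(
    reference: DirichletSpec | np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(reference, DirichletSpec):
        return reference.sample(n, rng)
    ref = np.asarray(reference, float)
    if ref.shape[0] < n:
        raise ValueError(f"reference has {ref.shape[0]} draws; need {n}")
    return ref[rng.choice(ref.shape[0], n, replace=False)]


def evaluate_posterior(
    posterior: MixingResults | np.ndarray,
    reference: DirichletSpec | np.ndarray,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    sources: Sequence[str] | None = None,
) -> EvaluationMetrics:
    """Measure a posterior's bias/precision/accuracy against a reference.

    Pairs ``n`` posterior draws (sampled without replacement) with ``n``
    reference draws under the given seed.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if sources is None:
        if isinstance(posterior, MixingResults):
            sources = posterior.model.source_names
        elif isinstance(reference, DirichletSpec):
            sources = reference.sources
        else:
            raise ValueError("source names required when both inputs are arrays")
    sources = tuple(sources)
    if isinstance(reference, DirichletSpec) and tuple(reference.sources) != sources:
        raise ValueError("reference sources do not match")

    post = (
        posterior.p_draws
        if isinstance(posterior, MixingResults)
        else np.asarray(posterior, float)
    )
    if post.shape[0] < n:
        raise ValueError(f"posterior has {post.shape[0]} draws; need {n}")
    post = post[rng.choice(post.shape[0], n, replace=False)]
    ref = _reference_draws(reference, n, rng)

    diffs = post - ref
    bias = diffs.mean(axis=0)
    variance = post.var(axis=0, ddof=1)
    return EvaluationMetrics(
        sources=sources,
        bias=bias,
        variance=variance,
        mse=variance + bias**2,
        n=n,
        ci_low=np.percentile(diffs, 2.5, axis=0),
        ci_high=np.percentile(diffs, 97.5, axis=0),
    )


def compare_models(
    models: Mapping[str, MixingModel | MixingResults],
    baseline: MixingModel | MixingResults,
    config: MCMCConfig | None = None,
    seed: int = 0,
    n: int = 1000,
) -> pd.DataFrame:
    """Compare fitted diet models against a baseline model's posterior.

    Each model's posterior draws are differenced against the baseline's.
    Output is one tidy row per (model, source): posterior mean and SD, the
    95% CI of the difference, a significance flag ``sig`` set when that CI
    overlaps zero, bias, the variance difference (model minus baseline) and
    MSE (model variance + bias^2).

    Accepts either unfitted models (fitted here with seeds derived from
    ``seed``) or already-fitted :class:`MixingResults`.
    """
    cfg = config or MCMCConfig()
    ss = np.random.SeedSequence(seed)
    fit_seeds = iter(ss.spawn(len(models) + 1))

    def ensure_fit(m: MixingModel | MixingResults) -> MixingResults:
        if isinstance(m, MixingResults):
            return m
        s = int(next(fit_seeds).generate_state(1)[0] % 2**31)
        return m.fit(cfg, seed=s)

    base_res = ensure_fit(baseline)
    base_names = tuple(base_res.model.source_names)
    pair_rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    for name, m in models.items():
        res = ensure_fit(m)
        if tuple(res.model.source_names) != base_names:
            raise ValueError(
                f"model {name!r} sources {res.model.source_names} do not "
                f"match baseline {base_names}"
            )
        metrics = evaluate_posterior(
            res, base_res.p_draws, n=n, seed=pair_rng, sources=base_names
        )
        means = res.p_draws.mean(axis=0)
        sds = res.p_draws.std(axis=0, ddof=1)
        for k, src in enumerate(base_names):
            rows.append(
                {
                    "model": name,
                    "source": src,
                    "mean": means[k],
                    "sd": sds[k],
                    "ci_low": metrics.ci_low[k],
                    "ci_high": metrics.ci_high[k],
                    "sig": bool(
                        metrics.ci_low[k] <= 0.0 <= metrics.ci_high[k]
                    ),
                    "bias": metrics.bias[k],
                    "variance_diff": metrics.variance[k]
                    - base_res.p_draws[:, k].var(ddof=1),
                    "mse": metrics.mse[k],
                }
            )
    return pd.DataFrame(rows)
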
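"""Minimum-informative-prior search and the equivalence test.

A Dirichlet prior is "minimum informative" for a dataset when it is the
least concentrated member of a deterministic candidate schedule whose
posterior diet is statistically indistinguishable from a reference diet.
Indistinguishability is judged by drawing 1,000 proportion vectors from the
reference Dirichlet, subtracting them from 1,000 sampled posterior vectors,
and requiring every source's 95% percentile interval of the differences to
overlap zero.

The candidate schedule raises the alpha of the most-consumed source one
integer at a time (others at 1) until the leading alpha matches the rounded
ratio of the top two reference means; it then scales the top pair at that
ratio until the full ranking of reference means is reflected, and finally
scales the whole vector proportionally.  The schedule is deterministic and
recorded in the trace so alternative schedules can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DirichletSpec
from .mixing import MCMCConfig, MixingModel, MixingResults

__all__ = [
    "EquivalenceResult",
    "PriorSearchTrace",
    "equivalence_test",
    "candidate_schedule",
    "minimum_informative_prior",
    "PriorSearchError",
]


class PriorSearchError(RuntimeError):
    """No candidate in the schedule passed the equivalence test."""

    def __init__(self, msg: str, trace: "PriorSearchTrace") -> None:
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class EquivalenceResult:
    """Per-source 95% CIs of (posterior - reference) differences."""

    sources: tuple[str, ...]
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_diff: np.ndarray
    passed: bool

    def __post_init__(self) -> None:
        ok = bool(np.all((self.ci_low <= 0.0) & (self.ci_high >= 0.0)))
        if ok != self.passed:
            raise ValueError("pass flag inconsistent with the CIs")


@dataclass
class PriorSearchTrace:
    """Ordered candidates with their equivalence results."""

    sources: tuple[str, ...]
    candidates: list[tuple[np.ndarray, EquivalenceResult]] = field(
        default_factory=list
    )
    selected: DirichletSpec | None = None

    @property
    def selected_alpha(self) -> np.ndarray | None:
        return None if self.selected is None else self.selected.alpha


def _posterior_matrix(
    posterior: MixingResults | np.ndarray, sources: Sequence[str]
) -> np.ndarray:
    if isinstance(posterior, MixingResults):
        if tuple(posterior.model.source_names) != tuple(sources):
            raise ValueError(
                f"posterior sources {posterior.model.source_names} do not "
                f"match reference sources {tuple(sources)}"
            )
        return posterior.p_draws
    return np.asarray(posterior, float)


def equivalence_test(
    posterior: MixingResults | np.ndarray,
    reference: DirichletSpec | np.ndarray,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    sources: Sequence[str] | None = None,
) -> EquivalenceResult:
    """Test whether a diet posterior is indistinguishable from a reference.

    Subtracts ``n_draws`` reference proportion vectors (drawn from the
    Dirichlet, or subsampled if a draw matrix is given) from ``n_draws``
    posterior vectors sampled without replacement, and checks that each
    source's 95% percentile CI of the differences contains zero.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if sources is None:
        if isinstance(reference, DirichletSpec):
            sources = reference.sources
        elif isinstance(posterior, MixingResults):
            sources = posterior.model.source_names
        else:
            raise ValueError("source names required when both inputs are arrays")
    sources = tuple(sources)

    post = _posterior_matrix(posterior, sources)
    if post.shape[0] < n_draws:
        raise ValueError(
            f"posterior has {post.shape[0]} draws; need at least {n_draws}"
        )
    if isinstance(reference, DirichletSpec):
        if tuple(reference.sources) != sources:
            raise ValueError(
                f"reference sources {reference.sources} do not match {sources}"
            )
        ref = reference.sample(n_draws, rng)
    else:
        ref = np.asarray(reference, float)
        if ref.shape[0] < n_draws:
            raise ValueError(
                f"reference has {ref.shape[0]} draws; need at least {n_draws}"
            )
        ref = ref[rng.choice(ref.shape[0], n_draws, replace=False)]

    idx = rng.choice(post.shape[0], n_draws, replace=False)
    diffs = post[idx] - ref
    lo = np.percentile(diffs, 2.5, axis=0)
    hi = np.percentile(diffs, 97.5, axis=0)
    return EquivalenceResult(
        sources=sources,
        ci_low=lo,
        ci_high=hi,
        mean_diff=diffs.mean(axis=0),
        passed=bool(np.all((lo <= 0.0) & (hi >= 0.0))),
    )


def candidate_schedule(
    reference_means: Sequence[float],
    max_scale: int = 25,
) -> list[np.ndarray]:
    """Deterministic ladder of Dirichlet alpha vectors, vague to precise.

    Phase 1 raises the leading alpha 1, 2, 3, ... (others at 1) up to the
    rounded ratio of the top two reference means; phase 2 scales the top
    pair at that ratio until the third-ranked source reflects the full mean
    ratios; phase 3 scales the whole vector proportionally, ``max_scale``
    times.  Ties in "most consumed" break by source order.
    """
    m = np.asarray(reference_means, float)
    K = m.size
    if K < 2:
        raise ValueError("need at least 2 sources")
    if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-6:
        raise ValueError("reference means must lie on the simplex")

    order = np.argsort(-m, kind="stable")  # rank by consumption, ties by index
    top, second = order[0], order[1]
    cap = max(1, round(m[top] / m[second]))

    schedule: list[np.ndarray] = []

    def push(alpha: np.ndarray) -> None:
        if not schedule or not np.array_equal(schedule[-1], alpha):
            schedule.append(alpha)

    # Phase 1: leading alpha 1..cap, everything else at 1.
    for a in range(1, cap + 1):
        alpha = np.ones(K)
        alpha[top] = a
        push(alpha)

    # Phase 2: scale the top pair at cap:1 until all ranked ratios are met.
    base = schedule[-1].copy()
    full = np.maximum(1.0, np.round(m / max(m.min(), 1e-12)))
    if K > 2:
        third = order[2]
        s = 1
        while base[top] / base[third] < full[top] / full[third] and s < max_scale:
            s += 1
            cand = np.ones(K)
            cand[top] = cap * s
            cand[second] = s
            push(cand)
            base = cand

    # Phase 3: proportional scaling of the final ratio vector.
    for t in range(2, max_scale + 1):
        push(base * t)

    return schedule


def minimum_informative_prior(
    model: MixingModel,
    reference: DirichletSpec,
    config: MCMCConfig | None = None,
    seed: int = 0,
    n_draws: int = 1000,
    schedule: Sequence[np.ndarray] | None = None,
    max_scale: int = 25,
) -> PriorSearchTrace:
    """Walk the candidate schedule until the posterior matches the reference.

    Fits the diet-mode ``model`` under each candidate prior (fresh seeds per
    candidate derived from ``seed``), applies :func:`equivalence_test`
    against ``reference``, and returns the trace with the first passing
    candidate selected.  Raises :class:`PriorSearchError` (carrying the
    trace) if no candidate passes.

    ``config`` may use a reduced per-candidate MCMC budget; the selected
    prior can then be confirmed at the full protocol.
    """
    if model.mode != "diet":
        raise ValueError("prior search requires a diet-mode model")
    if tuple(reference.sources) != tuple(model.source_names):
        raise ValueError("reference sources do not match the model")
    cfg = config or MCMCConfig()
    if schedule is None:
        schedule = candidate_schedule(reference.mean, max_scale=max_scale)

    ss = np.random.SeedSequence(seed)
    trace = PriorSearchTrace(sources=tuple(model.source_names))
    for alpha, child in zip(schedule, ss.spawn(len(schedule))):
        fit_seed, test_seed = child.spawn(2)
        candidate = model.with_prior(alpha)
        results = candidate.fit(cfg, seed=int(fit_seed.generate_state(1)[0] % 2**31))
        res = equivalence_test(
            results,
            reference,
            n_draws=n_draws,
            seed=np.random.default_rng(test_seed),
        )
        trace.candidates.append((np.asarray(alpha, float), res))
        if res.passed:
            trace.selected = DirichletSpec(model.source_names, alpha)
            return trace
    raise PriorSearchError(
        f"no candidate among {len(schedule)} passed the equivalence test",
        trace,
    )
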
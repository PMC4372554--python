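"""Bootstrap estimation of diet composition and Dirichlet fitting.

Diet proportions are estimated from feeding histories by mass: each recorded
food item is assigned a body mass drawn Uniform(min, max) for its species,
and a diet draw is the vector of per-species mass fractions.  Repeating this
B times yields a bootstrap distribution of diet proportions.  A Dirichlet is
then fitted to those draws by maximum likelihood (Minka's fixed-point
iteration on the digamma system) to serve as an informative prior for the
mixing model.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma

from .core import DirichletSpec
from .synthetic import FeedingRecord, MassRange

__all__ = [
    "DietEstimate",
    "bootstrap_diet",
    "fit_dirichlet_mle",
    "dirichlet_loglike",
    "DirichletFitError",
]


class DirichletFitError(RuntimeError):
    """Raised when the Dirichlet MLE fails to converge or degenerates."""


@dataclass
class DietEstimate:
    """Bootstrap diet composition: summary statistics plus the raw draws."""

    sources: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    draws: np.ndarray  # (B, K), each row on the simplex
    per_individual: pd.DataFrame | None = None
    individual_cis_overlap: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": self.sd,
                "ci_2.5%": self.ci_low,
                "ci_97.5%": self.ci_high,
            },
            index=pd.Index(self.sources, name="source"),
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sources, self.mean))


def _coerce_ranges(
    ranges: Mapping[str, tuple[float, float]] | Iterable[MassRange],
) -> dict[str, MassRange]:
    if isinstance(ranges, Mapping):
        return {
            sp: MassRange(sp, float(lo), float(hi)) for sp, (lo, hi) in ranges.items()
        }
    return {r.species: r for r in ranges}


def _mass_proportions(
    species_idx: np.ndarray, lo: np.ndarray, hi: np.ndarray, K: int,
    B: int, rng: np.random.Generator,
) -> np.ndarray:
    """B bootstrap draws of per-species mass fractions for one item list."""
    n = species_idx.size
    masses = rng.uniform(lo, hi, size=(B, n))  # one mass per item per iteration
    totals = np.zeros((B, K))
    for k in range(K):
        sel = species_idx == k
        if sel.any():
            totals[:, k] = masses[:, sel].sum(axis=1)
    return totals / totals.sum(axis=1, keepdims=True)


def bootstrap_diet(
    records: Sequence[FeedingRecord],
    ranges: Mapping[str, tuple[float, float]] | Iterable[MassRange],
    cutoff_date: dt.date | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    check_individual_overlap: bool = True,
) -> DietEstimate:
    """Bootstrap the proportional (by mass) contribution of each prey species.

    Records dated after ``cutoff_date`` are excluded (food eaten after the
    consumer tissue stopped growing cannot appear in it).  Per-individual
    estimates are computed first and their 95% CIs checked for overlap (a
    warning, not a failure, if they do not); all histories are then pooled
    and the pooled bootstrap repeated ``B`` times.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    range_map = _coerce_ranges(ranges)

    kept = [
        r for r in records if cutoff_date is None or r.date <= cutoff_date
    ]
    if not kept:
        raise ValueError(f"no feeding records on or before cutoff {cutoff_date}")
    missing = {r.species for r in kept} - set(range_map)
    if missing:
        raise ValueError(f"no mass range for species: {sorted(missing)}")

    present = {r.species for r in kept}
    sources = tuple(sp for sp in range_map if sp in present)
    k_of = {sp: k for k, sp in enumerate(sources)}
    K = len(sources)

    def expand(recs: Iterable[FeedingRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = np.concatenate([[k_of[r.species]] * r.count for r in recs]).astype(int)
        lo = np.array([range_map[sources[k]].min_kg for k in idx])
        hi = np.array([range_map[sources[k]].max_kg for k in idx])
        return idx, lo, hi

    per_individual = None
    overlap_ok = True
    individuals = sorted({r.individual_id for r in kept})
    if check_individual_overlap and len(individuals) > 1:
        rows = []
        cis = {}
        for ind in individuals:
            idx, lo, hi = expand([r for r in kept if r.individual_id == ind])
            props = _mass_proportions(idx, lo, hi, K, B, rng)
            lo_ci = np.percentile(props, 2.5, axis=0)
            hi_ci = np.percentile(props, 97.5, axis=0)
            cis[ind] = (lo_ci, hi_ci)
            for k, sp in enumerate(sources):
                rows.append(
                    {
                        "individual_id": ind,
                        "source": sp,
                        "mean": props[:, k].mean(),
                        "ci_2.5%": lo_ci[k],
                        "ci_97.5%": hi_ci[k],
                    }
                )
        per_individual = pd.DataFrame(rows)
        for k in range(K):
            max_lo = max(ci[0][k] for ci in cis.values())
            min_hi = min(ci[1][k] for ci in cis.values())
            if max_lo > min_hi:
                overlap_ok = False
        if not overlap_ok:
            warnings.warn(
                "per-individual 95% CIs of diet proportions do not all overlap; "
                "pooling individuals may mask real among-individual variation",
                stacklevel=2,
            )

    idx, lo, hi = expand(kept)
    draws = _mass_proportions(idx, lo, hi, K, B, rng)
    return DietEstimate(
        sources=sources,
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=1) if B > 1 else np.zeros(K),
        ci_low=np.percentile(draws, 2.5, axis=0),
        ci_high=np.percentile(draws, 97.5, axis=0),
        draws=draws,
        per_individual=per_individual,
        individual_cis_overlap=overlap_ok,
    )


def dirichlet_loglike(draws: np.ndarray, alpha: np.ndarray) -> float:
    """Total Dirichlet log-likelihood of simplex draws under alpha."""
    draws = np.asarray(draws, float)
    alpha = np.asarray(alpha, float)
    B = draws.shape[0]
    return float(
        B * (gammaln(alpha.sum()) - gammaln(alpha).sum())
        + ((alpha - 1.0) * np.log(draws).sum(axis=0)).sum()
    )


def _inv_digamma(y: np.ndarray, n_iter: int = 6) -> np.ndarray:
    # Minka's initialisation followed by Newton steps on digamma(x) = y.
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(n_iter):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def fit_dirichlet_mle(
    draws: np.ndarray | pd.DataFrame,
    sources: Sequence[str] | None = None,
    floor: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> DirichletSpec:
    """Maximum-likelihood Dirichlet fit to a (B, K) matrix of proportions.

    Uses the fixed-point iteration
    ``alpha_k <- invdigamma(digamma(sum alpha) + mean log p_k)``, which
    monotonically increases the likelihood, until the per-draw gradient of
    the log-likelihood has max-norm below ``tol``.  Draws are clipped to
    ``floor`` and renormalised first (bootstrap draws can contain exact
    zeros for rare prey, where the Dirichlet density is degenerate).
    """
    if isinstance(draws, pd.DataFrame):
        if sources is None:
            sources = list(draws.columns)
        draws = draws.to_numpy(float)
    draws = np.asarray(draws, float)
    if draws.ndim != 2:
        raise ValueError("draws must be a (B, K) matrix")
    B, K = draws.shape
    if B < K + 1:
        raise ValueError(f"need at least K+1={K + 1} draws, got {B}")
    if sources is None:
        sources = [f"source_{k + 1}" for k in range(K)]

    p = np.clip(draws, floor, None)
    p = p / p.sum(axis=1, keepdims=True)
    mean = p.mean(axis=0)
    var = p.var(axis=0, ddof=1)
    if np.any(var <= 1e-12) or not np.all(np.isfinite(var)):
        raise DirichletFitError(
            "degenerate draws: (near-)zero variance in at least one component"
        )
    logp_bar = np.log(p).mean(axis=0)

    # Moment-matched initialiser: concentration from the first component.
    s0 = mean[0] * (1.0 - mean[0]) / var[0] - 1.0
    alpha = mean * max(s0, 1e-3)

    # Fixed-point steps converge globally but only linearly; once close,
    # Newton steps on the structured Hessian finish to full precision.
    for it in range(max_iter):
        grad = digamma(alpha.sum()) - digamma(alpha) + logp_bar
        if np.max(np.abs(grad)) < tol:
            return DirichletSpec(sources, alpha)
        if it < 10 and np.max(np.abs(grad)) > 1e-3:
            alpha_new = _inv_digamma(digamma(alpha.sum()) + logp_bar)
        else:
            # H = c 11' - diag(q) per draw, with q_k = psi'(alpha_k),
            # c = psi'(sum alpha); invert via the Sherman-Morrison form.
            q = polygamma(1, alpha)
            c = polygamma(1, alpha.sum())
            b = (grad / q).sum() / (1.0 / c - (1.0 / q).sum())
            step = (grad + b) / q
            alpha_new = alpha + step
            # Backtrack if a step overshoots the positive orthant.
            shrink = 0
            while np.any(alpha_new <= 0) and shrink < 60:
                step *= 0.5
                alpha_new = alpha + step
                shrink += 1
        if not np.all(np.isfinite(alpha_new)) or np.any(alpha_new <= 0):
            raise DirichletFitError(
                f"iteration left the parameter space at step {it}: "
                f"alpha={alpha_new}"
            )
        alpha = alpha_new
        if alpha.sum() > 1e12:
            raise DirichletFitError(
                "concentration diverging: draws are effectively degenerate"
            )
    raise DirichletFitError(
        f"no convergence after {max_iter} iterations; "
        f"last alpha={alpha}, gradient max-norm={np.max(np.abs(grad)):.3e}"
    )
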
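"""Bayesian stable-isotope mixing model with a Metropolis-within-Gibbs engine.

The model: the isotope value of consumer i on isotope j is

    X_ij = sum_k p_k (s_jk + c_j) + eps_ij,

with source values s_jk ~ Normal(mu_jk, omega_jk^2), diet proportions
p ~ Dirichlet(alpha), residual eps_ij ~ Normal(0, sigma_j^2), and trophic
discrimination c_j per isotope.  Marginally over the source draws,

    X_ij ~ Normal( sum_k p_k (mu_jk + c_j),
                   sum_k p_k^2 (omega_jk^2 + tau_j^2) + sigma_j^2 ),

where tau_j is the TDF standard deviation when the discrimination offset is
supplied as data rather than sampled.

Two modes share this likelihood:

* ``mode="diet"`` — estimate p.  c_j is fixed at the supplied TDF means and
  its uncertainty tau_j enters the combined variance (the convention of
  SIAR-style mixing models).  Alternatively ``tdf_as_node=True`` samples c_j
  with a Normal(tdf mean, tau^2) prior instead.
* ``mode="tdf"`` — estimate c_j given an informative diet Dirichlet (from a
  controlled feeding study), with vague Uniform(0, 10) priors on c_j.

Sampling is Metropolis-within-Gibbs: p is updated jointly on the
softmax-transformed simplex (with the log-Jacobian sum_k log p_k), and each
c_j and log sigma_j by Gaussian random walk.  Step sizes adapt during
burn-in only and are frozen afterwards, so post-burn-in draws are valid
MCMC.  Convergence is monitored with the classic Gelman-Rubin potential
scale reduction factor (PSRF) on every scalar parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import (
    ConsumerData,
    DirichletSpec,
    SourceDistribution,
    TDFSet,
    source_arrays,
)

__all__ = [
    "MCMCConfig",
    "MixingModel",
    "MixingResults",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
    "ConvergenceWarning",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceWarning(UserWarning):
    """Emitted when a PSRF exceeds the configured threshold."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: lengths, thinning, seed and the PSRF gate.

    Defaults are the full protocol used to derive the reference results:
    three chains, 50,000 burn-in iterations, 15,000 sampling iterations
    thinned by 15, convergence declared at PSRF < 1.1.  ``psrf_action``
    selects what happens when a PSRF breaches the threshold ("warn",
    "error" or "ignore").
    """

    n_chains: int = 3
    burn_in: int = 50_000
    n_samples: int = 15_000
    thin: int = 15
    seed: int | None = None
    psrf_threshold: float = 1.1
    psrf_action: str = "warn"
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.n_samples, self.thin) < 1:
            raise ValueError("all MCMC lengths must be positive")
        if self.n_samples % self.thin != 0:
            raise ValueError(
                f"n_samples ({self.n_samples}) must be a multiple of "
                f"thin ({self.thin})"
            )
        if self.psrf_action not in ("warn", "error", "ignore"):
            raise ValueError(f"unknown psrf_action {self.psrf_action!r}")

    @property
    def draws_per_chain(self) -> int:
        return self.n_samples // self.thin


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    With m chains of n draws, W the mean within-chain variance and B/n the
    variance of the chain means, PSRF = sqrt(((n-1)/n * W + B/n) / W).
    Values near 1 indicate the chains sample a common distribution.
    """
    chains = [np.asarray(c, float).ravel() for c in chains]
    if len(chains) < 2:
        raise ValueError("need at least 2 chains to compute a PSRF")
    n = min(len(c) for c in chains)
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    arr = np.stack([c[:n] for c in chains])
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    return math.sqrt(((n - 1) / n * W + B_over_n) / W)


class MixingModel:
    """Stable-isotope mixing model over K sources and J isotopes.

    Parameters
    ----------
    consumers
        Consumer isotope matrix (I x J).
    sources
        Per-source Normal summaries (mean/SD per isotope).
    mode
        "diet" to estimate proportions given TDFs, "tdf" to estimate
        discrimination factors given a diet Dirichlet.
    tdf
        Discrimination factors.  Required in diet mode; ignored in tdf mode.
    prior
        Dirichlet over diet proportions.  In diet mode this is the prior on
        the estimand (default non-informative, all alpha = 1); in tdf mode
        it is the informative diet distribution and is required.
    tdf_bounds, sigma_bounds
        Uniform prior supports for sampled c_j and for the residual SDs.
    include_residual
        Include the per-isotope residual term eps_ij (default True).
    tdf_as_node
        In diet mode, sample c_j with a Normal(tdf mean, tdf sd^2) prior
        instead of folding the TDF SD into the combined variance.
    """

    def __init__(
        self,
        consumers: ConsumerData,
        sources: Sequence[SourceDistribution],
        mode: str = "diet",
        *,
        tdf: TDFSet | None = None,
        prior: DirichletSpec | None = None,
        tdf_bounds: tuple[float, float] = (0.0, 10.0),
        sigma_bounds: tuple[float, float] = (0.0, 10.0),
        include_residual: bool = True,
        tdf_as_node: bool = False,
    ) -> None:
        if mode not in ("diet", "tdf"):
            raise ValueError(f"mode must be 'diet' or 'tdf', got {mode!r}")
        self.consumers = consumers
        self.sources = tuple(sources)
        self.mode = mode
        self.isotopes = consumers.isotopes
        self.source_names, self.mu, self.omega = source_arrays(
            self.sources, self.isotopes
        )
        self.x = consumers.values  # (I, J)
        self.I, self.J = self.x.shape
        self.K = len(self.sources)

        for lo, hi in (tdf_bounds, sigma_bounds):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"prior bounds must be finite with lo < hi: ({lo}, {hi})")
        self.tdf_bounds = (float(tdf_bounds[0]), float(tdf_bounds[1]))
        self.sigma_bounds = (float(sigma_bounds[0]), float(sigma_bounds[1]))
        self.include_residual = bool(include_residual)
        self.tdf_as_node = bool(tdf_as_node)

        if mode == "diet":
            if tdf is None:
                raise ValueError("diet mode requires a TDFSet")
            if prior is None:
                prior = DirichletSpec(self.source_names, np.ones(self.K))
        else:
            if prior is None:
                raise ValueError("tdf mode requires an informative diet DirichletSpec")
            if tdf_as_node:
                raise ValueError("tdf_as_node applies to diet mode only")
        if tuple(prior.sources) != tuple(self.source_names):
            raise ValueError(
                f"prior sources {prior.sources} do not match model sources "
                f"{self.source_names}"
            )
        self.prior = prior
        self.tdf = tdf

        if tdf is not None:
            self.c_mean = np.array([tdf.mean[iso] for iso in self.isotopes])
            self.tau = np.array([tdf.sd[iso] for iso in self.isotopes])
        else:
            self.c_mean = np.zeros(self.J)
            self.tau = np.zeros(self.J)

        # Is c a sampled parameter, and does tau enter the combined variance?
        self.c_sampled = (mode == "tdf") or self.tdf_as_node
        self.tau_in_variance = (mode == "diet") and not self.tdf_as_node
        if self.include_residual:
            self.n_params = (self.K) + (self.J if self.c_sampled else 0) + self.J
        else:
            self.n_params = self.K + (self.J if self.c_sampled else 0)

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def from_dataframes(
        cls,
        consumers: pd.DataFrame,
        sources: pd.DataFrame,
        mode: str = "diet",
        isotopes: Sequence[str] | None = None,
        **kwargs,
    ) -> "MixingModel":
        """Build a model from tidy tables.

        ``consumers`` needs one isotope column per label; ``sources`` needs
        columns ``species`` plus ``mean_<iso>`` and ``sd_<iso>`` per label.
        """
        from .core import DEFAULT_ISOTOPES

        isotopes = tuple(isotopes or DEFAULT_ISOTOPES)
        cd = ConsumerData.from_dataframe(consumers, isotopes)
        src = [
            SourceDistribution(
                species=str(row["species"]),
                mean={iso: float(row[f"mean_{iso}"]) for iso in isotopes},
                sd={iso: float(row[f"sd_{iso}"]) for iso in isotopes},
                n=int(row["n"]) if "n" in sources.columns else None,
            )
            for _, row in sources.iterrows()
        ]
        return cls(cd, src, mode, **kwargs)

    def with_prior(self, prior: DirichletSpec | Sequence[float]) -> "MixingModel":
        """Clone this model with a different Dirichlet prior on p."""
        if not isinstance(prior, DirichletSpec):
            prior = DirichletSpec(self.source_names, prior)
        return MixingModel(
            self.consumers,
            self.sources,
            self.mode,
            tdf=self.tdf,
            prior=prior,
            tdf_bounds=self.tdf_bounds,
            sigma_bounds=self.sigma_bounds,
            include_residual=self.include_residual,
            tdf_as_node=self.tdf_as_node,
        )

    # ------------------------------------------------------------------ #
    # density

    def log_posterior(self, state: Mapping[str, np.ndarray]) -> float:
        """Log posterior density (up to nothing: all constants included).

        ``state`` maps "p" -> (K,), "sigma" -> (J,) when the residual term
        is on, and "c" -> (J,) when c is sampled.  States outside the
        support return -inf.
        """
        p = np.asarray(state["p"], float)
        if p.shape != (self.K,):
            raise ValueError(f"p must have shape ({self.K},)")
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
            return -math.inf

        if self.c_sampled:
            c = np.asarray(state["c"], float)
            if c.shape != (self.J,):
                raise ValueError(f"c must have shape ({self.J},)")
        else:
            c = self.c_mean

        if self.include_residual:
            sigma = np.asarray(state["sigma"], float)
            if sigma.shape != (self.J,):
                raise ValueError(f"sigma must have shape ({self.J},)")
            lo, hi = self.sigma_bounds
            if np.any(sigma <= lo) or np.any(sigma >= hi):
                return -math.inf
        else:
            sigma = np.zeros(self.J)

        lp = 0.0
        # Dirichlet prior on p.
        a = self.prior.alpha
        lp += float(
            gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * np.log(p)).sum()
        )
        # Priors on c.
        if self.mode == "tdf":
            lo, hi = self.tdf_bounds
            if np.any(c <= lo) or np.any(c >= hi):
                return -math.inf
            lp += -self.J * math.log(hi - lo)
        elif self.tdf_as_node:
            if np.any(self.tau <= 0):
                return -math.inf
            lp += float(
                np.sum(
                    -0.5 * _LOG_2PI
                    - np.log(self.tau)
                    - 0.5 * ((c - self.c_mean) / self.tau) ** 2
                )
            )
        # Uniform prior on sigma.
        if self.include_residual:
            lo, hi = self.sigma_bounds
            lp += -self.J * math.log(hi - lo)

        tau_var = (self.tau**2)[:, None] if self.tau_in_variance else 0.0
        mean = self.mu @ p + c * p.sum()  # (J,)
        var = (self.omega**2 + tau_var) @ (p**2) + sigma**2
        if np.any(var <= 0):
            return -math.inf
        resid = self.x - mean  # (I, J)
        lp += float(
            np.sum(-0.5 * (_LOG_2PI + np.log(var)) - resid**2 / (2.0 * var))
        )
        return lp

    # ------------------------------------------------------------------ #
    # sampler internals

    def _suff_stats(self) -> tuple[np.ndarray, np.ndarray]:
        xbar = self.x.mean(axis=0)
        ss = ((self.x - xbar) ** 2).sum(axis=0)
        return xbar, ss

    def _make_transformed_logpost(self):
        """Fast unnormalised log posterior on (z, c, u = log sigma).

        Uses per-isotope sufficient statistics; drops constants that cancel
        in Metropolis ratios.  Consistency with :meth:`log_posterior` (up to
        the dropped constants and Jacobians) is covered by the test suite.
        """
        xbar, ss = self._suff_stats()
        mu = self.mu
        om2 = self.omega**2 + (
            (self.tau**2)[:, None] if self.tau_in_variance else 0.0
        )
        alpha = self.prior.alpha
        I = self.I
        J = self.J
        c_sampled = self.c_sampled
        tdf_mode = self.mode == "tdf"
        c_lo, c_hi = self.tdf_bounds
        node = self.tdf_as_node
        c_mean, tau = self.c_mean, self.tau
        include_sigma = self.include_residual
        log_sig_hi = math.log(self.sigma_bounds[1]) if include_sigma else None
        sig_lo = self.sigma_bounds[0]

        def f(z: np.ndarray, c: np.ndarray | None, u: np.ndarray | None) -> float:
            w = np.empty(z.size + 1)
            w[0] = 0.0
            w[1:] = z
            w -= w.max()
            ew = np.exp(w)
            p = ew / ew.sum()
            logp = np.log(p)
            # Dirichlet prior + softmax Jacobian: sum_k alpha_k log p_k.
            lp = float(alpha @ logp)

            cc = c if c_sampled else c_mean
            if tdf_mode:
                if np.any(cc <= c_lo) or np.any(cc >= c_hi):
                    return -math.inf
            elif node:
                lp += float(np.sum(-0.5 * ((cc - c_mean) / tau) ** 2))

            if include_sigma:
                if np.any(u >= log_sig_hi):
                    return -math.inf
                sig = np.exp(u)
                if sig_lo > 0.0 and np.any(sig <= sig_lo):
                    return -math.inf
                lp += float(u.sum())  # Jacobian of sigma = exp(u)
                sig2 = sig**2
            else:
                sig2 = 0.0

            mean = mu @ p + cc
            var = om2 @ (p**2) + sig2
            if np.any(var <= 0):
                return -math.inf
            lp += float(
                np.sum(-0.5 * I * np.log(var) - (ss + I * (xbar - mean) ** 2) / (2.0 * var))
            )
            return lp

        return f

    def _initial_state(
        self, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        # p at the prior mean with overdispersed jitter on the softmax scale.
        p0 = self.prior.mean
        z = np.log(p0[1:] / p0[0]) + rng.normal(0.0, 0.5, self.K - 1)
        c = None
        if self.c_sampled:
            if self.mode == "tdf":
                lo, hi = self.tdf_bounds
                mid = 0.5 * (lo + hi)
                span = hi - lo
                c = np.clip(
                    mid + rng.normal(0.0, 0.1 * span, self.J),
                    lo + 1e-3 * span,
                    hi - 1e-3 * span,
                )
            else:
                c = self.c_mean + rng.normal(0.0, 1.0, self.J) * np.maximum(
                    self.tau, 1e-3
                )
        u = None
        if self.include_residual:
            u = math.log(0.5) + rng.normal(0.0, 0.3, self.J)
        return z, c, u

    def _run_chain(self, rng: np.random.Generator, cfg: MCMCConfig):
        logpost = self._make_transformed_logpost()
        z, c, u = self._initial_state(rng)
        lp = logpost(z, c, u)
        if not math.isfinite(lp):
            raise RuntimeError(
                "non-finite log posterior at initialization; check that the "
                "data are inside the model support"
            )

        blocks: list[str] = ["z"]
        if self.c_sampled:
            blocks += [f"c{j}" for j in range(self.J)]
        if self.include_residual:
            blocks += [f"u{j}" for j in range(self.J)]
        log_scale = {b: math.log(0.3) for b in blocks}
        accepted = {b: 0 for b in blocks}
        target = {b: (0.3 if b == "z" else 0.44) for b in blocks}

        n_keep = cfg.draws_per_chain
        p_out = np.empty((n_keep, self.K))
        c_out = np.empty((n_keep, self.J)) if self.c_sampled else None
        s_out = np.empty((n_keep, self.J)) if self.include_residual else None
        kept = 0

        total = cfg.burn_in + cfg.n_samples
        for it in range(total):
            adapting = it < cfg.burn_in
            for b in blocks:
                step = math.exp(log_scale[b])
                if b == "z":
                    prop_z = z + step * rng.standard_normal(self.K - 1)
                    lp_new = logpost(prop_z, c, u)
                    if lp_new - lp > -rng.exponential():
                        z, lp = prop_z, lp_new
                        accepted[b] += 1
                elif b.startswith("c"):
                    j = int(b[1:])
                    prop_c = c.copy()
                    prop_c[j] += step * rng.standard_normal()
                    lp_new = logpost(z, prop_c, u)
                    if lp_new - lp > -rng.exponential():
                        c, lp = prop_c, lp_new
                        accepted[b] += 1
                else:
                    j = int(b[1:])
                    prop_u = u.copy()
                    prop_u[j] += step * rng.standard_normal()
                    lp_new = logpost(z, c, prop_u)
                    if lp_new - lp > -rng.exponential():
                        u, lp = prop_u, lp_new
                        accepted[b] += 1
            if adapting and (it + 1) % cfg.adapt_interval == 0:
                for b in blocks:
                    rate = accepted[b] / cfg.adapt_interval
                    log_scale[b] += 0.66 * (rate - target[b])
                    log_scale[b] = min(max(log_scale[b], math.log(1e-4)), math.log(10.0))
                    accepted[b] = 0
            if not adapting:
                k = it - cfg.burn_in + 1
                if k % cfg.thin == 0:
                    w = np.concatenate([[0.0], z])
                    w -= w.max()
                    ew = np.exp(w)
                    p_out[kept] = ew / ew.sum()
                    if c_out is not None:
                        c_out[kept] = c
                    if s_out is not None:
                        s_out[kept] = np.exp(u)
                    kept += 1
        return p_out, c_out, s_out

    # ------------------------------------------------------------------ #

    def fit(
        self, config: MCMCConfig | None = None, seed: int | None = None
    ) -> "MixingResults":
        """Run the MCMC and return a :class:`MixingResults`.

        ``seed`` overrides ``config.seed``; per-chain generators are spawned
        from one SeedSequence so runs are exactly reproducible.
        """
        cfg = config or MCMCConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
        chain_states = [
            self._run_chain(np.random.default_rng(s), cfg)
            for s in ss.spawn(cfg.n_chains)
        ]
        results = MixingResults(self, cfg, chain_states)
        results._check_convergence()
        return results


class MixingResults:
    """Posterior draws, convergence diagnostics and summaries of a fit."""

    def __init__(
        self,
        model: MixingModel,
        config: MCMCConfig,
        chain_states: Sequence[tuple],
    ) -> None:
        self.model = model
        self.config = config
        self._chains = list(chain_states)
        n_keep = config.draws_per_chain
        self.chain_ids = np.repeat(np.arange(len(self._chains)), n_keep)
        self.p_draws = np.vstack([ch[0] for ch in self._chains])
        self.c_draws = (
            np.vstack([ch[1] for ch in self._chains])
            if self._chains[0][1] is not None
            else None
        )
        self.sigma_draws = (
            np.vstack([ch[2] for ch in self._chains])
            if self._chains[0][2] is not None
            else None
        )
        self._psrf: dict[str, float] | None = None

    # -- naming ---------------------------------------------------------

    @property
    def parameter_names(self) -> list[str]:
        names = [f"p[{s}]" for s in self.model.source_names]
        if self.c_draws is not None:
            names += [f"c[{iso}]" for iso in self.model.isotopes]
        if self.sigma_draws is not None:
            names += [f"sigma[{iso}]" for iso in self.model.isotopes]
        return names

    def _scalar_chains(self) -> dict[str, list[np.ndarray]]:
        out: dict[str, list[np.ndarray]] = {}
        for k, s in enumerate(self.model.source_names):
            out[f"p[{s}]"] = [ch[0][:, k] for ch in self._chains]
        if self.c_draws is not None:
            for j, iso in enumerate(self.model.isotopes):
                out[f"c[{iso}]"] = [ch[1][:, j] for ch in self._chains]
        if self.sigma_draws is not None:
            for j, iso in enumerate(self.model.isotopes):
                out[f"sigma[{iso}]"] = [ch[2][:, j] for ch in self._chains]
        return out

    def _draw_matrix(self) -> tuple[np.ndarray, list[str]]:
        cols = [self.p_draws]
        if self.c_draws is not None:
            cols.append(self.c_draws)
        if self.sigma_draws is not None:
            cols.append(self.sigma_draws)
        return np.hstack(cols), self.parameter_names

    # -- diagnostics ----------------------------------------------------

    @property
    def psrf(self) -> dict[str, float]:
        """Gelman-Rubin PSRF per monitored scalar."""
        if self._psrf is None:
            self._psrf = {
                name: gelman_rubin(chains)
                for name, chains in self._scalar_chains().items()
            }
        return self._psrf

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values())

    def _check_convergence(self) -> None:
        action = self.config.psrf_action
        if action == "ignore":
            return
        bad = {
            k: v for k, v in self.psrf.items() if v >= self.config.psrf_threshold
        }
        if bad:
            msg = (
                f"PSRF >= {self.config.psrf_threshold} for "
                + ", ".join(f"{k}: {v:.3f}" for k, v in bad.items())
                + "; increase burn_in/n_samples"
            )
            if action == "error":
                raise RuntimeError(msg)
            warnings.warn(msg, ConvergenceWarning, stacklevel=3)

    # -- summaries ------------------------------------------------------

    @property
    def posterior_mean(self) -> dict[str, float]:
        draws, names = self._draw_matrix()
        return dict(zip(names, draws.mean(axis=0)))

    def p_mean(self) -> dict[str, float]:
        return dict(zip(self.model.source_names, self.p_draws.mean(axis=0)))

    def c_mean(self) -> dict[str, float]:
        if self.c_draws is None:
            raise ValueError("this fit has no sampled discrimination factors")
        return dict(zip(self.model.isotopes, self.c_draws.mean(axis=0)))

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval and PSRF per parameter."""
        draws, names = self._draw_matrix()
        return pd.DataFrame(
            {
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "ci_2.5%": np.percentile(draws, 2.5, axis=0),
                "ci_97.5%": np.percentile(draws, 97.5, axis=0),
                "psrf": [self.psrf[n] for n in names],
            },
            index=pd.Index(names, name="parameter"),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        draws, names = self._draw_matrix()
        n_keep = self.config.draws_per_chain
        rows = {
            "chain": np.repeat(self.chain_ids, len(names)),
            "iteration": np.repeat(
                np.tile(np.arange(n_keep), len(self._chains)), len(names)
            ),
            "parameter": np.tile(names, draws.shape[0]),
            "value": draws.ravel(),
        }
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MixingResults(mode={self.model.mode!r}, "
            f"draws={self.p_draws.shape[0]}, max_psrf={self.max_psrf:.3f})"
        )


def log_posterior(model: MixingModel, state: Mapping[str, np.ndarray]) -> float:
    """Module-level alias for :meth:`MixingModel.log_posterior`."""
    return model.log_posterior(state)


def sample_posterior(
    model: MixingModel, config: MCMCConfig | None = None, seed: int | None = None
) -> MixingResults:
    """Module-level alias for :meth:`MixingModel.fit`."""
    return model.fit(config, seed=seed)
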
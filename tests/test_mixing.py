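"""Mixing-model density, sampler contracts and convergence diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from tdfmix import (
    ConsumerData,
    DirichletSpec,
    MCMCConfig,
    MixingModel,
    gelman_rubin,
    log_posterior,
)
from tdfmix.core import SourceDistribution, TDFSet
from tdfmix.datasets import CAPTIVE_SOURCES, DIET_ALPHA, SOURCE_NAMES, WOLF_TDF


def brute_force_log_posterior(model, state):
    """Straight-from-the-equations density, coded independently: explicit
    per-observation loops and scipy.stats distributions throughout."""
    p = np.asarray(state["p"], float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
        return -math.inf
    c = np.asarray(state["c"], float) if model.c_sampled else model.c_mean
    sigma = (
        np.asarray(state["sigma"], float)
        if model.include_residual
        else np.zeros(model.J)
    )

    lp = stats.dirichlet.logpdf(p / p.sum(), model.prior.alpha)
    if model.mode == "tdf":
        lo, hi = model.tdf_bounds
        for j in range(model.J):
            v = stats.uniform.logpdf(c[j], lo, hi - lo)
            if not np.isfinite(v):
                return -math.inf
            lp += v
    elif model.tdf_as_node:
        for j in range(model.J):
            lp += stats.norm.logpdf(c[j], model.c_mean[j], model.tau[j])
    if model.include_residual:
        lo, hi = model.sigma_bounds
        for j in range(model.J):
            v = stats.uniform.logpdf(sigma[j], lo, hi - lo)
            if not np.isfinite(v):
                return -math.inf
            lp += v

    for i in range(model.I):
        for j in range(model.J):
            mean = sum(p[k] * (model.mu[j, k] + c[j]) for k in range(model.K))
            var = sum(
                p[k] ** 2
                * (model.omega[j, k] ** 2 + (model.tau[j] ** 2 if model.tau_in_variance else 0.0))
                for k in range(model.K)
            ) + sigma[j] ** 2
            lp += stats.norm.logpdf(model.x[i, j], mean, math.sqrt(var))
    return lp


def _random_state(model, rng):
    p = rng.dirichlet(np.ones(model.K))
    state = {"p": p}
    if model.c_sampled:
        lo, hi = model.tdf_bounds
        state["c"] = rng.uniform(lo + 0.1, hi - 0.1, model.J)
    if model.include_residual:
        state["sigma"] = rng.uniform(0.05, 2.0, model.J)
    return state


def _models(wolf_consumers):
    cons = wolf_consumers(seed=4)
    return [
        MixingModel(cons, CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF),
        MixingModel(cons, CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF, prior=DIET_ALPHA),
        MixingModel(cons, CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF, tdf_as_node=True),
        MixingModel(cons, CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA),
        MixingModel(
            cons, CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA, include_residual=False
        ),
    ]


class TestLogPosterior:
    def test_matches_independent_evaluator_on_random_states(self, wolf_consumers, rng):
        for model in _models(wolf_consumers):
            for _ in range(20):
                state = _random_state(model, rng)
                assert model.log_posterior(state) == pytest.approx(
                    brute_force_log_posterior(model, state), abs=1e-10
                )

    def test_out_of_support_states_are_minus_inf(self, wolf_consumers):
        model = MixingModel(
            wolf_consumers(seed=4), CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA
        )
        base = {"p": np.array([0.9, 0.05, 0.05]), "c": np.array([2.0, 3.0]),
                "sigma": np.array([0.5, 0.5])}
        assert np.isfinite(model.log_posterior(base))
        for key, bad in [
            ("p", np.array([0.9, 0.2, -0.1])),
            ("p", np.array([0.5, 0.3, 0.3])),
            ("c", np.array([2.0, 11.0])),
            ("sigma", np.array([0.5, -0.1])),
            ("sigma", np.array([0.5, 10.5])),
        ]:
            state = dict(base, **{key: bad})
            assert model.log_posterior(state) == -math.inf

    def test_simplex_vertex_reduces_to_single_source(self, wolf_consumers):
        # With p at a vertex the mixture mean is mu_j1 + c_j; the density
        # equals a hand-built single-source Normal model there.
        model = MixingModel(
            wolf_consumers(seed=4), CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF,
            include_residual=True,
        )
        eps = 1e-9
        p = np.array([1.0 - 2 * eps, eps, eps])
        sigma = np.array([0.5, 0.4])
        lp = model.log_posterior({"p": p, "sigma": sigma})
        mean = model.mu[:, 0] + model.c_mean
        var = model.omega[:, 0] ** 2 + model.tau**2 + sigma**2
        ll = stats.norm.logpdf(model.x, mean, np.sqrt(var)).sum()
        prior = stats.dirichlet.logpdf(p, np.ones(3)) - 2 * math.log(10.0)
        assert lp == pytest.approx(ll + prior, abs=1e-3)

    def test_degenerate_exact_fit_peaks_at_true_offset(self):
        # Single source, zero spread: scanning c, the density is maximal at
        # the offset that reproduces the observations exactly.
        src = [SourceDistribution("s", {"d13C": -22.0, "d15N": 4.0},
                                  {"d13C": 0.0, "d15N": 0.0})]
        x = np.array([[-20.03, 7.04]] * 5)
        cons = ConsumerData(x)
        model = MixingModel(
            cons, src, "tdf",
            prior=DirichletSpec(("s",), [1.0]), include_residual=True,
        )
        sigma = np.array([0.05, 0.05])
        grid = np.linspace(0.5, 5.0, 91)
        best_c13 = max(
            grid,
            key=lambda c: model.log_posterior(
                {"p": [1.0], "c": [c, 3.04], "sigma": sigma}
            ),
        )
        assert best_c13 == pytest.approx(1.97, abs=0.03)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self, rng):
        chain = rng.normal(size=500)
        assert gelman_rubin([chain, chain.copy(), chain.copy()]) <= 1.0 + 1e-6

    def test_separated_chains_match_hand_formula(self, rng):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(5.0, 1.0, 1000)
        psrf = gelman_rubin([a, b])
        n = 1000
        W = (a.var(ddof=1) + b.var(ddof=1)) / 2
        B_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert psrf == pytest.approx(expected, abs=1e-12)
        assert psrf > 1.1  # grossly unconverged

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin([rng.normal(size=100)])

    def test_agrees_with_arviz_on_well_mixed_chains(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(size=(4, 2000))
        ours = gelman_rubin(list(chains))
        theirs = float(arviz.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSampler:
    def test_determinism_under_fixed_seed(self, wolf_consumers, fast_mcmc):
        model = MixingModel(
            wolf_consumers(seed=2), CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA
        )
        r1 = model.fit(fast_mcmc, seed=99)
        r2 = model.fit(fast_mcmc, seed=99)
        assert np.array_equal(r1.p_draws, r2.p_draws)
        assert np.array_equal(r1.c_draws, r2.c_draws)
        assert np.array_equal(r1.sigma_draws, r2.sigma_draws)
        r3 = model.fit(fast_mcmc, seed=100)
        assert not np.array_equal(r1.p_draws, r3.p_draws)

    def test_draws_respect_support(self, wolf_consumers, fast_mcmc):
        model = MixingModel(
            wolf_consumers(seed=2), CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA
        )
        res = model.fit(fast_mcmc, seed=5)
        assert np.allclose(res.p_draws.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.p_draws > 0)
        lo, hi = model.tdf_bounds
        assert np.all((res.c_draws > lo) & (res.c_draws < hi))
        slo, shi = model.sigma_bounds
        assert np.all((res.sigma_draws > slo) & (res.sigma_draws < shi))
        assert res.p_draws.shape[0] == fast_mcmc.n_chains * fast_mcmc.draws_per_chain

    def test_point_mass_diet_concentrates_c_at_shifted_mean(self, fast_mcmc):
        # Point-mass diet at source 1, zero source SD and tiny residual:
        # the posterior for c_j concentrates at mean(X_j) - mu_j1.
        src = [
            SourceDistribution("a", {"d13C": -22.0, "d15N": 4.0},
                               {"d13C": 0.0, "d15N": 0.0}),
            SourceDistribution("b", {"d13C": -30.0, "d15N": 1.0},
                               {"d13C": 0.0, "d15N": 0.0}),
        ]
        rng = np.random.default_rng(0)
        x = np.array([-20.0, 7.0]) + rng.normal(0, 0.02, (30, 2))
        model = MixingModel(
            ConsumerData(x), src, "tdf",
            prior=DirichletSpec(("a", "b"), [1e5, 1e-2]),
        )
        res = model.fit(fast_mcmc, seed=3)
        target = x.mean(axis=0) - np.array([-22.0, 4.0])
        c_mean = np.array(list(res.c_mean().values()))
        assert c_mean == pytest.approx(target, abs=0.05)

    def test_diet_posterior_permutation_equivariant(self, wolf_consumers, medium_mcmc):
        cons = wolf_consumers(seed=6)
        perm = [2, 0, 1]
        m1 = MixingModel(cons, CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF)
        m2 = MixingModel(
            cons, [CAPTIVE_SOURCES[i] for i in perm], "diet", tdf=WOLF_TDF
        )
        p1 = m1.fit(medium_mcmc, seed=11).p_mean()
        p2 = m2.fit(medium_mcmc, seed=12).p_mean()
        for name in SOURCE_NAMES:
            assert p1[name] == pytest.approx(p2[name], abs=0.04)

    def test_posterior_sd_shrinks_with_sample_size(self, medium_mcmc):
        # Monotone in expectation; averaged over 5 seeds.
        from tdfmix.synthetic import SyntheticScenario, generate_isotope_dataset

        sds = {}
        for I in (10, 80):
            acc = []
            for seed in range(5):
                scen = SyntheticScenario(
                    sources=CAPTIVE_SOURCES,
                    proportions=[0.6, 0.25, 0.15],
                    tdf=WOLF_TDF,
                    n_consumers=I,
                    residual_sd={"d13C": 0.3, "d15N": 0.2},
                    seed=seed,
                )
                cons, _ = generate_isotope_dataset(scen)
                res = MixingModel(cons, CAPTIVE_SOURCES, "diet", tdf=WOLF_TDF).fit(
                    medium_mcmc, seed=seed
                )
                acc.append(res.p_draws.std(axis=0, ddof=1).mean())
            sds[I] = np.mean(acc)
        assert sds[80] < sds[10]

    def test_summary_table_shape(self, wolf_consumers, fast_mcmc):
        model = MixingModel(
            wolf_consumers(seed=2), CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA
        )
        res = model.fit(fast_mcmc, seed=1)
        table = res.summary()
        assert list(table.columns) == ["mean", "sd", "ci_2.5%", "ci_97.5%", "psrf"]
        assert set(table.index) == {
            "p[deer]", "p[beaver]", "p[goose]", "c[d13C]", "c[d15N]",
            "sigma[d13C]", "sigma[d15N]",
        }
        long = res.to_frame()
        assert set(long.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(long) == 7 * res.p_draws.shape[0]

    def test_psrf_error_action(self, wolf_consumers):
        model = MixingModel(
            wolf_consumers(seed=2), CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA
        )
        cfg = MCMCConfig(
            burn_in=1, n_samples=20, thin=1, psrf_action="error",
            psrf_threshold=1.0001,
        )
        with pytest.raises(RuntimeError, match="PSRF"):
            model.fit(cfg, seed=0)

    def test_residual_term_barely_moves_tdf_estimates(self, wolf_consumers, medium_mcmc):
        # The residual component absorbs little here: estimates with and
        # without it agree closely.
        cons = wolf_consumers(seed=8)
        with_eps = MixingModel(cons, CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA).fit(
            medium_mcmc, seed=21
        )
        without = MixingModel(
            cons, CAPTIVE_SOURCES, "tdf", prior=DIET_ALPHA, include_residual=False
        ).fit(medium_mcmc, seed=22)
        for iso in ("d13C", "d15N"):
            assert with_eps.c_mean()[iso] == pytest.approx(
                without.c_mean()[iso], abs=0.15
            )

    def test_mode_validation(self, wolf_consumers):
        cons = wolf_consumers(seed=2)
        with pytest.raises(ValueError, match="TDFSet"):
            MixingModel(cons, CAPTIVE_SOURCES, "diet")
        with pytest.raises(ValueError, match="Dirichlet"):
            MixingModel(cons, CAPTIVE_SOURCES, "tdf")
        with pytest.raises(ValueError, match="mode"):
            MixingModel(cons, CAPTIVE_SOURCES, "banana", tdf=WOLF_TDF)
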
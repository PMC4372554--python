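"""Equivalence testing and the minimum-informative-prior search."""

import numpy as np
import pytest

from tdfmix import (
    DirichletSpec,
    MCMCConfig,
    MixingModel,
    candidate_schedule,
    equivalence_test,
    minimum_informative_prior,
)
from tdfmix.datasets import CAPTIVE_SOURCES, DIET_ALPHA, WOLF_TDF
from tdfmix.priors import PriorSearchError


class TestEquivalenceTest:
    def test_self_comparison_passes(self, diet_alpha, rng):
        post = diet_alpha.sample(2000, rng)
        res = equivalence_test(post, diet_alpha, seed=rng)
        assert res.passed
        assert np.all(res.ci_low <= res.ci_high)

    def test_self_comparison_pass_rate_exceeds_95_percent(self, diet_alpha):
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            post = diet_alpha.sample(1500, rng)
            if equivalence_test(post, diet_alpha, seed=rng).passed:
                passes += 1
        assert passes >= 95

    def test_separated_distributions_fail_on_every_source(self, rng):
        ref = DirichletSpec(("a", "b", "c"), [300.0, 300.0, 300.0])
        post = rng.dirichlet([5000.0, 1e-2, 1e-2], size=1500)
        res = equivalence_test(post, ref, seed=rng)
        assert not res.passed
        assert np.all((res.ci_low > 0) | (res.ci_high < 0))

    def test_flat_prior_posterior_differs_from_captive_diet(
        self, wolf_consumers, fox_tdf, diet_alpha, medium_mcmc
    ):
        # Non-informative prior with borrowed fox TDFs: the diet posterior
        # is distinguishable from the controlled-feeding reference.
        model = MixingModel(
            wolf_consumers(seed=1), CAPTIVE_SOURCES, "diet", tdf=fox_tdf
        )
        res = model.fit(medium_mcmc, seed=1)
        assert not equivalence_test(res, diet_alpha, seed=0).passed

    def test_source_name_mismatch_rejected(self, diet_alpha, rng):
        post = rng.dirichlet([1, 1, 1], size=1200)
        bad_ref = DirichletSpec(("x", "y", "z"), [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="required"):
            equivalence_test(post, np.asarray(post), seed=0)
        res = equivalence_test(post, bad_ref, sources=("x", "y", "z"), seed=0)
        assert res.sources == ("x", "y", "z")

    def test_insufficient_draws_rejected(self, diet_alpha, rng):
        post = diet_alpha.sample(500, rng)
        with pytest.raises(ValueError, match="500"):
            equivalence_test(post, diet_alpha, n_draws=1000, seed=0)


class TestCandidateSchedule:
    def test_phase1_cap_matches_rounded_top_ratio(self, diet_alpha):
        # means (0.941, 0.020, 0.039): deer/goose ratio rounds to 24
        schedule = candidate_schedule(diet_alpha.mean)
        phase1 = [a for a in schedule if a[1] == 1.0 and a[2] == 1.0]
        assert [a[0] for a in phase1] == list(range(1, 25))
        # later phases climb towards the full mean ratios
        assert any(a[0] > 24 for a in schedule)

    def test_two_source_symmetric_goes_straight_to_scaling(self):
        schedule = candidate_schedule([0.5, 0.5], max_scale=4)
        assert [list(a) for a in schedule] == [[1, 1], [2, 2], [3, 3], [4, 4]]

    def test_deterministic(self, diet_alpha):
        s1 = candidate_schedule(diet_alpha.mean)
        s2 = candidate_schedule(diet_alpha.mean)
        assert all(np.array_equal(a, b) for a, b in zip(s1, s2))
        assert len(s1) == len(s2)

    def test_single_source_rejected(self):
        with pytest.raises(ValueError, match="2 sources"):
            candidate_schedule([1.0])

    def test_precision_is_nondecreasing(self, diet_alpha):
        totals = [a.sum() for a in candidate_schedule(diet_alpha.mean)]
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestMinimumInformativePrior:
    def test_immediate_pass_returns_flat_prior(self, diet_alpha, fast_mcmc, rng):
        # Consumers drawn so informative that alpha=(1,1,1) already passes:
        # near-degenerate sources and a huge consumer sample pinned at the
        # reference mixture mean.
        from tdfmix.core import ConsumerData, SourceDistribution, TDFSet

        src = [
            SourceDistribution("deer", {"d13C": -22.0, "d15N": 4.2},
                               {"d13C": 0.05, "d15N": 0.05}),
            SourceDistribution("beaver", {"d13C": -24.8, "d15N": 2.3},
                               {"d13C": 0.05, "d15N": 0.05}),
            SourceDistribution("goose", {"d13C": -25.6, "d15N": 4.0},
                               {"d13C": 0.05, "d15N": 0.05}),
        ]
        tdf = TDFSet("t", {"d13C": 2.0, "d15N": 3.0}, {"d13C": 0.01, "d15N": 0.01})
        p_ref = diet_alpha.mean
        mu = np.array([[s.mean["d13C"] for s in src], [s.mean["d15N"] for s in src]])
        mean = mu @ p_ref + np.array([2.0, 3.0])
        x = mean + rng.normal(0, 0.02, (60, 2))
        model = MixingModel(ConsumerData(x), src, "diet", tdf=tdf)
        trace = minimum_informative_prior(
            model, diet_alpha, fast_mcmc, seed=1
        )
        assert np.array_equal(trace.selected.alpha, [1.0, 1.0, 1.0])
        assert len(trace.candidates) == 1

    def test_selected_candidate_is_first_passing(
        self, wolf_consumers, wolf_tdf, diet_alpha
    ):
        cfg = MCMCConfig(burn_in=3000, n_samples=2000, thin=2, psrf_action="ignore")
        model = MixingModel(
            wolf_consumers(seed=1), CAPTIVE_SOURCES, "diet", tdf=wolf_tdf
        )
        trace = minimum_informative_prior(model, diet_alpha, cfg, seed=7)
        assert trace.selected is not None
        *previous, last = trace.candidates
        assert last[1].passed
        assert np.array_equal(last[0], trace.selected.alpha)
        assert all(not res.passed for _, res in previous)

    def test_exhausted_schedule_raises_with_trace(
        self, wolf_consumers, fox_tdf, diet_alpha, fast_mcmc
    ):
        model = MixingModel(
            wolf_consumers(seed=1), CAPTIVE_SOURCES, "diet", tdf=fox_tdf
        )
        short = [np.array([1.0, 1.0, 1.0]), np.array([2.0, 1.0, 1.0])]
        with pytest.raises(PriorSearchError) as err:
            minimum_informative_prior(
                model, diet_alpha, fast_mcmc, seed=3, schedule=short
            )
        assert len(err.value.trace.candidates) == 2

    def test_requires_diet_mode(self, wolf_consumers, diet_alpha, fast_mcmc):
        model = MixingModel(
            wolf_consumers(seed=1), CAPTIVE_SOURCES, "tdf", prior=diet_alpha
        )
        with pytest.raises(ValueError, match="diet-mode"):
            minimum_informative_prior(model, diet_alpha, fast_mcmc, seed=0)
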
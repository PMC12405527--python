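"""Null and refined colony models against exact and agent-based oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mutburst import colony as cs
from mutburst.fluctuation import InputError

from _oracle import simulate_agent


def _chi2_same_distribution(x, y, edges):
    """Chi-square test that two count samples share one distribution."""
    hx = np.histogram(x, bins=edges)[0]
    hy = np.histogram(y, bins=edges)[0]
    keep = (hx + hy) > 0
    table = np.vstack([hx[keep], hy[keep]])
    return stats.chi2_contingency(table).pvalue


class TestSimulateNull:
    def test_no_mutation_channels(self):
        r = cs.simulate_null(cs.RateSet(0.0, 0.0), G=5, seed=1)
        assert r.wt == 32 and r.doubles == 0
        assert r.m1_only == r.m2_only == 0

    def test_deterministic_mutating_daughter(self):
        r = cs.simulate_null(cs.RateSet(1.0, 0.0), G=1, seed=1)
        assert (r.wt, r.m1_only) == (1, 1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mu1=st.floats(0.0, 0.3),
        mu2=st.floats(0.0, 0.3),
        G=st.integers(1, 8),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_count_conservation(self, mu1, mu2, G, seed):
        """Class counts always sum to 2^G: exponential growth, no death."""
        batch = cs.simulate_null_batch(cs.RateSet(mu1, mu2), G, 16, seed)
        assert np.all(batch.total == 2**G)

    def test_expected_event_count(self):
        """Mean mutation events per channel equal mu*(2^G - 1)."""
        mu1, mu2, G, n = 3e-3, 1e-3, 10, 20_000
        batch = cs.simulate_null_batch(cs.RateSet(mu1, mu2), G, n, seed=5)
        df = batch.to_dataframe()
        # simultaneous double events are counted directly per realization
        exp_sim = mu1 * mu2 * (2**G - 1)
        got_sim = batch.sim_events.mean()
        se_sim = batch.sim_events.std(ddof=1) / np.sqrt(n)
        assert abs(got_sim - exp_sim) <= 3 * max(se_sim, 1e-9) + 1e-6
        # single-mutant events are Poisson-thin: infer from mutant-free
        # colonies, P(no ch1 event) = (1 - mu1)^(2^G - 1)
        p_none = np.mean((df["m1_only"] + df["double_seq"]
                          + df["double_sim"]) == 0)
        expect_none = (1 - mu1) ** (2**G - 1)
        se = np.sqrt(expect_none * (1 - expect_none) / n)
        assert abs(p_none - expect_none) <= 4 * se + 1e-4

    def test_jackpot_overdispersion(self):
        """Final single-mutant counts are over-dispersed vs Poisson."""
        G, mu = 16, 2e-5  # mu * 2^G ~ 1.3
        batch = cs.simulate_null_batch(cs.RateSet(mu, 0.0), G, 4000, seed=9)
        counts = batch.counts["m1_only"]
        assert counts.var() / counts.mean() > 2

    def test_agent_based_oracle_equivalence(self):
        """Distribution of final single-mutant counts matches a cell-by-cell
        simulator (chi-square p > 0.01) at G = 6, inflated rates."""
        mu1, mu2, G, n = 0.05, 0.02, 6, 2000
        batch = cs.simulate_null_batch(cs.RateSet(mu1, mu2), G, n, seed=31)
        rng = np.random.default_rng(32)
        oracle = np.array([
            simulate_agent(mu1, mu2, G, rng)["m1_only"] for _ in range(n)
        ])
        edges = np.arange(0, 22).tolist() + [np.inf]
        p = _chi2_same_distribution(batch.counts["m1_only"], oracle, edges)
        assert p > 0.01

    def test_seed_determinism(self):
        a = cs.simulate_null_batch(cs.RateSet(1e-3, 1e-4), 10, 50, seed=77)
        b = cs.simulate_null_batch(cs.RateSet(1e-3, 1e-4), 10, 50, seed=77)
        c = cs.simulate_null_batch(cs.RateSet(1e-3, 1e-4), 10, 50, seed=78)
        assert a.to_dataframe().equals(b.to_dataframe())
        assert not a.to_dataframe().equals(c.to_dataframe())

    def test_overflow_guard(self):
        with pytest.raises(InputError):
            cs.simulate_null_batch(cs.RateSet(0.0, 0.0), 63, 1, seed=0)


class TestSimulateRefined:
    def test_strength_one_is_the_null_model(self):
        """F = 1 leaves the final-count distribution statistically
        indistinguishable from the null model."""
        rates, G, n = cs.RateSet(2e-3, 1e-3), 8, 2000
        ref = cs.simulate_refined_batch(
            rates, G, cs.MutatorParams(4, 1.0, 3), n, seed=41)
        null = cs.simulate_null_batch(rates, G, n, seed=42)
        edges = [0, 1, 2, 3, 5, 9, 17, np.inf]
        p = _chi2_same_distribution(ref.counts["m1_only"],
                                    null.counts["m1_only"], edges)
        assert p > 0.01
        assert np.all(ref.total == 2**G)

    def test_whole_population_episode_is_a_rate_change(self):
        """S = 2^g0 covering the rest of growth equals the null model with
        rates multiplied by F from g0 onward (agent-based oracle)."""
        mu1, F, G, g0 = 0.01, 10.0, 6, 2
        n = 2000
        ref = cs.simulate_refined_batch(
            cs.RateSet(mu1, 0.0), G,
            cs.MutatorParams(2**g0, F, G - g0, onset_policy=g0), n, seed=51)
        rng = np.random.default_rng(52)
        schedule = lambda g: (mu1 * F, 0.0) if g >= g0 else (mu1, 0.0)
        oracle = np.array([
            simulate_agent(mu1, 0.0, G, rng, rate_schedule=schedule)["m1_only"]
            for _ in range(n)
        ])
        edges = np.arange(0, 25).tolist() + [np.inf]
        p = _chi2_same_distribution(ref.counts["m1_only"], oracle, edges)
        assert p > 0.01

    def test_double_yield_increases_with_strength(self):
        """A strong episode strictly raises the mean double-mutant yield
        over the null model at the wild-type rates (sign check)."""
        rates = cs.RateSet(3.3e-6, 1.6e-7)
        G, n = 27, 10_000
        ref = cs.simulate_refined_batch(
            rates, G, cs.MutatorParams(100, 1e3, 5), n, seed=61)
        null = cs.simulate_null_batch(rates, G, n, seed=62)
        ref_doubles = ref.counts["double_seq"] + ref.counts["double_sim"]
        null_doubles = null.counts["double_seq"] + null.counts["double_sim"]
        assert ref_doubles.mean() > null_doubles.mean()

    def test_onset_respects_population_size(self):
        batch = cs.simulate_refined_batch(
            cs.RateSet(1e-4, 1e-4), 10, cs.MutatorParams(100, 10.0, 2),
            200, seed=71)
        assert np.all(batch.g0 >= 7)  # ceil(log2 100) = 7
        assert np.all(batch.g0 <= 9)

    def test_infeasible_onset_raises(self):
        with pytest.raises(InputError):
            # population never holds S before the final generation
            cs.simulate_refined_batch(
                cs.RateSet(1e-4, 1e-4), 5, cs.MutatorParams(32, 10.0, 1),
                10, seed=0)
        with pytest.raises(InputError):
            cs.MutatorParams(0, 10.0, 1)
        with pytest.raises(InputError):
            # strength pushes rates past admissibility
            cs.simulate_refined_batch(
                cs.RateSet(0.2, 0.2), 6, cs.MutatorParams(2, 10.0, 1),
                10, seed=0)


class TestEstimateModelRates:
    def test_degenerate_channel_yields_zero_rate(self):
        batch = cs.simulate_null_batch(cs.RateSet(1e-3, 0.0), 10, 100, seed=3)
        est = cs.estimate_model_rates(batch)
        assert est.rate2 == 0.0
        assert est.estimate2.degenerate

    def test_recovers_input_rates(self):
        """Self-consistency: null realizations at mu = 1e-4 give back the
        input rates within 25%."""
        batch = cs.simulate_null_batch(cs.RateSet(1e-4, 1e-4), 10, 5000,
                                       seed=13)
        est = cs.estimate_model_rates(batch, compute_ci=False)
        assert est.rate1 == pytest.approx(1e-4, rel=0.25)
        assert est.rate2 == pytest.approx(1e-4, rel=0.25)

    def test_accepts_realization_lists(self):
        reals = [cs.simulate_null(cs.RateSet(1e-3, 1e-4), 8, seed=s)
                 for s in range(40)]
        est = cs.estimate_model_rates(reals, compute_ci=False)
        assert est.rate1 >= 0

    def test_requires_two_realizations(self):
        with pytest.raises(InputError):
            cs.estimate_model_rates(
                [cs.simulate_null(cs.RateSet(1e-3, 1e-4), 8, seed=0)])


class TestClassifyDoubleOrigins:
    def test_no_channel1_means_no_doubles(self):
        batch = cs.simulate_null_batch(cs.RateSet(0.0, 1e-2), 10, 500, seed=7)
        summary = cs.classify_double_origins(batch)
        assert summary.n_with_doubles == 0
        assert summary.total_sequential_events == 0
        assert np.isnan(summary.sequential_fraction)

    def test_single_generation_doubles_are_simultaneous(self):
        batch = cs.simulate_null_batch(cs.RateSet(0.4, 0.4), 1, 500, seed=8)
        summary = cs.classify_double_origins(batch)
        assert summary.total_sequential_events == 0
        assert summary.n_with_doubles > 0  # p(both) = 0.16 per daughter

    def test_origin_tags_partition_double_lineages(self):
        batch = cs.simulate_null_batch(cs.RateSet(0.05, 0.05), 8, 300, seed=9)
        summary = cs.classify_double_origins(batch)
        assert (summary.n_with_sequential <= summary.n_with_doubles
                <= summary.n_realizations)
        frac = summary.sequential_fraction
        assert 0.0 <= frac <= 1.0
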
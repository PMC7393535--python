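"""Slippage model: pmf identities, closed-form estimator, simulation, KS fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from msical.extraction import AlleleLengthDistribution
from msical.model import (
    SlippageParams,
    estimate_slippage,
    grid_log_likelihood,
    ks_fitness,
    log_likelihood,
    multinoulli_pmf,
    pmf_vector,
    repeat_length_pmf,
    simulate_allele_distribution,
    truncated_mass,
)


def dist(*lengths):
    counts = {}
    for y in lengths:
        counts[y] = counts.get(y, 0) + 1
    return AlleleLengthDistribution(site_id="t", counts=counts)


params_st = st.tuples(
    st.floats(0.0, 0.45), st.floats(0.0, 0.45)
).map(lambda t: SlippageParams(*t))


class TestMultinoulli:
    def test_outcome_probabilities(self):
        params = SlippageParams(0.2, 0.1)
        assert multinoulli_pmf(0, params) == 0.2
        assert multinoulli_pmf(1, params) == pytest.approx(0.7)
        assert multinoulli_pmf(2, params) == 0.1

    def test_zero_slippage(self):
        assert multinoulli_pmf(0, SlippageParams(0.0, 0.0)) == 0.0

    @given(params_st)
    def test_normalization(self, params):
        assert sum(multinoulli_pmf(x, params) for x in (0, 1, 2)) == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            multinoulli_pmf(3, SlippageParams(0.1, 0.1))


class TestRepeatLengthPmf:
    def test_no_slippage_is_certain(self):
        assert repeat_length_pmf(7, 7, SlippageParams(0.0, 0.0)) == 1.0

    def test_single_deletion_branch(self):
        # n=2, y=1: C(2,1) * (1-p-q)^1 * p^1 = 2 * 0.8 * 0.1
        assert repeat_length_pmf(1, 2, SlippageParams(0.1, 0.1)) == pytest.approx(0.16)

    def test_total_mass_closed_form_n2(self):
        params = SlippageParams(0.1, 0.1)
        total = sum(repeat_length_pmf(y, 2, params) for y in range(5))
        assert total == pytest.approx(0.98)
        assert total == pytest.approx(truncated_mass(2, params))

    def test_zero_beyond_support(self):
        assert repeat_length_pmf(5, 2, SlippageParams(0.1, 0.1)) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            repeat_length_pmf(-1, 5, SlippageParams(0.1, 0.1))
        with pytest.raises(ValueError):
            repeat_length_pmf(1, 0, SlippageParams(0.1, 0.1))

    def test_mass_identity_grid(self):
        """Sum over the support equals (1-q)^n + (1-p)^n - (1-p-q)^n."""
        grid = np.linspace(0.0, 0.9, 21)
        for n in range(1, 21):
            for p in grid:
                for q in grid:
                    if p + q > 0.9:
                        continue
                    params = SlippageParams(p, q)
                    total = pmf_vector(n, params).sum()
                    assert abs(total - truncated_mass(n, params)) < 1e-12

    def test_deletion_branch_is_binomial(self):
        """With q=0 the mass at n-k is Binomial(n, p) at k; p=0 mirrors."""
        from scipy.stats import binom

        n, p = 12, 0.07
        for k in range(n + 1):
            assert repeat_length_pmf(n - k, n, SlippageParams(p, 0.0)) == pytest.approx(
                binom.pmf(k, n, p)
            )
            assert repeat_length_pmf(n + k, n, SlippageParams(0.0, p)) == pytest.approx(
                binom.pmf(k, n, p)
            )

    def test_expected_deletion_monotone_in_p(self):
        """E[(n - y)^+] strictly increases with p (enumeration)."""
        n = 10
        means = []
        for p in (0.01, 0.05, 0.1, 0.2):
            probs = pmf_vector(n, SlippageParams(p, 0.02))
            probs = probs / probs.sum()
            y = np.arange(2 * n + 1)
            means.append(float((np.maximum(n - y, 0) * probs).sum()))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestLogLikelihood:
    def test_reference_only_reads(self):
        assert log_likelihood(dist(5, 5), 5, SlippageParams(0.0, 0.0)) == 0.0

    def test_single_read(self):
        assert log_likelihood(dist(1), 2, SlippageParams(0.1, 0.1)) == pytest.approx(
            math.log(0.16)
        )

    def test_duplicate_read_adds_one_term(self):
        params = SlippageParams(0.05, 0.02)
        base = log_likelihood(dist(4, 5), 5, params)
        extra = log_likelihood(dist(4, 5, 5), 5, params)
        assert extra - base == pytest.approx(math.log(repeat_length_pmf(5, 5, params)))

    def test_impossible_read_gives_neg_inf(self):
        assert log_likelihood(dist(11), 5, SlippageParams(0.1, 0.1)) == -math.inf

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(dist(), 5, SlippageParams(0.1, 0.1))


class TestEstimator:
    @pytest.mark.parametrize(
        "lengths, n, expected_p, expected_q",
        [
            ((5, 5, 5), 5, 0.0, 0.0),
            ((4, 5, 6), 5, 1 / 15, 1 / 15),
            ((3, 4), 5, 0.3, 0.0),
        ],
    )
    def test_hand_examples(self, lengths, n, expected_p, expected_q):
        est = estimate_slippage(dist(*lengths), n)
        assert est.p == pytest.approx(expected_p)
        assert est.q == pytest.approx(expected_q)
        assert est.m == len(lengths)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_slippage(dist(), 5)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30))
    def test_matches_direct_substitution(self, lengths):
        n = 10
        est = estimate_slippage(dist(*lengths), n)
        m = len(lengths)
        assert est.p == pytest.approx(
            min(1.0, sum(n - y for y in lengths if y <= n) / (n * m))
        )
        assert est.q == pytest.approx(
            min(1.0, sum(y - n for y in lengths if y > n) / (n * m))
        )

    def test_likelihood_maximized_at_estimate(self):
        """Grid search on a 0.005 lattice peaks within one step of the
        closed-form estimate."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            sim = simulate_allele_distribution(15, SlippageParams(0.05, 0.01), 5000, rng)
            est = estimate_slippage(sim, 15)
            P, Q, ll = grid_log_likelihood(sim, 15, step=0.005)
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            assert abs(P[i, j] - est.p) <= 0.005 + 1e-9
            assert abs(Q[i, j] - est.q) <= 0.005 + 1e-9


class TestSimulation:
    def test_no_slippage_draws_reference_length(self):
        sim = simulate_allele_distribution(8, SlippageParams(0.0, 0.0), 200, rng=1)
        assert sim.counts == {8: 200}

    def test_same_seed_identical(self):
        a = simulate_allele_distribution(10, SlippageParams(0.05, 0.01), 500, rng=42)
        b = simulate_allele_distribution(10, SlippageParams(0.05, 0.01), 500, rng=42)
        assert a.counts == b.counts

    def test_mean_deletion_matches_enumeration(self):
        n, m = 10, 10000
        params = SlippageParams(0.05, 0.01)
        probs = pmf_vector(n, params)
        probs = probs / probs.sum()
        y = np.arange(2 * n + 1)
        expected = float((np.maximum(n - y, 0) / n * probs).sum())
        var = float(((np.maximum(n - y, 0) / n) ** 2 * probs).sum()) - expected**2
        sim = simulate_allele_distribution(n, params, m, rng=3)
        observed = sum(max(n - yy, 0) / n * c for yy, c in sim.counts.items()) / m
        assert abs(observed - expected) < 3 * math.sqrt(var / m)


class TestKsFitness:
    def test_degenerate_identical(self):
        obs = dist(*([10] * 20))
        stat, pval, fitted = ks_fitness(obs, 10, SlippageParams(0.0, 0.0), rng=0)
        assert stat == 0.0 and fitted

    def test_gross_mismatch_rejected(self):
        obs = dist(*([10] * 500))
        stat, pval, fitted = ks_fitness(obs, 10, SlippageParams(0.5, 0.0), m_sim=500, rng=0)
        assert not fitted
        assert stat > 0.9  # nearly all simulated mass sits far below y=n

    def test_self_fitness_rate(self):
        """Data simulated from the model itself should almost always fit
        (the tie-conservative KS rejects well under the nominal 5%)."""
        rng = np.random.default_rng(11)
        fitted = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(8, 21))
            p = float(rng.uniform(0.005, 0.05))
            params = SlippageParams(p, p / 5)
            obs = simulate_allele_distribution(n, params, 50, rng)
            fitted += ks_fitness(obs, n, params, rng=rng)[2]
        assert fitted / trials >= 0.93
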
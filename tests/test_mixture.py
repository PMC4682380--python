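"""Beta-binomial marginals, responsibilities, and the constrained EM fit."""

import numpy as np
import pytest
from scipy import integrate, stats

from dmrhmm.mixture import (BetaMixture, component_responsibilities,
                            fit_beta_mixture, log_beta_binomial_marginal,
                            subsample_shared_sites, subsample_sites)

from conftest import random_mixture, random_table


class TestLogBetaBinomialMarginal:
    def test_empty_observation_has_probability_one(self):
        assert log_beta_binomial_marginal(0, 0, 1.0, 1.0) == pytest.approx(0.0)

    def test_uniform_prior_gives_discrete_uniform(self):
        # with a flat level prior every outcome m of n draws is equally likely
        for n in range(0, 31):
            for m in range(0, n + 1):
                got = log_beta_binomial_marginal(m, n - m, 1.0, 1.0)
                assert got == pytest.approx(-np.log(n + 1), abs=1e-12)

    def test_matches_numerical_quadrature(self):
        m, u, a, b = 7, 1, 8.0, 2.0
        val, _ = integrate.quad(
            lambda th: stats.binom.pmf(m, m + u, th) * stats.beta.pdf(th, a, b),
            0, 1, epsabs=1e-14, epsrel=1e-12)
        got = np.exp(log_beta_binomial_marginal(m, u, a, b))
        assert got == pytest.approx(val, rel=1e-8)

    @pytest.mark.parametrize("alpha,beta", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.0)])
    def test_non_positive_shape_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            log_beta_binomial_marginal(1, 1, alpha, beta)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_beta_binomial_marginal(-1, 0, 1.0, 1.0)

    def test_sums_to_one_over_outcomes(self, rng):
        for _ in range(5):
            a, b = rng.uniform(1, 20, size=2)
            n = int(rng.integers(1, 40))
            m = np.arange(n + 1)
            total = np.exp(log_beta_binomial_marginal(m, n - m, a, b)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)


class TestBetaMixture:
    def test_constraint_violations_rejected(self):
        with pytest.raises(ValueError):
            BetaMixture(0.5, 0.5, 0.2, 8.0, 8.0)        # weights sum > 1
        with pytest.raises(ValueError):
            BetaMixture(0.5, 0.45, 0.05, 0.5, 8.0)      # alpha_h < 1
        with pytest.raises(ValueError):
            BetaMixture(0.5, 0.45, 0.05, 8.0, 8.0, beta_h=2.0)

    def test_component_means_bracket_half(self):
        mix = BetaMixture(0.4, 0.5, 0.1, 3.0, 5.0)
        mean_h = mix.alpha_h / (mix.alpha_h + mix.beta_h)
        mean_l = mix.alpha_l / (mix.alpha_l + mix.beta_l)
        assert mean_h > 0.5 > mean_l

    def test_density_integrates_to_one(self, rng):
        mix = random_mixture(rng)
        val, _ = integrate.quad(mix.pdf, 0, 1, epsabs=1e-10, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestResponsibilities:
    def test_no_data_returns_prior_weights(self, rng):
        mix = random_mixture(rng)
        r = component_responsibilities(0, 0, mix)
        assert np.allclose(r, mix.weights, atol=1e-12)

    def test_symmetric_mixture_symmetric_counts(self):
        mix = BetaMixture(0.45, 0.45, 0.1, 6.0, 6.0)
        r = component_responsibilities(4, 4, mix)
        assert r[0] == pytest.approx(r[1], abs=1e-12)

    def test_matches_direct_normalized_marginals(self, rng):
        mix = random_mixture(rng)
        m, u = 9, 3
        direct = np.array([
            w * np.exp(log_beta_binomial_marginal(m, u, a, b))
            for w, a, b in zip(mix.weights, mix.alphas, mix.betas)])
        direct /= direct.sum()
        got = component_responsibilities(m, u, mix)
        assert np.allclose(got, direct, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


class TestSubsample:
    def test_returns_all_when_fewer_than_requested(self, rng):
        t = random_table(rng, n_sites=5)
        covered = int((t.n1 >= 1).sum())
        got = subsample_sites(t, 1, 10, seed=0)
        assert len(got) == covered

    def test_same_seed_same_subset(self, rng):
        t = random_table(rng, n_sites=40)
        a = subsample_sites(t, 2, 10, seed=7)
        b = subsample_sites(t, 2, 10, seed=7)
        assert np.array_equal(a, b)

    def test_exact_count_when_enough_sites(self, rng):
        t = random_table(rng, n_sites=200, max_depth=20)
        got = subsample_sites(t, 1, 50, seed=1)
        assert len(got) == 50

    def test_shared_sites_use_common_index(self, rng):
        t = random_table(rng, n_sites=100, max_depth=20)
        c1, c2 = subsample_shared_sites(t, 30, seed=3)
        assert len(c1) == len(c2) == 30
        # every returned pair must exist as a row of the table
        df = t.df
        key = {(a, b, c, d) for a, b, c, d in
               zip(df.m1, df.u1, df.m2, df.u2)}
        assert all((a, b, c, d) in key
                   for (a, b), (c, d) in zip(c1.tolist(), c2.tolist()))


class TestFitBetaMixture:
    def _simulate(self, rng, truth, n_sites=2000, depth=10):
        comp = rng.choice(3, size=n_sites, p=truth.weights)
        theta = np.where(comp == 0, rng.beta(truth.alpha_h, 1, n_sites),
                         np.where(comp == 1, rng.beta(1, truth.beta_l, n_sites),
                                  rng.random(n_sites)))
        n = 1 + rng.poisson(depth - 1, n_sites)
        m = rng.binomial(n, theta)
        return np.column_stack([m, n - m])

    def test_weights_normalized_and_ll_monotone(self, rng):
        counts = self._simulate(rng, BetaMixture(0.5, 0.45, 0.05, 8.0, 8.0))
        mix, history = fit_beta_mixture(counts)
        assert mix.weights.sum() == pytest.approx(1.0, abs=1e-12)
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-10)

    def test_recovers_generating_parameters(self, rng):
        truth = BetaMixture(0.55, 0.4, 0.05, 6.0, 9.0)
        counts = self._simulate(rng, truth, n_sites=4000)
        mix, _ = fit_beta_mixture(counts)
        assert abs(mix.w_h - truth.w_h) < 0.08
        assert abs(mix.w_l - truth.w_l) < 0.08
        assert abs(mix.alpha_h - truth.alpha_h) / truth.alpha_h < 0.3
        assert abs(mix.beta_l - truth.beta_l) / truth.beta_l < 0.3

    def test_fully_methylated_input_collapses_to_high(self):
        counts = np.column_stack([np.full(300, 8), np.zeros(300, dtype=int)])
        mix, _ = fit_beta_mixture(counts)
        assert mix.w_h > 0.9
        r = component_responsibilities(8, 0, mix)
        assert r[0] > 0.9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_mixture(np.array([[1, 1]]), max_iter=0)
        with pytest.raises(ValueError):
            fit_beta_mixture(np.empty((0, 2)))
        with pytest.raises(ValueError):
            fit_beta_mixture(np.array([[0, 0]]))
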
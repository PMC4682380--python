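"""HMM topology, collapsed kernels, forward/backward, and Baum-Welch."""

import numpy as np
import pytest

from dmrhmm.hmm import (D_MAX, N_CPG, DOWN, NOCH, UP, HmmParams, default_hmm,
                        effective_transition, fit_transitions,
                        forward_backward, state_index)

from oracles import enumerate_log_likelihood, silent_chain_kernel


def simple_params(stay=None, q=None, initial=None) -> HmmParams:
    stay = np.full(N_CPG, 0.8) if stay is None else np.asarray(stay, float)
    q = np.full((N_CPG, N_CPG), 1 / N_CPG) if q is None else np.asarray(q, float)
    if initial is None:
        initial = np.full(N_CPG, 1 / N_CPG)
    return HmmParams(gap_stay=stay, gap_to_cpg=q, initial=initial)


def random_params(rng) -> HmmParams:
    q = rng.dirichlet(np.ones(N_CPG), size=N_CPG)
    return HmmParams(gap_stay=rng.uniform(0.2, 0.95, N_CPG), gap_to_cpg=q,
                     initial=rng.dirichlet(np.ones(N_CPG)))


class TestDefaultHmm:
    def test_full_matrix_row_stochastic(self):
        A = default_hmm(0).transition_matrix()
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_identical(self):
        a, b = default_hmm(3), default_hmm(3)
        assert np.array_equal(a.gap_stay, b.gap_stay)
        assert np.array_equal(a.gap_to_cpg, b.gap_to_cpg)

    def test_structural_zeros(self):
        A = default_hmm(1).transition_matrix()
        # CpG states may only enter their own gap state
        for s in range(N_CPG):
            row = A[s].copy()
            assert row[N_CPG + s] == 1.0
            row[N_CPG + s] = 0.0
            assert np.all(row == 0.0)
        # gap states never jump to a different gap state
        gap_block = A[N_CPG:, N_CPG:]
        assert np.all(gap_block == np.diag(np.diag(gap_block)))

    def test_initial_heavily_weighted_to_noch(self):
        p = default_hmm(0)
        noch = p.initial[state_index(NOCH, 0)] + p.initial[state_index(NOCH, 1)]
        assert noch == pytest.approx(0.9)

    def test_direction_swap_invariance(self):
        # Up and Down slots carry identical parameters, so a sample swap maps
        # the model onto itself (the basis of pipeline swap-equivariance)
        p = default_hmm(11)
        perm = np.array([state_index(d, u) for d in (DOWN, UP, NOCH)
                         for u in range(2)])
        assert np.array_equal(p.gap_stay, p.gap_stay[perm])
        assert np.array_equal(p.gap_to_cpg, p.gap_to_cpg[np.ix_(perm, perm)])
        assert np.array_equal(p.initial, p.initial[perm])


class TestEffectiveTransition:
    def test_geometric_law_with_uniform_exit(self):
        a = 0.7
        p = simple_params(stay=np.full(N_CPG, a))
        for d in (1, 2, 5, 9):
            T = effective_transition(p, d)
            expect = a ** (d - 1) * (1 - a) / N_CPG
            assert np.allclose(T[:N_CPG, :N_CPG], expect, atol=1e-14)

    def test_distance_one_skips_self_loop(self, rng):
        p = random_params(rng)
        T = effective_transition(p, 1)[:N_CPG, :N_CPG]
        expect = (1 - p.gap_stay)[:, None] * p.gap_to_cpg
        assert np.allclose(T, expect, atol=1e-15)

    def test_matches_explicit_silent_chain(self, rng):
        p = random_params(rng)
        for d in list(range(11)) + [17]:
            T = effective_transition(p, d)[:N_CPG, :N_CPG]
            assert np.allclose(T, silent_chain_kernel(p, d), atol=1e-12), d

    def test_log_kernel_agrees_with_linear_form(self, rng):
        p = random_params(rng)
        for d in (1, 3, 10):
            assert np.allclose(np.exp(p.log_kernel(d)),
                               effective_transition(p, d)[:N_CPG, :N_CPG],
                               atol=1e-13)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            effective_transition(simple_params(), -1)

    def test_huge_distance_capped_and_finite(self):
        p = simple_params()
        k = p.log_kernel(D_MAX * 10)
        assert np.all(np.isfinite(k) | (k == -np.inf))


class TestForwardBackward:
    def test_single_site_posterior_proportional_to_init_times_emission(self, rng):
        p = random_params(rng)
        log_e = np.log(rng.random((1, 3)))
        ll, post = forward_backward(log_e, [], p)
        weights = p.initial.reshape(3, 2).sum(axis=1) * np.exp(log_e[0])
        assert np.allclose(post[0], weights / weights.sum(), atol=1e-12)
        assert ll == pytest.approx(np.log(weights.sum()), abs=1e-12)

    def test_unit_emissions_likelihood_is_gap_pattern_probability(self, rng):
        # with emission 1 everywhere the likelihood is the model probability
        # of the observed inter-CpG distances (the kernels are substochastic)
        p = random_params(rng)
        gaps = [2, 5, 1]
        log_e = np.zeros((4, 3))
        ll, post = forward_backward(log_e, gaps, p)
        oracle = enumerate_log_likelihood(log_e, gaps, p)
        assert ll == pytest.approx(oracle, rel=1e-9)
        assert ll < 0.0
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("L", [1, 2, 3, 5])
    def test_matches_exhaustive_path_enumeration(self, rng, L):
        for _ in range(3):
            p = random_params(rng)
            log_e = np.log(rng.random((L, 3)) + 1e-3)
            gaps = rng.integers(1, 7, size=L - 1)
            ll, post = forward_backward(log_e, gaps, p)
            oracle = enumerate_log_likelihood(log_e, gaps, p)
            assert ll == pytest.approx(oracle, rel=1e-9)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_and_mismatched_inputs_rejected(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            forward_backward(np.zeros((0, 3)), [], p)
        with pytest.raises(ValueError):
            forward_backward(np.zeros((3, 3)), [1], p)


class TestFitTransitions:
    def _simulate_chain(self, rng, params, L, strength=12.0):
        """Sample a state path from the chain and return strong emissions
        identifying it, plus the gap lengths actually drawn."""
        states = np.empty(L, dtype=int)
        gaps = np.empty(L - 1, dtype=int)
        s = rng.choice(N_CPG, p=params.initial)
        states[0] = s
        for i in range(1, L):
            d = int(rng.geometric(1 - params.gap_stay[s]))
            gaps[i - 1] = d
            kernel = np.exp(params.log_kernel(int(d)))
            row = kernel[s] / kernel[s].sum()
            s = rng.choice(N_CPG, p=row)
            states[i] = s
        log_e = np.full((L, 3), -strength)
        log_e[np.arange(L), states // 2] = 0.0
        return log_e, gaps

    def test_monotone_and_fixed_point(self, rng):
        p = default_hmm(0)
        log_e = np.log(rng.random((40, 3)) + 1e-3)
        gaps = rng.integers(1, 80, size=39)
        fitted, history = fit_transitions(log_e, gaps, p, tol=1e-5, max_iter=500)
        assert np.all(np.diff(history) >= -1e-10)
        assert len(history) < 500, "EM should reach its tolerance"
        _, again = fit_transitions(log_e, gaps, fitted, tol=1e-5, max_iter=5)
        assert again[-1] - again[0] < 1e-5

    def test_recovers_noch_dwell_from_simulated_paths(self, rng):
        truth = default_hmm(5)
        truth = HmmParams(gap_stay=np.tile([0.75, 0.9], 3),
                          gap_to_cpg=truth.gap_to_cpg, initial=truth.initial)
        log_e, gaps = self._simulate_chain(rng, truth, L=5000)
        fitted, history = fit_transitions(log_e, gaps, default_hmm(0),
                                          tol=1e-6, max_iter=60)
        assert np.all(np.diff(history) >= -1e-10)
        # compare the mixture-of-geometrics mean dwell for NoCh sources
        # (unit labels are exchangeable, so compare sorted unit parameters)
        got = np.sort(fitted.gap_stay[[state_index(NOCH, 0), state_index(NOCH, 1)]])
        want = np.sort(truth.gap_stay[[state_index(NOCH, 0), state_index(NOCH, 1)]])
        assert np.all(np.abs(got - want) < 0.05)

    def test_expected_counts_match_two_site_hand_computation(self, rng):
        from dmrhmm.hmm import _expected_counts
        p = random_params(rng)
        d = 4
        log_e = np.log(rng.random((2, 3)) + 0.1)
        e6 = np.repeat(log_e, 2, axis=1)
        kernel = np.exp(p.log_kernel(d))
        joint = (p.initial * np.exp(e6[0]))[:, None] * kernel * np.exp(e6[1])[None, :]
        ll_hand = np.log(joint.sum())
        xi = joint / joint.sum()
        ll, q_num, self_num, exit_num, gamma0 = _expected_counts(log_e, [d], p)
        assert ll == pytest.approx(ll_hand, abs=1e-10)
        assert np.allclose(q_num, xi, atol=1e-12)
        assert np.allclose(exit_num, xi.sum(axis=1), atol=1e-12)
        assert np.allclose(self_num, (d - 1) * xi.sum(axis=1), atol=1e-12)
        assert np.allclose(gamma0, xi.sum(axis=1), atol=1e-12)

    def test_invalid_max_iter_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_transitions(np.zeros((2, 3)), [1], default_hmm(0), max_iter=0)
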
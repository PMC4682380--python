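"""Independent brute-force / quadrature oracles used by the tests.

These never call the code paths they check: emissions are integrated
numerically from the defining binomial-times-density integrals, HMM
likelihoods are obtained by exhaustive path enumeration, and DMR extraction
is compared against exhaustive search over disjoint segment combinations.
"""

import itertools

import numpy as np
from scipy import integrate, stats

from dmrhmm.caller import score_region
from dmrhmm.hmm import N_CPG, N_UNIT


# ---------------------------------------------------------------------------
# emission quadrature


def _mixture_pdf(mix, theta):
    return mix.pdf(theta)


def quad_emission_up(m1, u1, m2, u2, mix1, mix2):
    """Eq. of the Up emission as two 1-D integrals of Binom x Beta."""
    def one(m, u, a, b):
        val, _ = integrate.quad(
            lambda th: stats.binom.pmf(m, m + u, th) * stats.beta.pdf(th, a, b),
            0, 1, epsabs=1e-13, epsrel=1e-11, limit=200)
        return val
    return one(m1, u1, mix1.alpha_h, mix1.beta_h) \
        * one(m2, u2, mix2.alpha_l, mix2.beta_l)


def quad_emission_down(m1, u1, m2, u2, mix1, mix2):
    return quad_emission_up(m2, u2, m1, u1, mix2, mix1)


def quad_emission_noch(m1, u1, m2, u2, mix1, mix2):
    """Common-level integral of Binom x Binom x p1 x p2 / Z by quadrature."""
    def integrand(th):
        return (stats.binom.pmf(m1, m1 + u1, th) * stats.binom.pmf(m2, m2 + u2, th)
                * _mixture_pdf(mix1, th) * _mixture_pdf(mix2, th))
    num, _ = integrate.quad(integrand, 0, 1, epsabs=1e-13, epsrel=1e-11, limit=200)
    z, _ = integrate.quad(lambda th: _mixture_pdf(mix1, th) * _mixture_pdf(mix2, th),
                          0, 1, epsabs=1e-13, epsrel=1e-11, limit=200)
    return num / z


# ---------------------------------------------------------------------------
# HMM path enumeration


def silent_chain_kernel(params, d):
    """CpG-to-CpG kernel for distance d by stepping the explicit 12-state
    chain through its silent gap positions (linear space)."""
    A = params.transition_matrix()
    cpg, gap = slice(0, N_CPG), slice(N_CPG, 2 * N_CPG)
    block = np.zeros((N_CPG, N_CPG))
    for s in range(N_CPG):
        v = np.zeros(2 * N_CPG)
        v[s] = 1.0
        v = v @ A
        v[cpg] = 0.0          # first step must land in a gap state
        for _ in range(max(d - 1, 0)):
            w = v @ A
            w[cpg] = 0.0      # interior positions stay silent
            v = w
        v = v @ A
        block[s] = v[cpg]     # arrival at the next CpG
    return block


def enumerate_log_likelihood(log_e3, gaps, params):
    """Exhaustive sum over all CpG-state paths (6^L) using the collapsed
    per-distance kernels computed by the explicit silent chain."""
    log_e3 = np.asarray(log_e3, dtype=float)
    L = len(log_e3)
    kernels = [silent_chain_kernel(params, int(d)) for d in gaps]
    e6 = np.repeat(log_e3, N_UNIT, axis=1)
    total = -np.inf
    for path in itertools.product(range(N_CPG), repeat=L):
        lp = np.log(params.initial[path[0]]) if params.initial[path[0]] > 0 else -np.inf
        lp += e6[0, path[0]]
        ok = np.isfinite(lp)
        for i in range(L - 1):
            if not ok:
                break
            k = kernels[i][path[i], path[i + 1]]
            if k <= 0:
                ok = False
                break
            lp += np.log(k) + e6[i + 1, path[i + 1]]
        if ok and np.isfinite(lp):
            total = np.logaddexp(total, lp)
    return total


# ---------------------------------------------------------------------------
# exhaustive DMR segmentation


def best_disjoint_segments(emissions, gaps, params, threshold=0.0):
    """Exhaustive search over all disjoint (start, end, direction) segment
    combinations maximizing the total score, each segment above threshold.
    Returns (best_total, best_set) with the set sorted by start."""
    log_e3 = emissions.log_e if hasattr(emissions, "log_e") else np.asarray(emissions)
    L = len(log_e3)
    scores = {}
    for s in range(L):
        for e in range(s, L):
            for dirname in ("Up", "Down"):
                sc = score_region(emissions, gaps, params, s, e, dirname)
                if sc > threshold:
                    scores[(s, e, dirname)] = sc

    best = {"total": 0.0, "set": ()}

    def recurse(next_start, chosen, total):
        if total > best["total"] + 1e-12:
            best["total"] = total
            best["set"] = tuple(chosen)
        for (s, e, dirname), sc in scores.items():
            if s >= next_start:
                chosen.append((s, e, dirname))
                recurse(e + 1, chosen, total + sc)
                chosen.pop()

    recurse(0, [], 0.0)
    return best["total"], tuple(sorted(best["set"]))
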
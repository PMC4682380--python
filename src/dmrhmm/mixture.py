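"""Genome-wide methylation-level priors as constrained beta mixtures.

Methylation levels pooled over all CpG sites of a sample are strongly
bimodal: most sites are either nearly fully methylated or nearly
unmethylated, with a thin uniform background.  We model the per-sample level
distribution as a three-component mixture

    p(theta) = w_H Beta(theta | alpha_H, 1) + w_L Beta(theta | 1, beta_L)
               + w_unif Uniform(0, 1)

with alpha_H >= 1 and beta_L >= 1, so the H component is a monotone density
peaked at 1 and the L component its mirror peaked at 0 — each beta component
owns exactly one mode.  The mixture is fitted by maximum likelihood on read
counts (m, u) rather than on ratios m/n: integrating the binomial against
each beta component gives a beta-binomial marginal, so depth information is
retained and the fit automatically adapts to coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp, polygamma

_SHAPE_MAX = 1e6


def log_beta_binomial_marginal(m, u, alpha, beta):
    """log P(m | n=m+u) under a binomial with a Beta(alpha, beta) prior level.

    Closed form: log C(m+u, m) + log B(m+alpha, u+beta) - log B(alpha, beta).
    Vectorized over any broadcastable combination of arguments.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("counts must be non-negative")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("beta shape parameters must be positive")
    n = m + u
    log_choose = gammaln(n + 1) - gammaln(m + 1) - gammaln(u + 1)
    return log_choose + betaln(m + alpha, u + beta) - betaln(alpha, beta)


@dataclass(frozen=True)
class BetaMixture:
    """Three-component methylation-level prior for one sample.

    Components: H (high, Beta(alpha_h, 1)), L (low, Beta(1, beta_l)) and a
    uniform background (Beta(1, 1)).  The fixed unit shapes keep the
    differential-state integrals in closed form and pin each beta component
    to one mode.
    """

    w_h: float
    w_l: float
    w_unif: float
    alpha_h: float
    beta_l: float
    beta_h: float = field(default=1.0)
    alpha_l: float = field(default=1.0)

    def __post_init__(self):
        w = np.array([self.w_h, self.w_l, self.w_unif])
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must be a distribution, got {w}")
        if self.beta_h != 1.0 or self.alpha_l != 1.0:
            raise ValueError("constraint beta_h = alpha_l = 1 violated")
        if self.alpha_h < 1.0 or self.beta_l < 1.0:
            raise ValueError("shape parameters must be >= 1")

    # component arrays in fixed order (H, L, unif)
    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_h, self.w_l, self.w_unif])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([self.alpha_h, self.alpha_l, 1.0])

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta_h, self.beta_l, 1.0])

    def pdf(self, theta) -> np.ndarray:
        """Mixture density on [0, 1]."""
        theta = np.asarray(theta, dtype=float)
        dens = np.zeros_like(theta)
        for w, a, b in zip(self.weights, self.alphas, self.betas):
            dens += w * np.exp((a - 1) * np.log(np.clip(theta, 1e-300, 1.0))
                               + (b - 1) * np.log(np.clip(1 - theta, 1e-300, 1.0))
                               - betaln(a, b))
        return dens


def component_responsibilities(m, u, mix: BetaMixture) -> np.ndarray:
    """Posterior probability of each component (H, L, unif) given counts.

    With no reads (m = u = 0) every marginal is 1 and the posterior equals
    the prior weights.
    """
    return np.exp(_log_responsibilities(np.atleast_1d(m), np.atleast_1d(u), mix))[0] \
        if np.isscalar(m) else np.exp(_log_responsibilities(m, u, mix))


def _component_log_marginals(m, u, mix: BetaMixture) -> np.ndarray:
    m = np.asarray(m, dtype=float)[:, None]
    u = np.asarray(u, dtype=float)[:, None]
    return log_beta_binomial_marginal(m, u, mix.alphas[None, :], mix.betas[None, :])


def _log_responsibilities(m, u, mix: BetaMixture) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lw = np.log(mix.weights)
    lj = _component_log_marginals(m, u, mix) + lw[None, :]
    return lj - logsumexp(lj, axis=1, keepdims=True)


def subsample_sites(table, sample_index: int, n_sites: int, seed: int) -> np.ndarray:
    """Uniform subsample (without replacement) of covered sites of one sample.

    Returns an (k, 2) integer array of (m, u) pairs, k = min(n_sites, number
    of sites with n >= 1 in that sample).  Reproducible under ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if sample_index not in (1, 2):
        raise ValueError("sample_index must be 1 or 2")
    m = table.df[f"m{sample_index}"].to_numpy()
    u = table.df[f"u{sample_index}"].to_numpy()
    return _subsample(m, u, m + u >= 1, n_sites, seed)


def subsample_shared_sites(table, n_sites: int, seed: int):
    """One site subsample with coverage in BOTH samples; returns two (k, 2)
    arrays (sample-1 counts, sample-2 counts) over the same sites.

    Using a common site set keeps the two per-sample fits exactly symmetric
    under exchanging the samples.
    """
    df = table.df
    m1, u1 = df["m1"].to_numpy(), df["u1"].to_numpy()
    m2, u2 = df["m2"].to_numpy(), df["u2"].to_numpy()
    eligible = (m1 + u1 >= 1) & (m2 + u2 >= 1)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("no site with coverage in both samples")
    rng = np.random.default_rng(seed)
    if idx.size > n_sites:
        idx = np.sort(rng.choice(idx, size=n_sites, replace=False))
    return np.column_stack([m1[idx], u1[idx]]), np.column_stack([m2[idx], u2[idx]])


def _subsample(m, u, eligible, n_sites, seed) -> np.ndarray:
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("no site with coverage")
    rng = np.random.default_rng(seed)
    if idx.size > n_sites:
        idx = np.sort(rng.choice(idx, size=n_sites, replace=False))
    return np.column_stack([m[idx], u[idx]])


# ---------------------------------------------------------------------------
# EM fit


def _mstep_shape(shape, r, m, u, mirror: bool) -> float:
    """Damped Newton ascent of the EM Q-objective in the single free shape.

    For the H component (mirror=False) the objective is
    sum_i r_i [log B(m_i+a, u_i+1) - log B(a, 1)], which reduces to
    sum_i r_i [lgamma(m_i+a) - lgamma(n_i+a+1)] + (sum r) log a up to a
    shape-free constant; the L component is the mirror image (swap m, u).
    The step is projected onto [1, _SHAPE_MAX]; backtracking guarantees the
    objective never decreases, so the outer EM remains monotone
    (generalized EM).
    """
    rsum = float(r.sum())
    if rsum < 1e-12:
        return shape  # dead component: leave unchanged
    x = u if mirror else m
    n = m + u

    def q(a):
        return float(np.sum(r * (gammaln(x + a) - gammaln(n + a + 1)))
                     + rsum * np.log(a))

    a = float(shape)
    for _ in range(40):
        d1 = float(np.sum(r * (digamma(x + a) - digamma(n + a + 1))) + rsum / a)
        d2 = float(np.sum(r * (polygamma(1, x + a) - polygamma(1, n + a + 1))) - rsum / a**2)
        if abs(d1) < 1e-10 * max(1.0, rsum):
            break
        step = -d1 / d2 if d2 < 0 else np.sign(d1) * max(1.0, abs(a) * 0.5)
        new = np.clip(a + step, 1.0, _SHAPE_MAX)
        q_old = q(a)
        tries = 0
        while q(new) < q_old - 1e-12 and tries < 30:
            new = a + (new - a) / 2
            tries += 1
        if abs(new - a) < 1e-12:
            break
        a = float(np.clip(new, 1.0, _SHAPE_MAX))
    return a


def fit_beta_mixture(counts, tol: float = 1e-6, max_iter: int = 500,
                     seed: int | None = None):
    """Maximum-likelihood fit of the constrained 3-component mixture by EM.

    Parameters
    ----------
    counts : (k, 2) array-like of (m, u) pairs, each with m + u >= 1.
    tol : relative log-likelihood change for convergence.
    max_iter : maximum EM iterations (>= 1).
    seed : unused (the fit is deterministic from its moment-based start);
        accepted for interface uniformity.

    Returns
    -------
    (BetaMixture, list of per-iteration log-likelihoods)
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2 or len(counts) == 0:
        raise ValueError("counts must be a non-empty (k, 2) array of (m, u)")
    m, u = counts[:, 0], counts[:, 1]
    n = m + u
    if np.any(n < 1):
        raise ValueError("every site must have at least one read")

    # moment-based start: split sites at level 1/2, match component means
    level = m / n
    high = level > 0.5
    w = np.array([max(high.mean(), 1e-3) * 0.95,
                  max((~high).mean(), 1e-3) * 0.95, 0.05])
    w = w / w.sum()
    mu_h = float(level[high].mean()) if high.any() else 0.9
    mu_l = float(level[~high].mean()) if (~high).any() else 0.1
    # Beta(a, 1) mean a/(a+1) = mu  =>  a = mu/(1-mu)
    alpha_h = float(np.clip(mu_h / max(1 - mu_h, 1e-3), 1.0, 100.0))
    beta_l = float(np.clip((1 - mu_l) / max(mu_l, 1e-3), 1.0, 100.0))
    mix = BetaMixture(w[0], w[1], w[2], alpha_h, beta_l)

    history: list[float] = []
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lw = np.log(mix.weights)
        lj = _component_log_marginals(m, u, mix) + lw[None, :]
        site_ll = logsumexp(lj, axis=1)
        ll = float(site_ll.sum())
        resp = np.exp(lj - site_ll[:, None])
        if history and ll - history[-1] < tol * max(1.0, abs(ll)):
            history.append(ll)
            break
        history.append(ll)
        w = resp.mean(axis=0)
        alpha_h = _mstep_shape(mix.alpha_h, resp[:, 0], m, u, mirror=False)
        beta_l = _mstep_shape(mix.beta_l, resp[:, 1], m, u, mirror=True)
        mix = BetaMixture(w[0], w[1], w[2], alpha_h, beta_l)
    return mix, history
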
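"""Per-CpG log emission values for the differential-methylation states.

Each CpG site carries three emission values, one per differential state:

* Up   — hypermethylated in sample 1: level drawn from sample 1's high
  component and sample 2's low component, integrated against the binomial
  read-count likelihoods,
* Down — the mirror image,
* NoCh — a single common level for both samples, drawn from the product of
  the two full per-sample mixtures (renormalized on the diagonal
  theta1 = theta2).

All integrals are beta-binomial closed forms; everything is computed in log
space via log-gamma and logsumexp.  A site with no reads in either sample
emits probability 1 in every state, so it stays in the chain for distance
modeling without influencing state inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, xlogy

from .mixture import BetaMixture

UP, DOWN, NOCH = 0, 1, 2
DIRECTIONS = ("Up", "Down", "NoCh")


@dataclass
class EmissionTable:
    """Per-site log emissions, columns ordered (Up, Down, NoCh)."""

    log_e: np.ndarray  # (n_sites, 3)
    log_z: float       # diagonal-product normalizer shared by all sites

    def __len__(self) -> int:
        return len(self.log_e)

    @property
    def log_up(self) -> np.ndarray:
        return self.log_e[:, UP]

    @property
    def log_down(self) -> np.ndarray:
        return self.log_e[:, DOWN]

    @property
    def log_noch(self) -> np.ndarray:
        return self.log_e[:, NOCH]


@dataclass(frozen=True)
class LegacyEmissionConfig:
    """Configuration of the pseudocount emission model."""

    pseudo: float

    def __post_init__(self):
        if self.pseudo < 0:
            raise ValueError("pseudo must be non-negative")


def _log_bb_ratio(m, u, alpha, beta):
    # log B(m+alpha, u+beta) - log B(alpha, beta); the binomial coefficient
    # is added separately (shared by all three states)
    return betaln(m + alpha, u + beta) - betaln(alpha, beta)


def log_noch_normalizer(mix1: BetaMixture, mix2: BetaMixture) -> float:
    """log of Z = integral over [0,1] of p1(theta) p2(theta) d theta,
    expanded over the 3x3 component pairs in closed beta-function form."""
    return float(_noch_logsumexp(0.0, 0.0, mix1, mix2))


def _noch_logsumexp(m_tot, u_tot, mix1: BetaMixture, mix2: BetaMixture):
    """logsumexp over component pairs (s, t) of
    w_s w_t B(m_tot + a_s + a_t - 1, u_tot + b_s + b_t - 1) / (B_s B_t).

    Every pairwise combination and the final reduction are arranged to be
    bit-exactly invariant under exchanging the two mixtures (transposing the
    component grid), so a sample swap leaves the NoCh emission unchanged.
    """
    a1, b1, w1 = mix1.alphas, mix1.betas, mix1.weights
    a2, b2, w2 = mix2.alphas, mix2.betas, mix2.weights
    a_sum = (a1[:, None] + a2[None, :]) - 1.0  # (3, 3)
    b_sum = (b1[:, None] + b2[None, :]) - 1.0
    if np.any(a_sum < 1.0 - 1e-12) or np.any(b_sum < 1.0 - 1e-12):
        raise ValueError("component shapes violate the >= 1 constraints")
    with np.errstate(divide="ignore"):
        lw = np.log(w1)[:, None] + np.log(w2)[None, :]
    const = lw - (betaln(a1, b1)[:, None] + betaln(a2, b2)[None, :])
    m_tot = np.asarray(m_tot, dtype=float)
    u_tot = np.asarray(u_tot, dtype=float)
    terms = betaln(m_tot[..., None, None] + a_sum, u_tot[..., None, None] + b_sum)
    T = terms + const
    mx = T.max(axis=(-2, -1))
    E = np.exp(T - mx[..., None, None])
    diag = (E[..., 0, 0] + E[..., 1, 1]) + E[..., 2, 2]
    off = (E[..., 0, 1] + E[..., 1, 0]) \
        + ((E[..., 0, 2] + E[..., 2, 0]) + (E[..., 1, 2] + E[..., 2, 1]))
    return mx + np.log(diag + off)


def compute_emissions(table, mix1: BetaMixture, mix2: BetaMixture) -> EmissionTable:
    """Beta-mixture emissions for every site of a two-sample count table.

    Up uses (H of sample 1) x (L of sample 2); Down the mirror; NoCh pools
    the counts of both samples against the diagonal product of the two full
    mixtures, normalized by Z so it is a proper distribution over (m1, m2).
    """
    df = table.df
    m1 = df["m1"].to_numpy(float)
    u1 = df["u1"].to_numpy(float)
    m2 = df["m2"].to_numpy(float)
    u2 = df["u2"].to_numpy(float)
    n1, n2 = m1 + u1, m2 + u2

    # per-sample grouping keeps every sum a commutative two-term addition, so
    # exchanging the samples swaps Up and Down bit-exactly
    lc1 = gammaln(n1 + 1) - (gammaln(m1 + 1) + gammaln(u1 + 1))
    lc2 = gammaln(n2 + 1) - (gammaln(m2 + 1) + gammaln(u2 + 1))

    log_up = ((lc1 + _log_bb_ratio(m1, u1, mix1.alpha_h, mix1.beta_h))
              + (lc2 + _log_bb_ratio(m2, u2, mix2.alpha_l, mix2.beta_l)))
    log_down = ((lc1 + _log_bb_ratio(m1, u1, mix1.alpha_l, mix1.beta_l))
                + (lc2 + _log_bb_ratio(m2, u2, mix2.alpha_h, mix2.beta_h)))
    log_z = log_noch_normalizer(mix1, mix2)
    log_noch = (lc1 + lc2) \
        + (_noch_logsumexp(m1 + m2, u1 + u2, mix1, mix2) - log_z)

    log_e = np.column_stack([log_up, log_down, log_noch])
    if not np.all(np.isfinite(log_e)):
        raise FloatingPointError("non-finite emission value")
    return EmissionTable(log_e=log_e, log_z=log_z)


def compute_legacy_emissions(table, config: LegacyEmissionConfig) -> EmissionTable:
    """Pseudocount emissions: plug-in binomials with state-dependent levels.

    The empirical pseudocount shifts the plug-in level toward 1 for the
    sample expected high and toward 0 for the sample expected low; NoCh uses
    the pooled level.  With pseudo = 0 the Up and Down levels coincide and
    the direction of change becomes unidentifiable.
    """
    ps = float(config.pseudo)
    df = table.df
    m1 = df["m1"].to_numpy(float)
    u1 = df["u1"].to_numpy(float)
    m2 = df["m2"].to_numpy(float)
    u2 = df["u2"].to_numpy(float)
    n1, n2 = m1 + u1, m2 + u2

    def log_binom(m, u, theta):
        n = m + u
        log_choose = gammaln(n + 1) - gammaln(m + 1) - gammaln(u + 1)
        return log_choose + xlogy(m, theta) + xlogy(u, 1.0 - theta)

    def safe_div(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        return out

    theta1_up = safe_div(m1 + ps, n1 + ps)
    theta2_up = safe_div(m2, n2 + ps)
    theta1_dn = safe_div(m1, n1 + ps)
    theta2_dn = safe_div(m2 + ps, n2 + ps)
    eps = 1e-12
    theta0 = np.clip(safe_div(m1 + m2, n1 + n2), eps, 1 - eps)

    log_up = log_binom(m1, u1, np.clip(theta1_up, 0.0, 1.0)) \
        + log_binom(m2, u2, theta2_up)
    log_down = log_binom(m1, u1, theta1_dn) \
        + log_binom(m2, u2, np.clip(theta2_dn, 0.0, 1.0))
    log_noch = log_binom(m1, u1, theta0) + log_binom(m2, u2, theta0)
    # a site with no reads at all emits 1 in every state
    empty = (n1 + n2) == 0
    log_e = np.column_stack([log_up, log_down, log_noch])
    log_e[empty] = 0.0
    if not np.all(np.isfinite(log_e)):
        raise FloatingPointError("non-finite legacy emission value")
    return EmissionTable(log_e=log_e, log_z=0.0)
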
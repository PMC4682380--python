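"""Dual-unit hidden Markov chain over CpG sites with silent gap states.

State space: {CpG, gap} x {Up, Down, NoCh} x {basic, second} — 12 states.
CpG states are visited exactly at CpG positions and carry the emissions;
gap states are silent and occupy the interval positions between consecutive
CpGs, so the self-transition probability of each gap state encodes a
geometric distance distribution for its differential state.  The duplicated
(basic/second) unit gives each state a two-component mixture of geometrics,
which fits the heavy-tailed spacing of differentially methylated cytosines
far better than a single geometric.

Topology (within the allowed structure):

* ``CpG(x, u) -> gap(x, u)`` deterministically (probability 1);
* ``gap(x, u) -> gap(x, u)`` with probability ``a[x, u]`` (self loop only);
* ``gap(x, u) -> CpG(y, v)`` with probability ``(1 - a[x, u]) q[(x,u),(y,v)]``,
  so both direction changes and unit switches happen when a gap run ends.

Because gap states are silent and only self-loop, a run of d interval
positions collapses analytically: the CpG-to-CpG kernel for distance d is
``a^(d-1) (1 - a) q`` per source state, evaluated in log space so arbitrarily
large distances are exact.  The collapsed kernel is substochastic on
purpose — the model assigns probability to the observed inter-CpG distances
themselves, which is what lets EM learn distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_DIR = 3          # Up, Down, NoCh
N_UNIT = 2         # basic, second
N_CPG = N_DIR * N_UNIT
UP, DOWN, NOCH = 0, 1, 2

D_MAX = 10**6      # distances are capped here; geometric tails below ~e^-2000


def state_index(direction: int, unit: int) -> int:
    """Flat index of a (direction, unit) pair, shared by CpG and gap layers."""
    return direction * N_UNIT + unit


@dataclass
class HmmParams:
    """Transition parameters of the 12-state chain.

    Attributes
    ----------
    gap_stay : (6,) gap self-loop probability per (direction, unit).
    gap_to_cpg : (6, 6) conditional target distribution when a gap run ends;
        rows sum to 1.
    initial : (6,) distribution over CpG states at the first CpG of each
        chromosome.
    """

    gap_stay: np.ndarray
    gap_to_cpg: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        self.gap_stay = np.asarray(self.gap_stay, dtype=float)
        self.gap_to_cpg = np.asarray(self.gap_to_cpg, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.gap_stay.shape != (N_CPG,):
            raise ValueError("gap_stay must have shape (6,)")
        if self.gap_to_cpg.shape != (N_CPG, N_CPG):
            raise ValueError("gap_to_cpg must have shape (6, 6)")
        if self.initial.shape != (N_CPG,):
            raise ValueError("initial must have shape (6,)")
        if np.any(self.gap_stay <= 0) or np.any(self.gap_stay >= 1):
            raise ValueError("gap self-loop probabilities must be in (0, 1)")
        if np.any(self.gap_to_cpg < 0) or np.any(self.initial < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.gap_to_cpg.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("gap_to_cpg rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial must sum to 1")
        self._kernel_cache: dict[int, np.ndarray] = {}

    # -- full 12x12 matrix (CpG block first, gap block second) -------------

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 12x12 matrix; rows/cols 0-5 CpG states, 6-11 gap
        states, each layer ordered by (direction, unit).  Structurally
        forbidden transitions are exactly 0."""
        A = np.zeros((2 * N_CPG, 2 * N_CPG))
        for s in range(N_CPG):
            A[s, N_CPG + s] = 1.0                       # CpG -> own gap
            A[N_CPG + s, N_CPG + s] = self.gap_stay[s]  # gap self loop
            A[N_CPG + s, :N_CPG] = (1.0 - self.gap_stay[s]) * self.gap_to_cpg[s]
        return A

    # -- collapsed CpG->CpG kernels ---------------------------------------

    def log_kernel(self, d: int) -> np.ndarray:
        """(6, 6) log CpG-to-CpG kernel for two CpGs separated by d interval
        positions; cached per distance, exact in log space for any d."""
        if d < 0:
            raise ValueError("distance must be non-negative")
        d = min(int(d), D_MAX)
        cached = self._kernel_cache.get(d)
        if cached is not None:
            return cached
        stay = self.gap_stay
        dwell = max(d - 1, 0) * np.log(stay) + np.log1p(-stay)
        with np.errstate(divide="ignore"):
            logq = np.log(self.gap_to_cpg)
        out = dwell[:, None] + logq
        self._kernel_cache[d] = out
        return out

    def clear_cache(self) -> None:
        self._kernel_cache = {}


def effective_transition(params: HmmParams, d: int) -> np.ndarray:
    """Linear-space 12x12 one-step CpG-to-CpG kernel for gap length d.

    Only the CpG-row x CpG-column block is populated: entry (s, t) is the
    probability of leaving CpG state s, dwelling d interval positions in gap
    states, and arriving at CpG state t.  For d = 0 the instantaneous gap
    visit is marginalized out (equal to d = 1).  Computed from the explicit
    matrix power of the gap block, so it underflows for very large d; use
    ``HmmParams.log_kernel`` for log-space work.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    A = params.transition_matrix()
    A_cg = A[:N_CPG, N_CPG:]
    A_gg = A[N_CPG:, N_CPG:]
    A_gc = A[N_CPG:, :N_CPG]
    power = np.linalg.matrix_power(A_gg, max(int(d) - 1, 0))
    block = A_cg @ power @ A_gc
    out = np.zeros((2 * N_CPG, 2 * N_CPG))
    out[:N_CPG, :N_CPG] = block
    return out


def default_hmm(seed: int = 0) -> HmmParams:
    """Starting parameters: near-uniform allowed transitions with a small
    seeded unit asymmetry so EM can differentiate the basic and second
    units.  The jitter is replicated across Up/Down/NoCh, keeping the
    parameters exactly invariant under relabeling Up <-> Down (and hence the
    whole pipeline equivariant under swapping the two samples).  The initial
    distribution puts 0.9 on NoCh, split across units.
    """
    rng = np.random.default_rng(seed)
    # per-unit dwell asymmetry, same for every direction
    stay_unit = np.array([0.45, 0.55]) + rng.uniform(-0.02, 0.02, size=2)
    gap_stay = np.tile(stay_unit, N_DIR)

    # near-uniform exit targets; the second unit slightly favors keeping its
    # direction, the basic unit slightly favors leaving it
    bias_unit = np.array([-0.05, 0.05]) + rng.uniform(-0.01, 0.01, size=2)
    q = np.zeros((N_CPG, N_CPG))
    for x in range(N_DIR):
        for uu in range(N_UNIT):
            row = np.full(N_CPG, 1.0 / N_CPG)
            for v in range(N_UNIT):
                row[state_index(x, v)] += bias_unit[uu] / N_UNIT
            row = np.clip(row, 1e-6, None)
            q[state_index(x, uu)] = row / row.sum()

    initial = np.zeros(N_CPG)
    initial[[state_index(NOCH, 0), state_index(NOCH, 1)]] = 0.45
    initial[[state_index(UP, 0), state_index(UP, 1)]] = 0.025
    initial[[state_index(DOWN, 0), state_index(DOWN, 1)]] = 0.025
    return HmmParams(gap_stay=gap_stay, gap_to_cpg=q, initial=initial)


# ---------------------------------------------------------------------------
# forward / backward


def _expand_emissions(log_e3: np.ndarray) -> np.ndarray:
    """(L, 3) per-direction log emissions -> (L, 6) per-CpG-state values
    (the two units share emission functions)."""
    return np.repeat(log_e3, N_UNIT, axis=1)


def _sum_states(X: np.ndarray, axis: int) -> np.ndarray:
    """Sum over a 6-state axis with a fixed reduction tree: units within each
    direction first, then (Up + Down) + NoCh.  The tree is invariant under
    relabeling Up <-> Down, which keeps the whole EM bit-exactly equivariant
    when the two samples are exchanged."""
    Xr = np.moveaxis(X, axis, -1)
    s = Xr.reshape(Xr.shape[:-1] + (N_DIR, N_UNIT)).sum(axis=-1)
    return (s[..., 0] + s[..., 1]) + s[..., 2]


def _lse(M: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp along a 6-state axis with -inf handled (no nan) and the
    direction-symmetric reduction tree of :func:`_sum_states`."""
    m = M.max(axis=axis)
    finite = np.isfinite(m)
    safe = np.where(finite, m, 0.0)
    with np.errstate(invalid="ignore"):
        out = safe + np.log(_sum_states(np.exp(M - np.expand_dims(safe, axis)),
                                        axis))
    return np.where(finite, out, -np.inf)


def _dwell_terms(gaps: np.ndarray, params: HmmParams) -> np.ndarray:
    """(L-1, 6) log dwell factor (d-1) log a + log(1-a) per step and source
    state; this is the row-constant part of the collapsed kernel."""
    d = np.minimum(np.maximum(gaps - 1, 0), D_MAX - 1).astype(float)
    return d[:, None] * np.log(params.gap_stay)[None, :] \
        + np.log1p(-params.gap_stay)[None, :]


def _chain_arrays(emissions, gaps):
    log_e3 = emissions.log_e if hasattr(emissions, "log_e") else np.asarray(emissions, float)
    gaps = np.asarray(gaps, dtype=np.int64)
    if len(log_e3) == 0:
        raise ValueError("empty chain")
    if len(gaps) != len(log_e3) - 1:
        raise ValueError("need one gap length per adjacent site pair")
    if np.any(gaps < 0):
        raise ValueError("gap lengths must be non-negative")
    return log_e3, gaps


def _forward(log_e6, dwell, logq, log_pi):
    L = len(log_e6)
    la = np.empty((L, N_CPG))
    la[0] = log_pi + log_e6[0]
    for i in range(L - 1):
        la[i + 1] = _lse((la[i] + dwell[i])[:, None] + logq, axis=0) + log_e6[i + 1]
    return la


def _backward(log_e6, dwell, logq):
    L = len(log_e6)
    lb = np.zeros((L, N_CPG))
    for i in range(L - 2, -1, -1):
        lb[i] = dwell[i] + _lse(logq + (log_e6[i + 1] + lb[i + 1])[None, :], axis=1)
    return lb


def forward_backward(emissions, gaps, params: HmmParams):
    """Log-space forward/backward over the CpG steps of one chromosome.

    Parameters
    ----------
    emissions : EmissionTable or (L, 3) array of per-direction log emissions.
    gaps : (L-1,) inter-CpG gap lengths (interval positions, >= 0).
    params : HmmParams.

    Returns
    -------
    (log_likelihood, posteriors) where posteriors is an (L, 3) array of
    per-site state probabilities over (Up, Down, NoCh), units marginalized.
    """
    log_e3, gaps = _chain_arrays(emissions, gaps)
    log_e6 = _expand_emissions(log_e3)
    dwell = _dwell_terms(gaps, params)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        logq = np.log(params.gap_to_cpg)
    la = _forward(log_e6, dwell, logq, log_pi)
    lb = _backward(log_e6, dwell, logq)
    ll = float(_lse(la[-1], axis=0))
    ll_b = float(_lse(log_pi + log_e6[0] + lb[0], axis=0))
    if not np.isclose(ll, ll_b, rtol=1e-9, atol=1e-9):
        raise FloatingPointError(f"forward/backward disagree: {ll} vs {ll_b}")
    post6 = np.exp(la + lb - ll)
    post3 = post6.reshape(len(log_e6), N_DIR, N_UNIT).sum(axis=2)
    post3 /= post3.sum(axis=1, keepdims=True)
    return ll, post3


# ---------------------------------------------------------------------------
# Baum-Welch on transitions (emissions fixed)


def _expected_counts(log_e3, gaps, params):
    """One E-step on one chain: log-likelihood plus expected sufficient
    statistics (gap self-loops, gap exits, exit-target counts, initial)."""
    log_e6 = _expand_emissions(log_e3)
    gaps = np.asarray(gaps, dtype=np.int64)
    dwell = _dwell_terms(gaps, params)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        logq = np.log(params.gap_to_cpg)
    la = _forward(log_e6, dwell, logq, log_pi)
    lb = _backward(log_e6, dwell, logq)
    ll = float(_lse(la[-1], axis=0))

    L = len(log_e6)
    q_num = np.zeros((N_CPG, N_CPG))
    self_num = np.zeros(N_CPG)
    exit_num = np.zeros(N_CPG)
    if L > 1:
        K = dwell[:, :, None] + logq[None, :, :]      # (L-1, 6, 6)
        xi = np.exp(la[:-1, :, None] + K + (log_e6[1:] + lb[1:])[:, None, :] - ll)
        q_num = xi.sum(axis=0)
        per_source = _sum_states(xi, axis=2)          # (L-1, 6)
        dwell = np.maximum(gaps - 1, 0).astype(float)
        self_num = (dwell[:, None] * per_source).sum(axis=0)
        exit_num = per_source.sum(axis=0)
    gamma0 = np.exp(la[0] + lb[0] - ll)
    return ll, q_num, self_num, exit_num, gamma0


def fit_transitions(emissions, gaps, init: HmmParams, tol: float = 1e-4,
                    max_iter: int = 100):
    """Baum-Welch estimation of transition and initial probabilities with
    emissions held fixed; see :func:`fit_transitions_chains` for multiple
    chromosomes.  Returns (HmmParams, per-iteration log-likelihood list)."""
    log_e3, gaps = _chain_arrays(emissions, gaps)
    return fit_transitions_chains([(log_e3, gaps)], init, tol=tol, max_iter=max_iter)


def fit_transitions_chains(chains, init: HmmParams, tol: float = 1e-4,
                           max_iter: int = 100):
    """Baum-Welch over several independent chains (chromosomes).

    ``chains`` is a list of (log_e3, gaps) pairs.  The gap self-loop update
    uses the analytic expected dwell of the collapsed geometric runs
    (d - 1 self-loops and one exit per traversed gap), so the update is the
    exact EM M-step and the log-likelihood is non-decreasing.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    params = init
    history: list[float] = []
    for _ in range(max_iter):
        ll_tot = 0.0
        q_num = np.zeros((N_CPG, N_CPG))
        self_num = np.zeros(N_CPG)
        exit_num = np.zeros(N_CPG)
        pi_num = np.zeros(N_CPG)
        for log_e3, gaps in chains:
            ll, qn, sn, en, g0 = _expected_counts(np.asarray(log_e3, float),
                                                  gaps, params)
            ll_tot += ll
            q_num += qn
            self_num += sn
            exit_num += en
            pi_num += g0
        if history and ll_tot - history[-1] < tol:
            history.append(ll_tot)
            break
        history.append(ll_tot)

        row_tot = _sum_states(q_num, axis=1)[:, None]
        q = np.where(row_tot > 0, q_num / np.maximum(row_tot, 1e-300),
                     params.gap_to_cpg)
        q /= _sum_states(q, axis=1)[:, None]
        denom = self_num + exit_num
        stay = np.where(denom > 0,
                        self_num / np.maximum(denom, 1e-300), params.gap_stay)
        # exact zeros/ones only arise in degenerate chains; keep logs finite
        stay = np.clip(stay, 1e-10, 1 - 1e-10)
        pi = pi_num / _sum_states(pi_num, axis=0)
        params = HmmParams(gap_stay=stay, gap_to_cpg=q, initial=pi)
    return params, history
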
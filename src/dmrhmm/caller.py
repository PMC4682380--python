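"""Log-likelihood-ratio scoring and extraction of ranked DMRs.

A candidate region [s, e] in direction ``dir`` (Up or Down) is scored as the
log ratio between the best constrained state path that is in ``dir`` on
sites s..e and in NoCh everywhere else, and the best all-NoCh path.  Units
(basic/second) are collapsed before scoring by taking, per CpG step, the
most probable (unit, unit) choice of the effective transition kernel — a
Viterbi-style collapse that makes the score an exact sum of per-site
increments:

    score(s, e, dir) = sum_{i=s..e} (logE_dir[i] - logE_NoCh[i])
                     + entry/exit boundary log transition ratios
                     + within-region log transition ratios (dir vs NoCh).

Because the score is additive, all disjoint positive-scoring segments can be
recovered exactly by a linear dynamic program over the three macro states
(outside, inside-Up, inside-Down), maximizing the total score of a disjoint
segment set with every segment above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emissions import DOWN, NOCH, UP
from .hmm import N_UNIT, HmmParams

_DIR_NAME = {UP: "Up", DOWN: "Down"}
_DIR_INDEX = {"Up": UP, "Down": DOWN}


@dataclass(frozen=True)
class Dmr:
    """A scored, directed differentially methylated region.

    ``start``/``end`` are 0-based half-open genomic coordinates spanning the
    first to last CpG dinucleotide of the region (end = last CpG position
    + 2); ``direction`` is "Up" (hypermethylated in sample 1) or "Down";
    ``score`` is the log-likelihood ratio in nats; ``n_cpg`` the number of
    CpG sites covered.
    """

    chrom: str
    start: int
    end: int
    direction: str
    score: float
    n_cpg: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")


def collapsed_log_kernel(params: HmmParams, d: int) -> np.ndarray:
    """(3, 3) per-direction log kernel at distance d: max over the unit
    pair of the 6x6 collapsed CpG-to-CpG kernel."""
    k6 = params.log_kernel(int(d))
    k = k6.reshape(3, N_UNIT, 3, N_UNIT)
    return k.max(axis=(1, 3))


def collapsed_log_initial(params: HmmParams) -> np.ndarray:
    """(3,) per-direction log initial weight (max over units)."""
    with np.errstate(divide="ignore"):
        li = np.log(params.initial)
    return li.reshape(3, N_UNIT).max(axis=1)


class _Increments:
    """Precomputed per-site score increments for one chromosome chain."""

    def __init__(self, emissions, gaps, params: HmmParams):
        log_e3 = emissions.log_e if hasattr(emissions, "log_e") else np.asarray(emissions, float)
        gaps = np.asarray(gaps, dtype=np.int64)
        L = len(log_e3)
        if L == 0:
            raise ValueError("empty chain")
        if len(gaps) != L - 1:
            raise ValueError("need one gap length per adjacent site pair")
        self.L = L
        # emission log ratios vs NoCh, columns (Up, Down)
        self.g = log_e3[:, [UP, DOWN]] - log_e3[:, [NOCH, NOCH]]
        # per-gap collapsed kernels relative to the NoCh->NoCh baseline
        kernels = {}
        self.within = np.zeros((max(L - 1, 0), 2))   # dir->dir minus N->N
        self.enter = np.zeros((max(L - 1, 0), 2))    # N->dir minus N->N
        self.leave = np.zeros((max(L - 1, 0), 2))    # dir->N minus N->N
        for i, d in enumerate(gaps):
            d = int(d)
            M = kernels.get(d)
            if M is None:
                M = collapsed_log_kernel(params, d)
                kernels[d] = M
            base = M[NOCH, NOCH]
            for j, x in enumerate((UP, DOWN)):
                self.within[i, j] = M[x, x] - base
                self.enter[i, j] = M[NOCH, x] - base
                self.leave[i, j] = M[x, NOCH] - base
        li = collapsed_log_initial(params)
        self.init_ratio = np.array([li[UP] - li[NOCH], li[DOWN] - li[NOCH]])

    def segment_score(self, s: int, e: int, j: int) -> float:
        """Score of sites s..e in direction index j (0=Up, 1=Down)."""
        total = self.init_ratio[j] if s == 0 else self.enter[s - 1, j]
        total += self.g[s:e + 1, j].sum()
        if e > s:
            total += self.within[s:e, j].sum()
        if e < self.L - 1:
            total += self.leave[e, j]
        return float(total)


def score_region(emissions, gaps, params: HmmParams, s: int, e: int,
                 direction: str) -> float:
    """Log-likelihood ratio of the constrained directional path over the
    all-NoCh path for sites s..e (inclusive) of one chromosome chain."""
    if direction not in _DIR_INDEX:
        raise ValueError("direction must be 'Up' or 'Down'")
    if e < s:
        raise ValueError("region end before start")
    inc = _Increments(emissions, gaps, params)
    if e >= inc.L:
        raise ValueError("region exceeds chain length")
    return inc.segment_score(s, e, _DIR_INDEX[direction])


def extract_dmrs(emissions, gaps, positions, params: HmmParams, *,
                 chrom: str = "chr", threshold: float = 0.0) -> list[Dmr]:
    """All disjoint DMRs with score > threshold on one chromosome chain,
    ranked by descending score (ties by start).

    A joint linear DP over macro states {outside, inside-Up, inside-Down}
    maximizes the total score of a disjoint segment set; a segment may close
    only if its own score exceeds the threshold, and overlapping Up/Down
    candidates are resolved by the same maximization.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    inc = _Increments(emissions, gaps, params)
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) != inc.L:
        raise ValueError("positions must match emission table length")

    L = inc.L
    # f[i]: best total of disjoint closed segments within sites 0..i-1
    # (nothing open at site i, site i not inside a segment); a segment may
    # end at i-1, so adjacent segments (close at i-1, open at i) are allowed
    # as in the additive sum-of-scores semantics.
    # h[j][i]: best (base, seg) with a direction-j segment open covering i.
    f = np.empty(L)
    f_from = np.empty(L, dtype=np.int64)          # -1 stay outside, j close dir j
    h_base = np.empty((2, L))
    h_seg = np.empty((2, L))
    h_start = np.zeros((2, L), dtype=np.int64)

    f[0] = 0.0
    f_from[0] = -1
    for j in range(2):
        h_base[j, 0] = 0.0
        h_seg[j, 0] = inc.init_ratio[j] + inc.g[0, j]
        h_start[j, 0] = 0
    for i in range(1, L):
        # outside state first: stay outside, or close a segment ending at i-1
        best, frm = f[i - 1], -1
        for j in range(2):
            closed_seg = h_seg[j, i - 1] + inc.leave[i - 1, j]
            if closed_seg > threshold:
                tot = h_base[j, i - 1] + closed_seg
                if tot > best:
                    best, frm = tot, j
        f[i] = best
        f_from[i] = frm
        # open states: extend, or open fresh on top of f[i]
        for j in range(2):
            open_seg = inc.enter[i - 1, j] + inc.g[i, j]
            ext_seg = h_seg[j, i - 1] + inc.within[i - 1, j] + inc.g[i, j]
            open_tot = f[i] + open_seg
            ext_tot = h_base[j, i - 1] + ext_seg
            if ext_tot >= open_tot:
                h_base[j, i] = h_base[j, i - 1]
                h_seg[j, i] = ext_seg
                h_start[j, i] = h_start[j, i - 1]
            else:
                h_base[j, i] = f[i]
                h_seg[j, i] = open_seg
                h_start[j, i] = i

    # terminal: end outside, or with a segment running through the last site
    best, end_state = f[L - 1], -1
    for j in range(2):
        if h_seg[j, L - 1] > threshold:
            tot = h_base[j, L - 1] + h_seg[j, L - 1]
            if tot > best:
                best, end_state = tot, j

    # traceback: each recorded segment opened on top of f[its start]
    segments: list[tuple[int, int, int]] = []  # (start, end, dir index)
    if end_state >= 0:
        s = int(h_start[end_state, L - 1])
        segments.append((s, L - 1, end_state))
        i = s
    else:
        i = L - 1
    while i >= 0:
        frm = int(f_from[i])
        if frm == -1:
            i -= 1
        else:
            e2 = i - 1
            s2 = int(h_start[frm, e2])
            segments.append((s2, e2, frm))
            i = s2

    dmrs = []
    for s, e, j in segments:
        score = inc.segment_score(s, e, j)
        dmrs.append(Dmr(chrom=chrom, start=int(positions[s]),
                        end=int(positions[e]) + 2,
                        direction=_DIR_NAME[UP if j == 0 else DOWN],
                        score=score, n_cpg=e - s + 1))
    dmrs.sort(key=lambda d: (-d.score, d.chrom, d.start))
    return dmrs


def rank_dmrs(dmrs) -> list[Dmr]:
    """Global ranking by descending score, ties by (chrom, start)."""
    return sorted(dmrs, key=lambda d: (-d.score, d.chrom, d.start))
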
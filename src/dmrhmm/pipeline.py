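"""End-to-end detection pipeline: mixtures -> emissions -> HMM -> DMRs.

This is the programmatic equivalent of running ``fit`` followed by
``detect``: subsample covered sites, fit the per-sample beta mixtures,
compute emissions (beta-mixture or legacy pseudocount), learn transition
probabilities by Baum-Welch, and extract ranked DMRs per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import caller, emissions as em, hmm as hmm_mod, mixture as mx
from .counts import CpGTable


@dataclass
class DetectionResult:
    dmrs: list                       # globally ranked
    mix1: mx.BetaMixture | None
    mix2: mx.BetaMixture | None
    hmm: hmm_mod.HmmParams
    mixture_ll: dict = field(default_factory=dict)   # per-sample EM traces
    hmm_ll: list = field(default_factory=list)       # Baum-Welch trace


def fit_mixtures(table: CpGTable, n_sites: int = 10000, seed: int = 0,
                 shared_sites: bool = True, tol: float = 1e-6,
                 max_iter: int = 500):
    """Fit the two per-sample level mixtures on a site subsample.

    With ``shared_sites`` (default) one subsample of sites covered in both
    samples feeds both fits, which keeps the result exactly symmetric under
    exchanging the samples; otherwise each sample subsamples its own
    covered sites independently.
    """
    if shared_sites:
        c1, c2 = mx.subsample_shared_sites(table, n_sites, seed)
    else:
        c1 = mx.subsample_sites(table, 1, n_sites, seed)
        c2 = mx.subsample_sites(table, 2, n_sites, seed)
    mix1, log1 = mx.fit_beta_mixture(c1, tol=tol, max_iter=max_iter)
    mix2, log2 = mx.fit_beta_mixture(c2, tol=tol, max_iter=max_iter)
    return mix1, mix2, {"sample1": log1, "sample2": log2}


def _chains(table: CpGTable, etable: em.EmissionTable):
    """Split the emission table into per-chromosome (log_e, gaps, positions,
    chrom) chains; gap length = pos[i+1] - pos[i] - 1 interval positions."""
    out = []
    offset = 0
    for chrom, sub in table.per_chromosome():
        L = len(sub)
        pos = sub.df["pos"].to_numpy()
        gaps = np.maximum(np.diff(pos) - 1, 0)
        out.append((chrom, etable.log_e[offset:offset + L], gaps, pos))
        offset += L
    return out


def run_detection(table: CpGTable, *, emission_mode: str = "new",
                  pseudo: float | None = None, n_sites: int = 10000,
                  seed: int = 0, threshold: float = 0.0,
                  top: int | None = None, shared_sites: bool = True,
                  mixtures=None, hmm_init=None,
                  mixture_tol: float = 1e-6, mixture_max_iter: int = 500,
                  hmm_tol: float = 1e-4, hmm_max_iter: int = 100,
                  ) -> DetectionResult:
    """Run the full detection pipeline on a two-sample count table.

    Parameters
    ----------
    emission_mode : "new" (beta-mixture emissions) or "legacy"
        (pseudocount emissions; requires ``pseudo``).
    mixtures : optional (mix1, mix2) to reuse a previous fit.
    hmm_init : optional HmmParams to start Baum-Welch from.
    top : keep only the top-ranked DMRs if given.
    """
    mix_ll: dict = {}
    if emission_mode == "new":
        if mixtures is not None:
            mix1, mix2 = mixtures
        else:
            mix1, mix2, mix_ll = fit_mixtures(table, n_sites=n_sites, seed=seed,
                                              shared_sites=shared_sites,
                                              tol=mixture_tol,
                                              max_iter=mixture_max_iter)
        etable = em.compute_emissions(table, mix1, mix2)
    elif emission_mode == "legacy":
        if pseudo is None:
            raise ValueError("legacy emission mode requires pseudo")
        mix1 = mix2 = None
        etable = em.compute_legacy_emissions(table, em.LegacyEmissionConfig(pseudo))
    else:
        raise ValueError(f"unknown emission mode {emission_mode!r}")

    chains = _chains(table, etable)
    init = hmm_init if hmm_init is not None else hmm_mod.default_hmm(seed)
    params, hmm_ll = hmm_mod.fit_transitions_chains(
        [(log_e, gaps) for _, log_e, gaps, _ in chains], init,
        tol=hmm_tol, max_iter=hmm_max_iter)

    dmrs = []
    for chrom, log_e, gaps, pos in chains:
        dmrs.extend(caller.extract_dmrs(log_e, gaps, pos, params,
                                        chrom=chrom, threshold=threshold))
    dmrs = caller.rank_dmrs(dmrs)
    if top is not None:
        dmrs = dmrs[:top]
    return DetectionResult(dmrs=dmrs, mix1=mix1, mix2=mix2, hmm=params,
                           mixture_ll=mix_ll, hmm_ll=hmm_ll)
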
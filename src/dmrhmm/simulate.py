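"""Count-level simulator of two-sample bisulfite-seq data with planted DMRs.

The generator emulates the standard planted-region benchmark at the level of
per-CpG read counts (no read sequences or alignment): CpG positions are
drawn from a two-component geometric spacing mixture (dense "island" spacing
plus sparse background), every site receives a baseline methylation level
from a bimodal beta-mixture prior shared by both samples, a set of
non-overlapping regions is planted in which the methylation level switches
fully between the samples (Up regions: sample 1 forced to the maximum and
sample 2 to the minimum; Down regions mirrored), and read counts are drawn
per site as n ~ Poisson(depth),
m ~ Binomial(n, theta'), where theta' folds in a small bisulfite
conversion/sequencing error.  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import Dmr
from .counts import COLUMNS, CpGTable
from .mixture import BetaMixture

DEFAULT_LEVEL_MODEL = BetaMixture(w_h=0.5, w_l=0.45, w_unif=0.05,
                                  alpha_h=8.0, beta_l=8.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    ``dmr_length`` is a genomic target in bp; at the default spacing
    (25% island spacing with mean 15 bp, 75% background with mean 120 bp,
    ~94 bp overall) the default 5000 bp regions hold roughly 50 CpGs.

    ``switch_mode`` selects how planted regions differ between samples:
    ``"both"`` (default) forces a full methylation switch — sample 1 to the
    maximum and sample 2 to the minimum for Up regions, mirrored for Down —
    so the planted direction holds at every CpG of the region;
    ``"sample2"`` changes only sample 2 (sample 1 keeps its baseline
    levels), which leaves baseline-low sites inside an Up region
    non-differential and makes truth regions mosaics.
    """

    n_cpg: int = 20000
    n_dmr: int = 50
    dmr_length: int = 5000
    depth: float = 10.0
    conversion_error: float = 0.005
    island_weight: float = 0.25
    mean_spacing_island: float = 15.0
    mean_spacing_background: float = 120.0
    level_model: BetaMixture = field(default_factory=lambda: DEFAULT_LEVEL_MODEL)
    switch_mode: str = "both"
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        if self.n_cpg < 1 or self.n_dmr < 0:
            raise ValueError("n_cpg must be >= 1 and n_dmr >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.conversion_error < 0.5):
            raise ValueError("conversion_error must be in [0, 0.5)")
        if self.dmr_length < 2:
            raise ValueError("dmr_length must cover at least one CpG")
        if self.switch_mode not in ("both", "sample2"):
            raise ValueError("switch_mode must be 'both' or 'sample2'")


@dataclass(frozen=True)
class SimResult:
    """Full generator state: the count table, the truth list, and the
    per-site levels actually used (before the error flip)."""

    table: CpGTable
    truth: list[Dmr]
    positions: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray


def _draw_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    comp = rng.random(cfg.n_cpg) < cfg.island_weight
    mean = np.where(comp, cfg.mean_spacing_island, cfg.mean_spacing_background)
    # geometric spacings with a floor of 2 bp (CpG dinucleotides cannot overlap)
    p = 1.0 / np.maximum(mean - 1.0, 1.0)
    spacing = 1 + rng.geometric(np.clip(p, 1e-9, 1.0))
    pos = np.cumsum(spacing) + 1000
    return pos.astype(np.int64)


def _place_regions(cfg: SimConfig, positions: np.ndarray,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    span_lo, span_hi = int(positions[0]), int(positions[-1])
    if cfg.n_dmr * cfg.dmr_length > (span_hi - span_lo):
        raise ValueError("planted DMRs exceed the simulated genome span")
    regions: list[tuple[int, int]] = []
    attempts = 0
    while len(regions) < cfg.n_dmr:
        attempts += 1
        if attempts > 1000 * max(cfg.n_dmr, 1):
            raise ValueError("could not place non-overlapping DMRs; genome too small")
        start = int(rng.integers(span_lo, span_hi - cfg.dmr_length))
        end = start + cfg.dmr_length
        if any(start < e and s < end for s, e in regions):
            continue
        inside = (positions >= start) & (positions < end)
        if not inside.any():
            continue
        regions.append((start, end))
    regions.sort()
    return regions


def simulate_dataset(config: SimConfig, *, full_output: bool = False):
    """Generate a two-sample count table with planted DMRs.

    Returns ``(CpGTable, truth)`` where ``truth`` is a list of
    :class:`~dmrhmm.caller.Dmr` records (score 0) whose intervals span the
    CpG dinucleotides inside each planted region.  With
    ``full_output=True`` a :class:`SimResult` with the internal level
    assignments is returned instead.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    positions = _draw_positions(cfg, rng)

    # baseline levels shared by both samples
    mix = cfg.level_model
    comp = rng.choice(3, size=cfg.n_cpg, p=mix.weights)
    theta = np.empty(cfg.n_cpg)
    theta[comp == 0] = rng.beta(mix.alpha_h, mix.beta_h, size=(comp == 0).sum())
    theta[comp == 1] = rng.beta(mix.alpha_l, mix.beta_l, size=(comp == 1).sum())
    theta[comp == 2] = rng.random((comp == 2).sum())

    regions = _place_regions(cfg, positions, rng)
    directions = np.where(rng.random(len(regions)) < 0.5, "Up", "Down")

    theta1 = theta.copy()
    theta2 = theta.copy()
    truth: list[Dmr] = []
    for (start, end), direction in zip(regions, directions):
        inside = (positions >= start) & (positions < end)
        # Up = hypermethylated in sample 1: sample 2 forced to the minimum
        theta2[inside] = 0.0 if direction == "Up" else 1.0
        if cfg.switch_mode == "both":
            theta1[inside] = 1.0 if direction == "Up" else 0.0
        first = int(positions[inside][0])
        last = int(positions[inside][-1])
        truth.append(Dmr(chrom=cfg.chrom, start=first, end=last + 2,
                         direction=str(direction), score=0.0,
                         n_cpg=int(inside.sum())))

    eps = cfg.conversion_error
    th1 = theta1 * (1 - eps) + (1 - theta1) * eps
    th2 = theta2 * (1 - eps) + (1 - theta2) * eps
    n1 = rng.poisson(cfg.depth, size=cfg.n_cpg)
    n2 = rng.poisson(cfg.depth, size=cfg.n_cpg)
    m1 = rng.binomial(n1, th1)
    m2 = rng.binomial(n2, th2)

    df = pd.DataFrame({"chrom": cfg.chrom, "pos": positions,
                       "m1": m1, "u1": n1 - m1,
                       "m2": m2, "u2": n2 - m2})[list(COLUMNS)]
    table = CpGTable(df)
    if full_output:
        return SimResult(table=table, truth=truth, positions=positions,
                         theta1=theta1, theta2=theta2)
    return table, truth


def write_truth(truth: list[Dmr], path) -> None:
    """Write planted regions as a BED file (strand = direction)."""
    with open(path, "w") as fh:
        fh.write("# planted DMRs; strand + = Up (hypermethylated in sample 1)\n")
        for i, d in enumerate(truth, start=1):
            strand = "+" if d.direction == "Up" else "-"
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tTRUE{i}\t0\t{strand}\n")
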
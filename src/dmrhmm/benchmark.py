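"""Reciprocal-overlap correctness metric for planted-DMR benchmarks.

A predicted region counts as a correct recovery of a true region if the two
intervals reciprocally overlap in at least a given fraction of BOTH their
lengths — so neither a sliver of a huge call nor a sliver of a huge truth
region passes.  Accuracy in the top-k calls is the number of true regions
recovered by the k highest-ranked predictions divided by k (the benchmark
plants as many regions as it ranks, so the rate is precision and recall at
once).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OverlapCriterion:
    """Required reciprocal-overlap fraction, e.g. 0.5, 0.9 or 0.99."""

    fraction: float

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")


def _interval(x):
    if hasattr(x, "chrom"):
        return x.chrom, int(x.start), int(x.end)
    chrom, start, end = x[0], int(x[1]), int(x[2])
    return chrom, start, end


def reciprocal_overlap(a, b) -> float:
    """min(|a ∩ b| / |a|, |a ∩ b| / |b|) for half-open intervals; 0 across
    chromosomes.  Accepts Dmr-like objects or (chrom, start, end) tuples."""
    ca, sa, ea = _interval(a)
    cb, sb, eb = _interval(b)
    if ea <= sa or eb <= sb:
        raise ValueError("zero-length interval")
    if ca != cb:
        return 0.0
    inter = min(ea, eb) - max(sa, sb)
    if inter <= 0:
        return 0.0
    return min(inter / (ea - sa), inter / (eb - sb))


def accuracy_at(predicted, truth, k: int, criterion: OverlapCriterion,
                match_direction: bool = True) -> float:
    """Fraction of the top-k predictions that recover distinct true regions.

    Predictions are consumed in rank order; each prediction can match at
    most one still-unmatched truth region (the one it overlaps best), and a
    match requires reciprocal overlap >= ``criterion.fraction`` plus, if
    ``match_direction``, agreement of the Up/Down call.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    top = list(predicted)[:k]
    unmatched = list(range(len(truth)))
    correct = 0
    for pred in top:
        best_j, best_ov = None, 0.0
        for j in unmatched:
            t = truth[j]
            if match_direction and getattr(t, "direction", None) is not None \
                    and getattr(pred, "direction", None) != t.direction:
                continue
            ov = reciprocal_overlap(pred, t)
            if ov >= criterion.fraction and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            unmatched.remove(best_j)
            correct += 1
    return correct / k
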
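"""Per-CpG two-sample read-count tables: parsing, validation, strand merging,
and BED output of ranked DMRs.

The central container is :class:`CpGTable`, a thin, validated wrapper around a
pandas DataFrame with columns ``chrom, pos, m1, u1, m2, u2``.  ``m`` counts
reads supporting methylation at the CpG cytosine (C-C matches after bisulfite
conversion), ``u`` counts reads not supporting it (C-T mismatches).
Coordinates are 0-based positions of the plus-strand cytosine; intervals are
half-open BED-style throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ("chrom", "pos", "m1", "u1", "m2", "u2")


class FormatError(ValueError):
    """Raised for malformed count input (bad counts, duplicates, wrong shape)."""


@dataclass(frozen=True)
class CpGRecord:
    """A single CpG site with methylated/unmethylated counts for two samples."""

    chrom: str
    pos: int
    m1: int
    u1: int
    m2: int
    u2: int

    @property
    def n1(self) -> int:
        return self.m1 + self.u1

    @property
    def n2(self) -> int:
        return self.m2 + self.u2


class CpGTable:
    """Ordered per-CpG count records, grouped by chromosome.

    Invariants enforced at construction: non-negative integer counts, no
    duplicate (chrom, pos), strictly increasing positions within each
    chromosome (input is sorted if needed, with a warning).
    """

    def __init__(self, df: pd.DataFrame, *, _validated: bool = False):
        if not _validated:
            df = _validate_frame(df)
        self.df = df

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple | CpGRecord]) -> "CpGTable":
        rows = []
        for r in records:
            if isinstance(r, CpGRecord):
                rows.append((r.chrom, r.pos, r.m1, r.u1, r.m2, r.u2))
            else:
                rows.append(tuple(r))
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CpGRecord]:
        for row in self.df.itertuples(index=False):
            yield CpGRecord(row.chrom, int(row.pos), int(row.m1), int(row.u1),
                            int(row.m2), int(row.u2))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CpGTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    # -- derived views -----------------------------------------------------

    @property
    def n1(self) -> np.ndarray:
        return (self.df["m1"] + self.df["u1"]).to_numpy()

    @property
    def n2(self) -> np.ndarray:
        return (self.df["m2"] + self.df["u2"]).to_numpy()

    def chromosomes(self) -> list[str]:
        return list(self.df["chrom"].unique())

    def per_chromosome(self) -> Iterator[tuple[str, "CpGTable"]]:
        """Yield (chrom, sub-table) in chromosome order of first appearance."""
        for chrom in self.chromosomes():
            sub = self.df[self.df["chrom"] == chrom].reset_index(drop=True)
            yield chrom, CpGTable(sub, _validated=True)

    def swap_samples(self) -> "CpGTable":
        """Return the table with samples 1 and 2 exchanged."""
        df = self.df[["chrom", "pos", "m2", "u2", "m1", "u1"]].copy()
        df.columns = list(COLUMNS)
        return CpGTable(df, _validated=True)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    for c in ("m1", "u1", "m2", "u2"):
        vals = df[c].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.asarray(vals, dtype=float) == np.floor(vals)):
                raise FormatError(f"non-integer count in column {c}")
            df[c] = vals.astype(np.int64)
        if (df[c] < 0).any():
            raise FormatError(f"negative count in column {c}")
    df["pos"] = df["pos"].astype(np.int64)
    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise FormatError(f"duplicate site {dup['chrom']}:{dup['pos']}")
    # per-chromosome sortedness: stable sort only if needed
    sorted_ok = True
    for _, g in df.groupby("chrom", sort=False):
        p = g["pos"].to_numpy()
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            sorted_ok = False
            break
    if not sorted_ok:
        logger.warning("input sites not position-sorted; sorting")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# readers


def read_cpg_table(path, format: str = "tsv", *, one_based: bool = False) -> CpGTable:
    """Read a per-CpG two-sample count table.

    ``format="tsv"``: TAB-separated with 6 columns
    ``chrom pos m1 u1 m2 u2``; lines starting with ``#`` are comments.
    ``format="bedgraph-pair"`` is handled by :func:`read_bedgraph_pair`
    (two files, one per sample).

    With ``one_based=True`` the position column is converted to 0-based.
    """
    if format == "bedgraph-pair":
        raise ValueError("bedgraph-pair input takes two paths; use read_bedgraph_pair")
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                nums = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            pos, m1, u1, m2, u2 = nums
            if min(m1, u1, m2, u2) < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if pos < (1 if one_based else 0):
                raise FormatError(f"{path}:{lineno}: bad position {pos}")
            rows.append((chrom, pos - (1 if one_based else 0), m1, u1, m2, u2))
    if not rows:
        raise FormatError(f"{path}: no data lines")
    return CpGTable(pd.DataFrame(rows, columns=COLUMNS))


def _read_bedgraph_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["chrom", "start", "end", "m", "u"],
                     dtype={"chrom": str})
    for c in ("start", "m", "u"):
        if (df[c] < 0).any():
            raise FormatError(f"{path}: negative value in column {c}")
    return df[["chrom", "start", "m", "u"]]


def read_bedgraph_pair(path_sample1, path_sample2) -> CpGTable:
    """Read two bedGraph-style count files (columns chrom start end m u),
    one per sample, and join them on (chrom, start).

    Sites present in only one file get zero counts in the other sample.
    """
    a = _read_bedgraph_counts(path_sample1).rename(columns={"m": "m1", "u": "u1"})
    b = _read_bedgraph_counts(path_sample2).rename(columns={"m": "m2", "u": "u2"})
    merged = a.merge(b, on=["chrom", "start"], how="outer")
    merged = merged.fillna(0).rename(columns={"start": "pos"})
    merged = merged[["chrom", "pos", "m1", "u1", "m2", "u2"]]
    for c in ("pos", "m1", "u1", "m2", "u2"):
        merged[c] = merged[c].astype(np.int64)
    return CpGTable(merged)


def merge_strands(plus: CpGTable, minus: CpGTable) -> CpGTable:
    """Merge per-strand counts into per-CpG-dinucleotide counts.

    A minus-strand cytosine at position p+1 belongs to the CpG whose
    plus-strand cytosine sits at p; its counts are added there.  Unpaired
    minus records are kept at their own position (logged).
    """
    if len(minus) == 0:
        return CpGTable(plus.df.copy(), _validated=True)
    p = plus.df.copy()
    m = minus.df.copy()
    m["pos"] = m["pos"] - 1  # candidate partner position
    key_p = set(zip(p["chrom"], p["pos"]))
    paired_mask = [((c, q) in key_p) for c, q in zip(m["chrom"], m["pos"])]
    paired_mask = np.asarray(paired_mask, dtype=bool)
    paired = m[paired_mask]
    unpaired = m[~paired_mask].copy()
    unpaired["pos"] = unpaired["pos"] + 1  # restore original position
    if len(unpaired):
        logger.info("merge_strands: %d unpaired minus-strand records kept as-is",
                    len(unpaired))
    merged = pd.concat([p, paired, unpaired], ignore_index=True)
    out = merged.groupby(["chrom", "pos"], sort=False, as_index=False).sum()
    return CpGTable(out[list(COLUMNS)])


# ---------------------------------------------------------------------------
# writers


def write_cpg_table(table: CpGTable, path) -> None:
    """Write a table in the 6-column counts-tsv format (exact round trip)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tm1\tu1\tm2\tu2\n")
        table.df.to_csv(fh, sep="\t", header=False, index=False)


def write_dmrs(dmrs, path, *, parameters: dict | None = None) -> None:
    """Write ranked DMRs as BED.

    Columns: chrom, start, end, name ``DMR<rank>``, score (2 decimals),
    strand (``+`` = Up i.e. hypermethylated in sample 1, ``-`` = Down),
    and the full-precision log-likelihood ratio in column 7.  Equal scores
    are ordered by (chrom, start).
    """
    dmrs = sorted(dmrs, key=lambda d: (-d.score, d.chrom, d.start))
    with open(path, "w") as fh:
        fh.write("# dmrhmm DMR calls; score = log-likelihood ratio (nats)\n")
        if parameters:
            for k, v in parameters.items():
                fh.write(f"# {k}={v}\n")
        for rank, d in enumerate(dmrs, start=1):
            strand = "+" if d.direction == "Up" else "-"
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tDMR{rank}\t"
                     f"{d.score:.2f}\t{strand}\t{d.score!r}\n")


def read_dmrs(path) -> list:
    """Read a DMR BED written by :func:`write_dmrs` (or any BED6 with strand
    encoding direction); returns Dmr objects ranked as in the file."""
    from .caller import Dmr

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            score = float(f[6]) if len(f) > 6 else (float(f[4]) if len(f) > 4 else 0.0)
            direction = "Up" if strand == "+" else "Down"
            out.append(Dmr(chrom=chrom, start=start, end=end,
                           direction=direction, score=score, n_cpg=0))
    return out
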
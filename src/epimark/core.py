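"""Genomic coordinate conventions and core domain types.

All coordinates are 0-based half-open ``[start, end)`` internally; GTF
(1-based closed) is converted at the I/O boundary.  Strand is one of
``+``, ``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class GeneModel:
    """Stranded gene with exon structure and a derived TSS.

    The TSS is the 5'-most transcribed base: ``interval.start`` on the
    plus strand, ``interval.end - 1`` on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    def upstream_window(self, span: int) -> GenomicInterval | None:
        """Strand-aware promoter window of ``span`` bp ending at the TSS.

        Plus strand: ``[TSS - span, TSS)``; minus strand the mirror image
        ``[TSS + 1, TSS + 1 + span)``.  Clipped at position 0; returns None
        for a zero-length window.
        """
        if span <= 0:
            return None
        if self.strand == "+":
            lo, hi = self.tss - span, self.tss
        else:
            lo, hi = self.tss + 1, self.tss + 1 + span
        lo = max(0, lo)
        if lo >= hi:
            return None
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def mark_window(self, window_up: int) -> GenomicInterval:
        """Strand-aware span from ``window_up`` bp upstream of the TSS to the
        gene end, used to associate peaks with a gene ("has the mark")."""
        if self.strand == "+":
            lo = max(0, self.interval.start - window_up)
            return GenomicInterval(self.chrom, lo, self.interval.end, "+")
        return GenomicInterval(
            self.chrom, self.interval.start, self.interval.end + window_up, "-"
        )


@dataclass
class Peak:
    """Scored enrichment interval from a peak caller (unstranded)."""

    peak_id: str
    interval: GenomicInterval
    score: float = 0.0
    sample: str = ""

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: negative score")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def centre(self) -> int:
        return self.interval.centre


class DensityTrack:
    """Binned normalized read density (reads-per-million style) per chromosome.

    Values are non-negative floats; array length is ceil(chrom_length / bin_size).
    """

    def __init__(self, bin_size: int, chrom_lengths: Mapping[str, int]):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        self.data: Dict[str, np.ndarray] = {
            c: np.zeros(math.ceil(length / bin_size), dtype=float)
            for c, length in self.chrom_lengths.items()
        }

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        """Add ``value`` to every bin overlapping ``[start, end)``."""
        arr = self.data[chrom]
        b0 = max(0, start // self.bin_size)
        b1 = min(len(arr), -(-end // self.bin_size))
        arr[b0:b1] += value

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base lookup; out-of-range positions return 0."""
        arr = self.data.get(chrom)
        if arr is None:
            return np.zeros(len(positions), dtype=float)
        pos = np.asarray(positions, dtype=np.int64)
        idx = pos // self.bin_size
        ok = (pos >= 0) & (idx < len(arr))
        out = np.zeros(len(pos), dtype=float)
        out[ok] = arr[idx[ok]]
        return out

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def scaled(self, factor: float) -> "DensityTrack":
        t = DensityTrack(self.bin_size, self.chrom_lengths)
        for c, arr in self.data.items():
            t.data[c] = arr * factor
        return t


def gene_density(
    genes: Iterable[GeneModel],
    chrom_lengths: Mapping[str, int],
    window: int = 10_000,
) -> DensityTrack:
    """Count gene TSSs per fixed genomic window (default 10 kb units).

    Windows are disjoint, so the counts sum to the number of genes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(genes, Mapping):
        genes = genes.values()
    track = DensityTrack(window, chrom_lengths)
    for g in genes:
        if g.chrom not in track.data:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        track.data[g.chrom][g.tss // window] += 1
    return track


# ---------------------------------------------------------------------------
# Interval-set arithmetic on (start, end) pair lists — used for genome
# background accounting where exact base counts matter.

Pairs = List[Tuple[int, int]]


def merge_pairs(pairs: Sequence[Tuple[int, int]]) -> Pairs:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    out: Pairs = []
    for s, e in sorted(p for p in pairs if p[0] < p[1]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_pairs(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]) -> Pairs:
    """Set difference a \\ b for merged, sorted interval lists."""
    b = merge_pairs(b)
    out: Pairs = []
    for s, e in merge_pairs(a):
        cur = s
        for bs, be in b:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_length(pairs: Sequence[Tuple[int, int]]) -> int:
    return sum(e - s for s, e in pairs)
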
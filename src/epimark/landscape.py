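"""Peak-to-feature classification, metagene/TSS profiling and concurrence
statistics for a histone mark such as H3K4me3.

A peak is assigned a single genomic-region label from its centre position
with the precedence promoter > exon > intron > intergenic, the accounting
convention of pie-chart peak-distribution summaries (UTRs count as exon,
downstream sequence as intergenic).  TSS-centred profiles rescale each gene
body to three equal parts plus fixed 1-kb flanks, so genes of different
lengths average onto a common axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from .core import (
    DensityTrack,
    GeneModel,
    Peak,
    merge_pairs,
    subtract_pairs,
    total_length,
)

log = logging.getLogger(__name__)

REGIONS = ("promoter", "exon", "intron", "intergenic")

# 70-bin metagene scheme: 20 x 50 bp upstream, 3 x 10 body bins, 20 x 50 bp
# downstream.
N_UP, N_BODY, N_DOWN = 20, 30, 20
FLANK = 1000


@dataclass
class RegionBreakdown:
    counts: Dict[str, float]
    mode: str  # "peaks" or "genome_background"

    @property
    def fractions(self) -> Dict[str, float]:
        total = sum(self.counts.values())
        return {r: self.counts[r] / total for r in REGIONS}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            {"region": REGIONS,
             "count": [self.counts[r] for r in REGIONS],
             "fraction": [fr[r] for r in REGIONS]}
        )


class RegionIndex:
    """Interval trees over promoters, exons and gene bodies for point lookup."""

    def __init__(self, genes: Mapping[str, GeneModel], promoter_span: int = 3000):
        self.promoter_span = promoter_span
        self._promoters: Dict[str, IntervalTree] = {}
        self._exons: Dict[str, IntervalTree] = {}
        self._bodies: Dict[str, IntervalTree] = {}
        for g in genes.values():
            prom = g.upstream_window(promoter_span)
            if prom is not None:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(prom.start, prom.end)
            for e in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(e.start, e.end)
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end
            )
        self._known_chroms = set(self._bodies)

    def classify(self, chrom: str, pos: int) -> str:
        if chrom not in self._known_chroms:
            return "intergenic"
        if self._promoters.get(chrom) and self._promoters[chrom][pos]:
            return "promoter"
        if self._exons.get(chrom) and self._exons[chrom][pos]:
            return "exon"
        if self._bodies[chrom][pos]:
            return "intron"
        return "intergenic"


def classify_peak_region(
    peak: Peak, genes: Mapping[str, GeneModel], promoter_span: int = 3000,
    index: RegionIndex | None = None,
) -> str:
    """Label a peak by its centre: promoter > exon > intron > intergenic.

    The promoter is the strand-aware ``promoter_span`` bp upstream of the
    TSS.  A centre on a chromosome with no annotated gene is intergenic.
    """
    if index is None:
        index = RegionIndex(genes, promoter_span)
    if peak.chrom not in index._known_chroms:
        log.warning("peak %s on unannotated chromosome %s", peak.peak_id, peak.chrom)
    return index.classify(peak.chrom, peak.centre)


def region_breakdown(
    genes: Mapping[str, GeneModel],
    chrom_lengths: Mapping[str, int],
    peaks: Sequence[Peak] | None = None,
    promoter_span: int = 3000,
) -> RegionBreakdown:
    """Region composition of the peak set, or of the genome itself.

    With ``peaks`` given, every peak centre is classified; without, the
    fraction of genomic bases falling in each region class is computed under
    the same precedence, giving the genome-background reference.
    """
    if peaks is not None:
        if len(peaks) == 0:
            raise ValueError("region_breakdown: no peaks supplied")
        index = RegionIndex(genes, promoter_span)
        counts = {r: 0.0 for r in REGIONS}
        for p in peaks:
            counts[index.classify(p.chrom, p.centre)] += 1
        return RegionBreakdown(counts, "peaks")

    counts = {r: 0.0 for r in REGIONS}
    by_chrom: Dict[str, Dict[str, list]] = {}
    for g in genes.values():
        d = by_chrom.setdefault(g.chrom, {"prom": [], "exon": [], "body": []})
        prom = g.upstream_window(promoter_span)
        if prom is not None:
            d["prom"].append((prom.start, min(prom.end, chrom_lengths[g.chrom])))
        d["exon"].extend((e.start, e.end) for e in g.exons)
        d["body"].append((g.interval.start, g.interval.end))
    for chrom, length in chrom_lengths.items():
        d = by_chrom.get(chrom, {"prom": [], "exon": [], "body": []})
        prom = merge_pairs(d["prom"])
        exon = subtract_pairs(d["exon"], prom)
        intron = subtract_pairs(subtract_pairs(d["body"], d["exon"]), prom)
        n_prom, n_exon, n_intron = map(total_length, (prom, exon, intron))
        counts["promoter"] += n_prom
        counts["exon"] += n_exon
        counts["intron"] += n_intron
        counts["intergenic"] += length - n_prom - n_exon - n_intron
    return RegionBreakdown(counts, "genome_background")


def expression_groups(expr: pd.DataFrame, sample: str) -> pd.Series:
    """Split genes into expression-level groups L1..L10 plus "unexpressed".

    Genes with FPKM > 0 are ranked descending (ties broken by gene_id) and
    cut into 10 contiguous groups whose sizes differ by at most one; L1 holds
    the highest FPKM values.  FPKM = 0 genes form the "unexpressed" group.
    """
    if sample not in expr.columns:
        raise KeyError(f"sample {sample!r} not in expression matrix")
    fpkm = expr[sample]
    labels = pd.Series("unexpressed", index=expr.index, name="group")
    pos = fpkm[fpkm > 0]
    if pos.empty:
        log.warning("sample %s has no expressed genes", sample)
        return labels
    order = pos.sort_index().sort_values(ascending=False, kind="stable").index
    for i, chunk in enumerate(np.array_split(np.arange(len(order)), 10)):
        labels.loc[order[chunk]] = f"L{i + 1}"
    return labels


def _gene_bin_means(track: DensityTrack, gene: GeneModel) -> np.ndarray:
    """70-bin strand-oriented density profile for one gene."""
    s, e = gene.interval.start, gene.interval.end
    length = e - s
    edges = [s - FLANK + i * (FLANK // N_UP) for i in range(N_UP)]
    body_edges = [s + (i * length) // N_BODY for i in range(N_BODY)]
    down_edges = [e + i * (FLANK // N_DOWN) for i in range(N_DOWN)]
    starts = np.array(edges + body_edges + down_edges, dtype=np.int64)
    ends = np.concatenate([starts[1:], [e + FLANK]])
    vals = np.empty(N_UP + N_BODY + N_DOWN, dtype=float)
    for i, (bs, be) in enumerate(zip(starts, ends)):
        pos = np.arange(bs, be)
        vals[i] = track.values_at(gene.chrom, pos).mean() if be > bs else 0.0
    if gene.strand == "-":
        vals = vals[::-1]
    return vals


def metagene_profile(track: DensityTrack, genes: Iterable[GeneModel]) -> np.ndarray:
    """Average 70-bin profile over genes: 1-kb upstream flank (bins 0-19),
    gene body in three equal parts (bins 20-49), 1-kb downstream (50-69).

    Each gene is resampled onto the common axis strand-aware (minus-strand
    genes are reversed so bin 0 is always 5' upstream).
    """
    gene_list = list(genes)
    if not gene_list:
        raise ValueError("metagene_profile: empty gene subset")
    for g in gene_list:
        if len(g.interval) < 3:
            raise ValueError(f"gene {g.gene_id} shorter than 3 bp")
    return np.mean([_gene_bin_means(track, g) for g in gene_list], axis=0)


def tss_matrix(
    track: DensityTrack,
    genes: Mapping[str, GeneModel],
    half_window: int = 1000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Gene x bin density matrix over [TSS - half_window, TSS + half_window).

    Rows are strand-oriented (bin 0 is upstream); genes closer than the
    half-window to a chromosome edge are zero-padded.
    """
    n_bins = 2 * half_window // bin_size
    rows = {}
    for gid in sorted(genes):
        g = genes[gid]
        if g.strand == "+":
            pos = np.arange(g.tss - half_window, g.tss + half_window)
        else:
            pos = np.arange(g.tss + half_window, g.tss - half_window, -1)
        vals = track.values_at(g.chrom, pos)
        length = track.chrom_lengths.get(g.chrom)
        if length is not None:
            vals[(pos < 0) | (pos >= length)] = 0.0
        rows[gid] = vals.reshape(n_bins, bin_size).mean(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"bin{i}" for i in range(n_bins)])


def kmeans_rows(matrix: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """Cluster TSS-profile rows with k-means (k-means++ init, 10 restarts).

    Deterministic under a fixed seed.  Cluster labels are renumbered by
    descending cluster mean so label 0 is always the highest-signal group.
    """
    if len(matrix) < k:
        raise ValueError(f"need >= {k} rows for k={k}, got {len(matrix)}")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        log.warning("all rows identical; single cluster")
        return pd.Series(0, index=matrix.index, name="cluster")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        raw = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return pd.Series([remap[int(c)] for c in raw], index=matrix.index, name="cluster")


def concurrence_stats(
    genes: Mapping[str, GeneModel],
    expr: pd.DataFrame,
    peaks: Sequence[Peak],
    sample: str,
    active_cutoff: float = 0.0,
    window_up: int = 1000,
) -> Tuple[float, float]:
    """Concurrence frequencies between the mark and active transcription.

    A gene is active iff FPKM > ``active_cutoff``; it "has the mark" iff at
    least one peak centre lies in its strand-aware span
    [TSS - window_up, gene end).  Returns (fraction of active genes with the
    mark, fraction of peaks whose centre lies in such a span of an active
    gene).  With no active genes the first fraction is NaN; with no peaks
    the second is NaN.
    """
    if active_cutoff < 0:
        raise ValueError("active_cutoff must be >= 0")
    fpkm = expr[sample]
    active = [genes[g] for g in sorted(genes) if g in fpkm.index and fpkm[g] > active_cutoff]
    if not active:
        log.warning("no active genes at cutoff %s", active_cutoff)
        return float("nan"), 0.0
    spans: Dict[str, IntervalTree] = {}
    for g in active:
        w = g.mark_window(window_up)
        spans.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end, g.gene_id)
    marked_gene_ids = set()
    peaks_near = 0
    for p in peaks:
        tree = spans.get(p.chrom)
        hits = tree[p.centre] if tree is not None else set()
        if hits:
            peaks_near += 1
            marked_gene_ids.update(h.data for h in hits)
    frac_active_with_mark = len(marked_gene_ids) / len(active)
    frac_peaks_near_active = peaks_near / len(peaks) if len(peaks) else float("nan")
    return frac_active_with_mark, frac_peaks_near_active
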
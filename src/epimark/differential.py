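"""Tissue-differential mark enrichment and expression-consistency statistics.

Differential regions between two samples (e.g. root vs stem) are called by a
library-size-scaled one-sided Poisson comparison restricted to candidate
regions (the union of both samples' peaks): within a region, the count in
one sample is tested against the other sample's count (plus a pseudocount of
one) as the Poisson rate, in both directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import DensityTrack, GeneModel, GenomicInterval, Peak, merge_pairs

log = logging.getLogger(__name__)


@dataclass
class DifferentialRegion:
    interval: GenomicInterval
    direction: str  # "<sampleA>_up" or "<sampleB>_up"
    p_value: float
    count_a: float  # library-scaled counts
    count_b: float


def poisson_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam); the enrichment tail probability."""
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _region_counts(track: DensityTrack, region: Tuple[str, int, int]) -> float:
    chrom, start, end = region
    arr = track.data.get(chrom)
    if arr is None:
        return 0.0
    b0 = max(0, start // track.bin_size)
    b1 = min(len(arr), -(-end // track.bin_size))
    return float(arr[b0:b1].sum())


def candidate_regions_from_peaks(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> List[Tuple[str, int, int]]:
    """Merged union of both samples' peak intervals."""
    by_chrom: Dict[str, list] = {}
    for p in list(peaks_a) + list(peaks_b):
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    regions = []
    for chrom in sorted(by_chrom):
        regions.extend((chrom, s, e) for s, e in merge_pairs(by_chrom[chrom]))
    return regions


def call_differential(
    track_a: DensityTrack,
    track_b: DensityTrack,
    candidate_regions: Sequence[Tuple[str, int, int]],
    alpha: float = 1e-5,
    sample_a: str = "A",
    sample_b: str = "B",
) -> List[DifferentialRegion]:
    """Call regions with significantly more signal in one sample.

    Both libraries are scaled to the smaller total depth; per region a
    one-sided Poisson tail test is run in each direction with the opposite
    scaled count plus a pseudocount of 1 as the rate.  Regions significant
    in neither direction are omitted.
    """
    if not candidate_regions:
        raise ValueError("no candidate regions")
    tot_a, tot_b = track_a.total(), track_b.total()
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("zero-depth track")
    smaller = min(tot_a, tot_b)
    fa, fb = smaller / tot_a, smaller / tot_b
    out: List[DifferentialRegion] = []
    for chrom, start, end in candidate_regions:
        a = _region_counts(track_a, (chrom, start, end)) * fa
        b = _region_counts(track_b, (chrom, start, end)) * fb
        p_a_up = poisson_tail(int(round(a)), b + 1.0)
        p_b_up = poisson_tail(int(round(b)), a + 1.0)
        iv = GenomicInterval(chrom, start, end)
        if p_a_up < alpha and a > b:
            out.append(DifferentialRegion(iv, f"{sample_a}_up", p_a_up, a, b))
        elif p_b_up < alpha and b > a:
            out.append(DifferentialRegion(iv, f"{sample_b}_up", p_b_up, a, b))
    return out


def genes_for_regions(
    regions: Sequence[DifferentialRegion],
    genes: Mapping[str, GeneModel],
    window_up: int = 1000,
) -> Dict[str, List[str]]:
    """Assign differential regions to genes via the mark-association window
    ([TSS - window_up, gene end), strand-aware); keyed by direction."""
    trees: Dict[str, IntervalTree] = {}
    for g in genes.values():
        w = g.mark_window(window_up)
        trees.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end, g.gene_id)
    assigned: Dict[str, set] = {}
    for r in regions:
        tree = trees.get(r.interval.chrom)
        if tree is None:
            continue
        centre = r.interval.centre
        for hit in tree[centre]:
            assigned.setdefault(r.direction, set()).add(hit.data)
    return {d: sorted(ids) for d, ids in assigned.items()}


def expression_consistency(
    diff_regions: Sequence[DifferentialRegion],
    genes: Mapping[str, GeneModel],
    expr: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    fold: float = 2.0,
    active_cutoff: float = 0.0,
    window_up: int = 1000,
) -> Dict[str, float]:
    """Fraction of direction-up genes that are also expression-up.

    A gene counts as highly expressed in the up-sample iff its FPKM there is
    at least ``fold`` times the other sample's and above ``active_cutoff``.
    """
    assigned = genes_for_regions(diff_regions, genes, window_up)
    out: Dict[str, float] = {}
    for direction, up_sample, other in (
        (f"{sample_a}_up", sample_a, sample_b),
        (f"{sample_b}_up", sample_b, sample_a),
    ):
        gene_ids = assigned.get(direction, [])
        if not gene_ids:
            out[direction] = float("nan")
            continue
        n_cons = 0
        for gid in gene_ids:
            hi, lo = expr.loc[gid, up_sample], expr.loc[gid, other]
            if hi > active_cutoff and math.isfinite(fold) and hi >= fold * lo:
                n_cons += 1
        out[direction] = n_cons / len(gene_ids)
    return out


def tissue_specific_zscore(
    expr: pd.DataFrame, threshold: float = 2.0, log_transform: bool = True
) -> Dict[str, List[str]]:
    """Screen tissue-specific genes by per-gene z-score across samples.

    z_s = (x_s - mean)/sd over samples of log(FPKM + 1) (or raw FPKM with
    ``log_transform=False``); a gene is specific to sample s iff z_s >=
    threshold.  Constant-expression genes (sd = 0) are excluded.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-score screen needs >= 2 samples")
    X = np.log1p(expr.to_numpy(dtype=float)) if log_transform else expr.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(X)
    z[ok] = (X[ok] - mean[ok]) / sd[ok]
    out: Dict[str, List[str]] = {}
    for j, sample in enumerate(expr.columns):
        hits = expr.index[ok & (z[:, j] >= threshold)]
        out[sample] = sorted(hits)
    return out
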
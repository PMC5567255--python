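"""Reciprocal-best-hit orthologue pairing and chromosome-level conservation.

Hit tables are BLAST outfmt-6 style (qseqid, sseqid, evalue, bitscore).  A
pair (a, b) is an orthologue call iff b is a's lowest-E-value hit A->B, a is
b's lowest B->A, and both E-values pass a strict cutoff (default 1e-55).
Chromosome conservation is summarised as the row-normalised share of pairs
each chromosome of genome A sends to each chromosome of genome B; cells at
or above ~50% are flagged as highly conserved correspondences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, Peak

log = logging.getLogger(__name__)

HIT_COLUMNS = ["qseqid", "sseqid", "evalue", "bitscore"]


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: lowest e-value, ties by higher bitscore then
    lexicographic subject id."""
    df = hits.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    return df.groupby("qseqid", sort=True).first()["sseqid"]


def rbh_orthologs(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, e_cutoff: float = 1e-55
) -> List[Tuple[str, str]]:
    """Reciprocal-best-hit pairs passing the E-value cutoff in both directions."""
    for df, name in ((hits_ab, "A->B"), (hits_ba, "B->A")):
        missing = set(HIT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"hit table {name} missing columns {sorted(missing)}")
        if (df["evalue"] <= 0).any():
            raise ValueError(f"hit table {name} has non-positive e-values")
    ab = hits_ab[hits_ab["evalue"] <= e_cutoff]
    ba = hits_ba[hits_ba["evalue"] <= e_cutoff]
    if ab.empty or ba.empty:
        return []
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    pairs = []
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.append((a, b))
    return sorted(pairs)


@dataclass
class RatioMatrix:
    """Row-normalised orthologue-pair share per chromosome pair."""

    ratios: pd.DataFrame  # rows: chroms of A; cols: chroms of B
    pair_counts: pd.DataFrame

    def high_conservation(self, threshold: float = 0.45) -> pd.DataFrame:
        return self.ratios >= threshold


def chromosome_ratio_matrix(
    pairs: Sequence[Tuple[str, str]],
    chrom_of_a: Mapping[str, str],
    chrom_of_b: Mapping[str, str],
    denominator: str = "pairs",
) -> RatioMatrix:
    """ratio(i, j) = pairs linking chrom i of A to chrom j of B, divided by
    all pairs involving chrom i (``denominator="pairs"``, the default; rows
    with pairs sum to 1) or by the number of genome-A genes on chrom i
    (``denominator="genes"``).  Empty rows are zero and logged."""
    for a, b in pairs:
        if a not in chrom_of_a:
            raise KeyError(f"gene {a} has no chromosome assignment in genome A")
        if b not in chrom_of_b:
            raise KeyError(f"gene {b} has no chromosome assignment in genome B")
    rows = sorted(set(chrom_of_a.values()))
    cols = sorted(set(chrom_of_b.values()))
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for a, b in pairs:
        counts.loc[chrom_of_a[a], chrom_of_b[b]] += 1
    if denominator == "pairs":
        row_tot = counts.sum(axis=1)
    elif denominator == "genes":
        row_tot = pd.Series(chrom_of_a).value_counts().reindex(rows).fillna(0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    ratios = counts.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0)
    for chrom in rows:
        if counts.loc[chrom].sum() == 0:
            log.warning("chromosome %s has no orthologue pairs", chrom)
    return RatioMatrix(ratios, counts)


def classify_conservation(
    matrix: RatioMatrix, threshold: float = 0.45
) -> pd.DataFrame:
    """Flag highly conserved chromosome correspondences and the best partner
    per row ("close to 50% or over" of a chromosome's pairs)."""
    flags = matrix.high_conservation(threshold)
    best = matrix.ratios.idxmax(axis=1)
    best_ratio = matrix.ratios.max(axis=1)
    return pd.DataFrame(
        {
            "best_partner": best,
            "best_ratio": best_ratio,
            "high_conservation": [
                bool(flags.loc[i, best[i]]) for i in matrix.ratios.index
            ],
        }
    )


def export_circos_tracks(
    pairs: Sequence[Tuple[str, str]],
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
    chrom_a: str,
    chrom_b: str,
    peaks: Sequence[Peak],
    expr: pd.DataFrame,
    sample: str,
    out_links: str,
    out_peaks: str,
    out_expr: str,
    window: int = 10_000,
) -> int:
    """Write circos text tracks for one chromosome pair.

    The link file lines are ``chromA startA endA chromB startB endB``; the
    peak and expression tracks are per-gene/per-peak value lines on the two
    chromosomes.  Returns the number of links written.
    """
    links = []
    for a, b in pairs:
        ga, gb = genes_a.get(a), genes_b.get(b)
        if ga is None or gb is None or ga.chrom != chrom_a or gb.chrom != chrom_b:
            continue
        links.append(
            (chrom_a, ga.interval.start, ga.interval.end,
             chrom_b, gb.interval.start, gb.interval.end)
        )
    links.sort()
    if not links:
        log.warning("no orthologue links on %s/%s", chrom_a, chrom_b)
    with open(out_links, "w") as fh:
        for rec in links:
            fh.write(" ".join(str(x) for x in rec) + "\n")
    with open(out_peaks, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.peak_id)):
            if p.chrom in (chrom_a, chrom_b):
                fh.write(f"{p.chrom} {p.interval.start} {p.interval.end} {p.score:.6g}\n")
    with open(out_expr, "w") as fh:
        for gid, genes in (("A", genes_a), ("B", genes_b)):
            for g in sorted(genes.values(), key=lambda g: (g.chrom, g.interval.start)):
                if g.chrom in (chrom_a, chrom_b) and g.gene_id in expr.index:
                    v = expr.loc[g.gene_id, sample] if sample in expr.columns else 0.0
                    fh.write(f"{g.chrom} {g.interval.start} {g.interval.end} {v:.6g}\n")
    return len(links)
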
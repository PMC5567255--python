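"""Readers and writers for the pipeline's file formats.

GTF/GFF (genes and transcript candidates), BED3-6 (peaks, ESTs), bedGraph
(density tracks) and headered TSV (expression, hit tables, edge lists).
GTF is 1-based closed on disk and converted to 0-based half-open in memory.
All writers emit deterministic ordering: (chrom, start, id).
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Mapping, Tuple

import gffutils
import numpy as np
import pandas as pd

from .core import DensityTrack, GeneModel, GenomicInterval, Peak

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input record, reported with its line number."""


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start ({end} < {start})")
            if start < 1:
                raise FormatError(f"{path}:{lineno}: GTF coordinates are 1-based; got start {start}")


def _gtf_db(path: str) -> gffutils.FeatureDB:
    return gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def parse_annotation(path: str) -> Dict[str, GeneModel]:
    """Read a GTF/GFF gene annotation into GeneModel objects keyed by gene_id.

    Exon features are grouped by their ``gene_id`` attribute; the gene span is
    the union span of its exons (or the gene/transcript feature when present).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    if os.path.getsize(path) == 0:
        log.warning("empty annotation file %s", path)
        return {}
    db = _gtf_db(path)
    exons: Dict[str, List[GenomicInterval]] = {}
    strands: Dict[str, str] = {}
    for f in db.features_of_type("exon"):
        gid = f.attributes["gene_id"][0]
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand if f.strand in "+-" else ".")
        exons.setdefault(gid, []).append(iv)
        strands[gid] = iv.strand
    if not exons:
        log.warning("no exon features in %s", path)
        return {}
    genes: Dict[str, GeneModel] = {}
    for gid in sorted(exons):
        ivs = sorted(exons[gid], key=lambda e: e.start)
        strand = strands[gid]
        if strand not in ("+", "-"):
            raise FormatError(f"gene {gid} in {path} is unstranded; use parse_candidates")
        span = GenomicInterval(ivs[0].chrom, ivs[0].start, max(e.end for e in ivs), strand)
        genes[gid] = GeneModel(gid, span, ivs)
    return genes


def write_annotation(genes: Mapping[str, GeneModel], path: str, source: str = "epimark") -> None:
    ordered = sorted(genes.values(), key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            for e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";\n'
                )


def parse_peaks(path: str, sample: str = "") -> List[Peak]:
    """Read a BED3+ peak file; column 4 is the name, column 5 the score.

    Peaks are returned sorted by (chrom, start); missing scores default to 0.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 else 0.0
            peaks.append(Peak(name, GenomicInterval(fields[0], start, end), score, sample))
    peaks.sort(key=lambda p: (p.chrom, p.interval.start, p.peak_id))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str) -> None:
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.peak_id))
    with open(path, "w") as fh:
        for p in ordered:
            fh.write(f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\t{p.score:.6g}\n")


def parse_bed6(path: str) -> List[Tuple[str, GenomicInterval]]:
    """Read stranded BED6 records (e.g. EST alignments) as (name, interval)."""
    out: List[Tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            if fields[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            out.append(
                (fields[3], GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5]))
            )
    out.sort(key=lambda r: (r[1].chrom, r[1].start, r[0]))
    return out


def write_bed6(records: Iterable[Tuple[str, GenomicInterval]], path: str) -> None:
    ordered = sorted(records, key=lambda r: (r[1].chrom, r[1].start, r[0]))
    with open(path, "w") as fh:
        for name, iv in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path: str) -> DensityTrack:
    """Reconstruct a DensityTrack from a dense bedGraph written by this package."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if df.empty:
        raise FormatError(f"{path}: empty bedGraph")
    bin_size = int((df["end"] - df["start"]).iloc[:-1].max()) if len(df) > 1 else int(df["end"].iloc[0])
    chrom_lengths = df.groupby("chrom", sort=True)["end"].max().to_dict()
    track = DensityTrack(bin_size, chrom_lengths)
    for chrom, sub in df.groupby("chrom", sort=True):
        idx = (sub["start"] // bin_size).to_numpy()
        track.data[chrom][idx] = sub["value"].to_numpy()
    return track


def write_bedgraph(track: DensityTrack, path: str) -> None:
    """Write every bin (including zeros) so the track round-trips exactly."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            length = track.chrom_lengths[chrom]
            for i, v in enumerate(arr):
                s = i * track.bin_size
                e = min(length, s + track.bin_size)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_expression(path: str) -> pd.DataFrame:
    """Headered TSV of FPKM values: gene_id column + one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id").sort_index()
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative FPKM value")
    return df


def write_expression(expr: pd.DataFrame, path: str) -> None:
    expr.sort_index().to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    """Generic headered TSV (hit tables, edge lists)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
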
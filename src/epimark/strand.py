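"""Strand inference for unstranded novel transcript candidates.

Assembled transcript fragments from unstranded RNA-seq carry no strand, but
an active-promoter mark such as H3K4me3 sits at (and just downstream of) the
TSS.  The candidate body is split into three equal parts; an associated peak
whose centre falls upstream of the candidate or in the left third implies a
forward-strand TSS ("+"), the right third or downstream implies "-", and the
middle third is ambiguous ("middle").  Stranded EST alignments then merge
nearby fragments and proof the inferred strand: an EST is a direct
observation of the transcribed strand, so it overrides the peak call on
conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, Peak, overlap_length

log = logging.getLogger(__name__)

STRAND_LABELS = ("+", "-", "middle", "unknown")


@dataclass
class TranscriptCandidate:
    """Unstranded assembly fragment with an inferred strand and evidence."""

    candidate_id: str
    interval: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)
    strand: str = "unknown"
    evidence: Set[str] = field(default_factory=set)
    status: str = "novel"  # novel | overlaps_known | merged_into:<id>
    ambiguous: bool = False

    def __post_init__(self):
        if not self.exons:
            self.exons = [replace(self.interval, strand=".")]
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def centre(self) -> int:
        return self.interval.centre


@dataclass(frozen=True)
class EstAlignment:
    """Stranded EST alignment; direct evidence of transcript strand."""

    est_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"EST {self.est_id} must be stranded")


def filter_novel(
    candidates: Iterable[TranscriptCandidate],
    known_genes: Mapping[str, GeneModel],
) -> List[TranscriptCandidate]:
    """Mark candidates whose exons touch any known-gene exon as overlaps_known.

    The comparison is exon-level and strand-blind (candidates are
    unstranded): a candidate sitting entirely inside a known intron stays
    novel.
    """
    exon_trees: Dict[str, IntervalTree] = {}
    for g in known_genes.values():
        for e in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(e.start, e.end)
    out = []
    for c in candidates:
        tree = exon_trees.get(c.chrom)
        hit = tree is not None and any(tree.overlap(e.start, e.end) for e in c.exons)
        out.append(replace_status(c, "overlaps_known" if hit else "novel"))
    return out


def replace_status(c: TranscriptCandidate, status: str) -> TranscriptCandidate:
    c2 = TranscriptCandidate(c.candidate_id, c.interval, list(c.exons), c.strand,
                             set(c.evidence), status, c.ambiguous)
    return c2


def associate_peak(
    candidate: TranscriptCandidate,
    peaks: Sequence[Peak],
    max_dist: int = 2000,
) -> Optional[Peak]:
    """Best mark peak for a candidate, or None.

    Eligible peaks have their centre within the candidate span extended by
    ``max_dist`` on each side.  The highest-scoring eligible peak wins; ties
    break by smaller centre-to-candidate-centre distance, then leftmost.
    """
    lo = candidate.interval.start - max_dist
    hi = candidate.interval.end + max_dist
    eligible = [p for p in peaks
                if p.chrom == candidate.chrom and lo <= p.centre < hi]
    if not eligible:
        return None
    return min(eligible, key=lambda p: (-p.score, abs(p.centre - candidate.centre), p.centre))


def infer_strand(candidate: TranscriptCandidate, peak: Peak) -> str:
    """Strand implied by the peak centre relative to the candidate body.

    The body [start, end) is split into three near-equal thirds (remainder
    bases go to the rightmost thirds).  Centre left of the body or in the
    left third -> "+"; middle third -> "middle"; right third or beyond ->
    "-".  A centre exactly on a third boundary belongs to the region on its
    right.
    """
    s, e = candidate.interval.start, candidate.interval.end
    length = e - s
    if length < 3:
        raise ValueError(f"candidate {candidate.candidate_id} shorter than 3 bp")
    b1 = s + length // 3
    b2 = s + (2 * length) // 3
    c = peak.centre
    if c < b1:
        return "+"
    if c < b2:
        return "middle"
    return "-"


def _merge_pair(a: TranscriptCandidate, b: TranscriptCandidate,
                strand: str, est_id: str) -> TranscriptCandidate:
    first, second = (a, b) if a.interval.start <= b.interval.start else (b, a)
    iv = GenomicInterval(a.chrom, first.interval.start,
                         max(a.interval.end, b.interval.end), ".")
    merged = TranscriptCandidate(
        first.candidate_id, iv, list(first.exons) + list(second.exons),
        strand, a.evidence | b.evidence | {f"est:{est_id}"}, "novel",
    )
    return merged


def merge_with_ests(
    candidates: Sequence[TranscriptCandidate],
    ests: Sequence[EstAlignment],
    max_gap: int = 5000,
) -> List[TranscriptCandidate]:
    """Merge novel fragments linked by a shared EST and proof their strands.

    Two candidates merge when one EST overlaps both by >=1 bp and the gap
    between them is at most ``max_gap``; the merged record keeps the
    left-hand id, spans the union, and takes the EST strand.  An EST also
    sets (or, on conflict, overrides — recorded as "est_override") the
    strand of single candidates it overlaps.  ESTs touching more than two
    candidates chain-merge left to right.  Candidates left at
    "middle"/"unknown" with no EST stay flagged ambiguous.
    """
    pool: Dict[str, TranscriptCandidate] = {}
    order: List[str] = []
    merged_away: Dict[str, str] = {}
    for c in candidates:
        c2 = replace_status(c, c.status)
        pool[c2.candidate_id] = c2
        order.append(c2.candidate_id)

    def resolve(cid: str) -> str:
        while cid in merged_away:
            cid = merged_away[cid]
        return cid

    for est in sorted(ests, key=lambda e: (e.interval.chrom, e.interval.start, e.est_id)):
        hit_ids = []
        for cid in order:
            cur = resolve(cid)
            if cur in hit_ids:
                continue
            c = pool[cur]
            if c.status != "novel":
                continue
            if overlap_length(c.interval, est.interval) >= 1:
                hit_ids.append(cur)
        if not hit_ids:
            continue
        hit_ids.sort(key=lambda cid: pool[cid].interval.start)
        # chain-merge left to right under the gap bound
        current = pool[hit_ids[0]]
        for nxt_id in hit_ids[1:]:
            nxt = pool[nxt_id]
            gap = max(nxt.interval.start - current.interval.end,
                      current.interval.start - nxt.interval.end, 0)
            if gap > max_gap:
                _apply_est_strand(nxt, est)
                continue
            merged = _merge_pair(current, nxt, est.interval.strand, est.est_id)
            for old in (current.candidate_id, nxt.candidate_id):
                if old != merged.candidate_id:
                    merged_away[old] = merged.candidate_id
                    pool[old] = replace_status(pool[old], f"merged_into:{merged.candidate_id}")
            pool[merged.candidate_id] = merged
            current = merged
        _apply_est_strand(current, est)

    out = []
    for cid in order:
        if resolve(cid) != cid:
            out.append(pool[cid])  # merged-away stub, status merged_into:<id>
            continue
        c = pool[cid]
        if c.status == "novel" and c.strand in ("middle", "unknown"):
            c.ambiguous = True
        out.append(c)
    return out


def _apply_est_strand(c: TranscriptCandidate, est: EstAlignment) -> None:
    if overlap_length(c.interval, est.interval) < 1:
        return
    s = est.interval.strand
    if c.strand in ("+", "-") and c.strand != s:
        c.evidence.add("est_override")
    c.evidence.add(f"est:{est.est_id}")
    c.strand = s
    c.ambiguous = False


def annotate_pipeline(
    candidates: Sequence[TranscriptCandidate],
    known_genes: Mapping[str, GeneModel],
    peaks_by_sample: Mapping[str, Sequence[Peak]],
    ests: Sequence[EstAlignment],
    max_dist: int = 2000,
    max_gap: int = 5000,
) -> Tuple[List[TranscriptCandidate], Dict[str, int]]:
    """Full novel-transcript annotation.

    Stages: known-exon filtering; per-sample peak association and strand
    inference (samples treated independently); cross-sample reconciliation
    (agreement kept, "+"/"-" disagreement demoted to "unknown" pending EST
    evidence); EST merging and strand proofing.  Returns the annotated set
    and per-sample peak-support counts plus their intersection.
    """
    staged = filter_novel(candidates, known_genes)
    support: Dict[str, Set[str]] = {s: set() for s in peaks_by_sample}
    for c in staged:
        if c.status != "novel":
            continue
        calls = {}
        for sample, peaks in peaks_by_sample.items():
            peak = associate_peak(c, peaks, max_dist)
            if peak is None:
                continue
            support[sample].add(c.candidate_id)
            calls[sample] = infer_strand(c, peak)
            c.evidence.add(f"peak:{peak.peak_id}")
        directional = {s for s in calls.values() if s in ("+", "-")}
        if len(directional) == 1:
            c.strand = directional.pop()
        elif len(directional) == 2:
            c.strand = "unknown"
            c.ambiguous = True
            c.evidence.add("sample_conflict")
        elif calls:
            c.strand = "middle"
    final = merge_with_ests(staged, ests, max_gap)
    counts = {s: len(ids) for s, ids in support.items()}
    if len(support) > 1:
        inter = set.intersection(*support.values()) if support else set()
        counts["intersection"] = len(inter)
    return final, counts
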
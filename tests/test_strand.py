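import pytest

from epimark.core import GenomicInterval, Peak
from epimark.strand import (
    EstAlignment,
    TranscriptCandidate,
    annotate_pipeline,
    associate_peak,
    filter_novel,
    infer_strand,
    merge_with_ests,
)

from conftest import make_gene


def cand(cid, start, end, chrom="chr1", exons=None):
    iv = GenomicInterval(chrom, start, end, ".")
    ex = [GenomicInterval(chrom, s, e, ".") for s, e in exons] if exons else None
    return TranscriptCandidate(cid, iv, ex or [])


def pk(start, end, score=10.0, pid="p", chrom="chr1"):
    return Peak(pid, GenomicInterval(chrom, start, end), score)


class TestFilterNovel:
    def test_exon_inside_known_exon(self):
        known = {"g": make_gene("g", "chr1", 5000, 8000, "+")}
        out = filter_novel([cand("c", 6000, 6500)], known)
        assert out[0].status == "overlaps_known"

    def test_intergenic_is_novel(self):
        known = {"g": make_gene("g", "chr1", 5000, 8000, "+")}
        out = filter_novel([cand("c", 50_000, 51_000)], known)
        assert out[0].status == "novel"

    def test_intron_only_overlap_stays_novel(self):
        known = {"g": make_gene("g", "chr1", 5000, 9000, "+",
                                exons=[(5000, 6000), (8000, 9000)])}
        c = cand("c", 6500, 7500)
        out = filter_novel([c], known)
        assert out[0].status == "novel"
        # brute-force base check: candidate shares no base with any known exon
        known_exonic = set(range(5000, 6000)) | set(range(8000, 9000))
        assert not (set(range(6500, 7500)) & known_exonic)


class TestAssociatePeak:
    def test_upstream_peak_within_window(self):
        c = cand("c", 10_000, 13_000)
        p = pk(8800, 9300)  # centre 9050, 950 bp upstream of start
        assert associate_peak(c, [p]) is p

    def test_peak_beyond_2000_rejected(self):
        c = cand("c", 10_000, 13_000)
        p = pk(15_200, 15_800)  # centre 15500, 2500 bp beyond the end
        assert associate_peak(c, [p]) is None

    def test_highest_score_wins(self):
        c = cand("c", 10_000, 13_000)
        weak, strong = pk(9000, 9400, 40, "weak"), pk(13_500, 13_900, 80, "strong")
        assert associate_peak(c, [weak, strong]).peak_id == "strong"

    def test_score_tie_breaks_by_proximity_then_leftmost(self):
        c = cand("c", 10_000, 13_000)  # centre 11500
        near = pk(11_000, 11_400, 50, "near")     # centre 11200
        far = pk(9000, 9400, 50, "far")           # centre 9200
        assert associate_peak(c, [far, near]).peak_id == "near"
        left = pk(10_300, 10_700, 50, "left")     # centre 10500, dist 1000
        right = pk(12_300, 12_700, 50, "right")   # centre 12500, dist 1000
        assert associate_peak(c, [right, left]).peak_id == "left"


class TestInferStrand:
    @pytest.mark.parametrize(
        "centre,expected",
        [(1200, "+"), (800, "+"), (2500, "middle"), (3800, "-"), (4500, "-"),
         (2000, "middle"), (3000, "-")],  # boundaries belong to the right region
    )
    def test_thirds_rule(self, centre, expected):
        c = cand("c", 1000, 4000)
        assert infer_strand(c, pk(centre - 100, centre + 100)) == expected

    def test_short_candidate_rejected(self):
        c = cand("c", 1000, 1002)
        with pytest.raises(ValueError):
            infer_strand(c, pk(900, 1100))

    def test_exhaustive_sweep_partitions_into_three_labels(self):
        """Every centre position in the eligibility window maps to exactly one
        of +, middle, -; boundaries agree with a brute-force thirds rule."""
        c = cand("c", 1000, 4001)  # length 3001: remainder goes rightward
        length = 3001
        b1, b2 = 1000 + length // 3, 1000 + (2 * length) // 3
        seen = {"+": 0, "middle": 0, "-": 0}
        for centre in range(0, 4001 + 2000):
            label = infer_strand(c, pk(centre, centre + 1))
            brute = "+" if centre < b1 else ("middle" if centre < b2 else "-")
            assert label == brute
            seen[label] += 1
        assert all(v > 0 for v in seen.values())


class TestMergeWithEsts:
    def test_est_links_two_fragments(self):
        frags = [cand("a", 1000, 2000), cand("b", 3000, 4000)]
        est = EstAlignment("e1", GenomicInterval("chr1", 1800, 3200, "+"))
        out = merge_with_ests(frags, [est])
        merged = [c for c in out if c.status == "novel"]
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (1000, 4000)
        assert merged[0].strand == "+"
        stubs = [c for c in out if c.status.startswith("merged_into:")]
        assert stubs and stubs[0].status == "merged_into:a"

    def test_est_overrides_peak_strand(self):
        c = cand("a", 1000, 4000)
        c.strand = "+"
        est = EstAlignment("e1", GenomicInterval("chr1", 1500, 2500, "-"))
        out = merge_with_ests([c], [est])
        assert out[0].strand == "-"
        assert "est_override" in out[0].evidence

    def test_no_est_leaves_candidate_unchanged(self):
        c = cand("a", 1000, 4000)
        c.strand = "+"
        out = merge_with_ests([c], [])
        assert out[0].strand == "+" and out[0].interval == c.interval

    def test_gap_bound_blocks_merge(self):
        frags = [cand("a", 1000, 2000), cand("b", 9000, 10_000)]
        est = EstAlignment("e1", GenomicInterval("chr1", 1900, 9100, "+"))
        out = merge_with_ests(frags, [est], max_gap=5000)
        assert sum(c.status == "novel" for c in out) == 2

    def test_merging_never_loses_bases(self, world):
        before = {(c.chrom, e.start, e.end) for c in world.candidates for e in c.exons}
        out = merge_with_ests(world.candidates, world.ests)
        after_bases = set()
        for c in out:
            if c.status == "novel":
                for e in c.exons:
                    after_bases.add((c.chrom, e.start, e.end))
        # every original exon span survives somewhere in the output
        covered = set()
        for chrom, s, e in before:
            ok = any(chrom == c2 and s2 <= s and e <= e2 for c2, s2, e2 in after_bases)
            if ok:
                covered.add((chrom, s, e))
        assert covered == before


class TestAnnotatePipeline:
    def _world_inputs(self):
        known = {"g": make_gene("g", "chr1", 100_000, 103_000, "+")}
        return known

    def test_agreeing_samples_keep_strand(self):
        known = self._world_inputs()
        c = cand("c", 10_000, 13_000)
        peaks = {"root": [pk(10_200, 10_600, pid="r")],
                 "stem": [pk(10_300, 10_700, pid="s")]}
        final, counts = annotate_pipeline([c], known, peaks, [])
        assert final[0].strand == "+"
        assert counts == {"root": 1, "stem": 1, "intersection": 1}

    def test_conflicting_samples_without_est_unknown(self):
        known = self._world_inputs()
        c = cand("c", 10_000, 13_000)
        peaks = {"root": [pk(10_200, 10_600, pid="r")],
                 "stem": [pk(12_600, 12_900, pid="s")]}
        final, _ = annotate_pipeline([c], known, peaks, [])
        assert final[0].strand == "unknown"
        assert final[0].ambiguous
        assert "sample_conflict" in final[0].evidence

    def test_conflict_resolved_by_est(self):
        known = self._world_inputs()
        c = cand("c", 10_000, 13_000)
        peaks = {"root": [pk(10_200, 10_600, pid="r")],
                 "stem": [pk(12_600, 12_900, pid="s")]}
        est = EstAlignment("e", GenomicInterval("chr1", 11_000, 12_000, "-"))
        final, _ = annotate_pipeline([c], known, peaks, [est])
        assert final[0].strand == "-"
        assert not final[0].ambiguous

    def test_recovery_degrades_as_peak_offset_grows(self):
        """Pushing the generator's novel-gene peak offset far past the gene
        length must not improve strand recovery (sanity curve)."""
        from epimark.synthetic import SyntheticConfig, generate_world, strand_recovery

        def rate(offset):
            # no ESTs: isolate the peak-position signal
            cfg = SyntheticConfig(seed=2, n_genes=60, n_ortholog_pairs=20,
                                  module_spec=(), est_per_novel=0.0,
                                  novel_peak_offset_mean=offset)
            return strand_recovery(generate_world(cfg))

        near, mid, far = rate(150), rate(900), rate(2600)
        assert near >= mid >= far
        assert near > far

    def test_idempotent_on_own_output(self, world):
        final1, _ = annotate_pipeline(world.candidates, world.genes,
                                      world.peaks, world.ests)
        survivors = [c for c in final1 if c.status == "novel"]
        final2, _ = annotate_pipeline(survivors, world.genes, world.peaks, world.ests)
        key = lambda cs: sorted(
            (c.candidate_id, c.chrom, c.interval.start, c.interval.end, c.strand)
            for c in cs if c.status == "novel")
        assert key(final2) == key(survivors)
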
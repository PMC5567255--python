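import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epimark.core import DensityTrack, GenomicInterval, Peak
from epimark.landscape import (
    classify_peak_region,
    concurrence_stats,
    expression_groups,
    kmeans_rows,
    metagene_profile,
    region_breakdown,
    tss_matrix,
)

from conftest import make_gene


def peak(chrom, start, end, score=1.0, pid="p"):
    return Peak(pid, GenomicInterval(chrom, start, end), score)


@pytest.fixture
def toy_genes():
    # plus-strand gene with two exons and an intron, minus-strand single-exon gene
    return {
        "gp": make_gene("gp", "chr1", 5000, 8000, "+",
                        exons=[(5000, 6000), (7000, 8000)]),
        "gm": make_gene("gm", "chr1", 20_000, 22_000, "-"),
    }


class TestClassify:
    def test_centre_in_exon(self, toy_genes):
        assert classify_peak_region(peak("chr1", 5400, 5600), toy_genes) == "exon"

    def test_centre_in_intron(self, toy_genes):
        assert classify_peak_region(peak("chr1", 6400, 6600), toy_genes) == "intron"

    def test_upstream_centre_is_promoter(self, toy_genes):
        # centre 500 bp upstream of the plus-strand TSS
        assert classify_peak_region(peak("chr1", 4400, 4600), toy_genes) == "promoter"

    def test_minus_strand_promoter_is_right_of_gene(self, toy_genes):
        assert classify_peak_region(peak("chr1", 22_400, 22_600), toy_genes) == "promoter"

    def test_gene_free_chromosome_intergenic(self, toy_genes):
        assert classify_peak_region(peak("chrZ", 100, 200), toy_genes) == "intergenic"

    def test_promoter_beats_exon_of_overlapping_gene(self):
        # gene B's exon covers gene A's promoter region; precedence wins
        genes = {
            "A": make_gene("A", "chr1", 10_000, 12_000, "+"),
            "B": make_gene("B", "chr1", 6000, 11_000, "+"),
        }
        label = classify_peak_region(peak("chr1", 9400, 9600), genes)
        assert label == "promoter"


class TestRegionBreakdown:
    def test_all_intergenic_peaks(self, toy_genes):
        peaks = [peak("chr1", 100_000 + i * 1000, 100_500 + i * 1000, pid=f"p{i}")
                 for i in range(5)]
        bd = region_breakdown(toy_genes, {"chr1": 200_000}, peaks)
        assert bd.fractions == {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 1}

    def test_zero_peaks_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            region_breakdown(toy_genes, {"chr1": 200_000}, [])

    def test_whole_chromosome_gene_is_all_exon(self):
        genes = {"g": make_gene("g", "chr1", 0, 10_000)}
        bd = region_breakdown(genes, {"chr1": 10_000}, None, promoter_span=0)
        assert bd.fractions["exon"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, world):
        bd = region_breakdown(world.genes, world.chrom_lengths, None)
        assert sum(bd.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        bd2 = region_breakdown(world.genes, world.chrom_lengths, world.peaks["root"])
        assert sum(bd2.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_classification_invariant_to_peak_order(self, world):
        peaks = list(world.peaks["root"])
        fwd = region_breakdown(world.genes, world.chrom_lengths, peaks)
        rev = region_breakdown(world.genes, world.chrom_lengths, peaks[::-1])
        assert fwd.counts == rev.counts


class TestExpressionGroups:
    def test_even_split_of_twenty(self):
        expr = pd.DataFrame({"root": np.arange(20, 0, -1.0)},
                            index=[f"g{i:02d}" for i in range(20)])
        groups = expression_groups(expr, "root")
        assert (groups.value_counts() == 2).all()
        assert groups["g00"] == "L1"  # highest FPKM

    def test_zero_fpkm_is_unexpressed(self):
        expr = pd.DataFrame({"root": [5.0, 0.0, 1.0]}, index=["a", "b", "c"])
        groups = expression_groups(expr, "root")
        assert groups["b"] == "unexpressed"
        assert groups["a"] == "L1"

    def test_group_sizes_differ_by_at_most_one(self, world):
        groups = expression_groups(world.expression, "root")
        sizes = groups[groups != "unexpressed"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_all_zero_sample_only_unexpressed(self):
        expr = pd.DataFrame({"root": [0.0, 0.0]}, index=["a", "b"])
        assert (expression_groups(expr, "root") == "unexpressed").all()


class TestMetagene:
    def test_uniform_track_flat_profile(self):
        track = DensityTrack(50, {"chr1": 100_000})
        track.data["chr1"][:] = 3.0
        genes = [make_gene("g", "chr1", 30_000, 33_000, "+")]
        prof = metagene_profile(track, genes)
        np.testing.assert_allclose(prof, 3.0)

    def test_first_third_signal_lands_in_bins_20_29(self):
        track = DensityTrack(1, {"chr1": 100_000})
        genes = [make_gene("g", "chr1", 30_000, 33_000, "+")]
        track.data["chr1"][30_000:31_000] = 9.0  # exactly the first body third
        prof = metagene_profile(track, genes)
        assert prof[20:30] == pytest.approx(9.0)
        assert prof[:20].max() == 0 and prof[30:].max() == 0

    def test_minus_strand_mirrors_plus(self):
        # strand-symmetric construction: signal upstream of each TSS
        track = DensityTrack(1, {"chr1": 100_000})
        gp = make_gene("gp", "chr1", 30_000, 33_000, "+")
        gm = make_gene("gm", "chr1", 60_000, 63_000, "-")
        track.data["chr1"][29_000:30_000] = 4.0   # upstream of plus TSS
        track.data["chr1"][63_000:64_000] = 4.0   # upstream of minus TSS
        np.testing.assert_allclose(
            metagene_profile(track, [gp]), metagene_profile(track, [gm])
        )

    def test_empty_subset_rejected(self, world):
        with pytest.raises(ValueError):
            metagene_profile(world.tracks["root"], [])


class TestTssMatrix:
    def test_gene_at_chromosome_start_zero_padded(self):
        track = DensityTrack(50, {"chr1": 50_000})
        track.data["chr1"][:] = 2.0
        genes = {"g": make_gene("g", "chr1", 100, 3000, "+")}
        m = tss_matrix(track, genes)
        assert m.shape == (1, 40)
        row = m.loc["g"].to_numpy()
        assert row[:17].max() == 0        # bases before position 0
        assert row[-1] == pytest.approx(2.0)

    def test_constant_track_constant_rows(self, world):
        track = DensityTrack(50, world.chrom_lengths)
        for c in track.data:
            track.data[c][:] = 1.5
        some = {g: world.genes[g] for g in list(world.genes)[:5]}
        m = tss_matrix(track, some)
        np.testing.assert_allclose(m.to_numpy(), 1.5)

    def test_row_means_match_brute_force(self, world):
        track = world.tracks["root"]
        some = {g: world.genes[g] for g in sorted(world.genes)[:5]}
        m = tss_matrix(track, some)
        for gid, g in some.items():
            # strand-oriented window: [TSS-1000, TSS+1000) mirrored for minus
            if g.strand == "+":
                pos = np.arange(g.tss - 1000, g.tss + 1000)
            else:
                pos = np.arange(g.tss - 999, g.tss + 1001)
            vals = track.values_at(g.chrom, pos)
            assert m.loc[gid].mean() == pytest.approx(vals.mean())


class TestKmeans:
    def test_recovers_orthogonal_prototypes(self):
        protos = np.eye(4) * 10
        X = np.repeat(protos, 4, axis=0)
        m = pd.DataFrame(X)
        labels = kmeans_rows(m, k=4, seed=0)
        assert labels.nunique() == 4
        for i in range(4):
            assert labels.iloc[4 * i: 4 * i + 4].nunique() == 1

    def test_identical_rows_single_label(self):
        m = pd.DataFrame(np.ones((6, 5)))
        labels = kmeans_rows(m, k=4, seed=0)
        assert labels.nunique() == 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_rows(pd.DataFrame(np.ones((2, 5))), k=4, seed=0)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(3)
        truth = np.repeat(np.arange(4), 30)
        centres = rng.normal(0, 1, size=(4, 40)) * 8
        X = centres[truth] + rng.normal(0, 0.5, size=(120, 40))
        labels = kmeans_rows(pd.DataFrame(X), k=4, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_deterministic_under_seed(self, world):
        from epimark.landscape import tss_matrix as tm
        m = tm(world.tracks["root"], world.genes)
        a = kmeans_rows(m, 4, seed=7)
        b = kmeans_rows(m, 4, seed=7)
        assert (a == b).all()


class TestConcurrence:
    def test_constructed_full_coverage(self):
        genes = {"g1": make_gene("g1", "chr1", 5000, 8000, "+"),
                 "g2": make_gene("g2", "chr1", 20_000, 23_000, "-")}
        expr = pd.DataFrame({"root": [1.0, 2.0]}, index=["g1", "g2"])
        peaks = [peak("chr1", 5100, 5600, pid="a"), peak("chr1", 22_000, 22_500, pid="b")]
        fa, fp = concurrence_stats(genes, expr, peaks, "root")
        assert fa == 1.0 and fp == 1.0

    def test_zero_peaks(self):
        genes = {"g1": make_gene("g1", "chr1", 5000, 8000, "+")}
        expr = pd.DataFrame({"root": [1.0]}, index=["g1"])
        fa, fp = concurrence_stats(genes, expr, [], "root")
        assert fa == 0.0 and np.isnan(fp)

    def test_no_active_genes_flagged_nan(self):
        genes = {"g1": make_gene("g1", "chr1", 5000, 8000, "+")}
        expr = pd.DataFrame({"root": [0.0]}, index=["g1"])
        fa, fp = concurrence_stats(genes, expr, [peak("chr1", 5100, 5600)], "root")
        assert np.isnan(fa) and fp == 0.0

    def test_upstream_window_is_strand_aware(self):
        gm = {"g": make_gene("g", "chr1", 20_000, 23_000, "-")}
        expr = pd.DataFrame({"root": [1.0]}, index=["g"])
        # peak centre 500 bp beyond the minus-strand gene end = upstream of TSS
        fa, _ = concurrence_stats(gm, expr, [peak("chr1", 23_300, 23_700)], "root")
        assert fa == 1.0
        # but beyond the 1-kb window it does not count
        fa2, _ = concurrence_stats(gm, expr, [peak("chr1", 24_200, 24_600)], "root")
        assert fa2 == 0.0
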
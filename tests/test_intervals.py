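import numpy as np
import pytest

from mkcobind.intervals import (BedParseError, GeneModel, GenomicInterval,
                                PeakSet, chrom_concordance, merge_union,
                                read_gene_models, read_peaks, write_bed)
from oracles import per_base_union, random_peaksets


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 500, 400)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        iv = GenomicInterval("chr1", 10, 20, strand="+")
        assert len(iv) == 10

    def test_overlap_bp(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.overlap_bp(GenomicInterval("chr1", 150, 250)) == 50
        assert a.overlap_bp(GenomicInterval("chr2", 150, 250)) == 0
        assert a.overlap_bp(GenomicInterval("chr1", 200, 250)) == 0


class TestReadPeaks:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        ps = read_peaks(p, "GATA1")
        assert len(ps) == 0

    def test_unsorted_lines_sorted(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t10\t20\nchr1\t300\t400\nchr1\t10\t20\n")
        ps = read_peaks(p, "GATA1")
        coords = [(iv.chrom, iv.start) for iv in ps.intervals]
        assert coords == [("chr1", 10), ("chr1", 300), ("chr2", 10)]

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t500\t400\n")
        with pytest.raises(BedParseError, match=":2:"):
            read_peaks(p, "GATA1")
        p.write_text("chr1\tabc\t200\n")
        with pytest.raises(BedParseError, match="non-integer"):
            read_peaks(p, "GATA1")

    def test_track_lines_skipped_and_merging(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("track name=peaks\nbrowser position chr1\n"
                     "chr1\t100\t200\nchr1\t150\t250\n")
        ps = read_peaks(p, "GATA1")
        assert len(ps) == 1
        assert ps.intervals[0] == GenomicInterval("chr1", 100, 250)
        assert ps.n_merged_away == 1


class TestWriteBed:
    def test_empty_list(self, tmp_path):
        out = tmp_path / "o.bed"
        write_bed([], out)
        assert out.read_text() == ""

    def test_round_trip_random_fixture(self, tmp_path, rng):
        # 100 disjoint random intervals: read(write(x)) is the identity
        starts = np.cumsum(rng.integers(50, 500, size=100)) + \
            np.arange(100) * 600
        ivs = [GenomicInterval("chr1", int(s), int(s) + int(l), strand="+")
               for s, l in zip(starts, rng.integers(50, 400, size=100))]
        out = tmp_path / "o.bed"
        write_bed(ivs, out)
        back = read_peaks(out, "X")
        assert [(iv.chrom, iv.start, iv.end) for iv in back.intervals] == \
            [(iv.chrom, iv.start, iv.end) for iv in ivs]


class TestMergeUnion:
    def test_transitive_union(self):
        a = PeakSet("GATA1", [GenomicInterval("chr1", 100, 200)])
        b = PeakSet("FLI1", [GenomicInterval("chr1", 150, 250)])
        [(region, bound)] = merge_union([a, b], min_overlap=1)
        assert (region.start, region.end) == (100, 250)
        assert bound == {"GATA1", "FLI1"}

    def test_disjoint(self):
        a = PeakSet("A", [GenomicInterval("chr1", 0, 50)])
        b = PeakSet("B", [GenomicInterval("chr1", 100, 150)])
        regions = merge_union([a, b])
        assert len(regions) == 2
        assert [bound for _, bound in regions] == [{"A"}, {"B"}]

    def test_chain(self):
        sets = [PeakSet(f, [GenomicInterval("chr1", s, e)])
                for f, (s, e) in zip("ABC", [(0, 10), (9, 20), (19, 30)])]
        [(region, bound)] = merge_union(sets)
        assert (region.start, region.end) == (0, 30)
        assert bound == {"A", "B", "C"}
        oracle = per_base_union(sets, {"chr1": 40})
        assert [(r.start, r.end, b) for r, b in merge_union(sets)] == \
            [(r.start, r.end, b) for r, b in oracle]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            merge_union([])
        a = PeakSet("A", [GenomicInterval("chr1", 0, 50)])
        with pytest.raises(ValueError):
            merge_union([a, a])  # duplicate factor labels
        with pytest.raises(ValueError):
            merge_union([a], min_overlap=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {"chrA": 20_000, "chrB": 10_000}
        sets = random_peaksets(rng, list("ABCD"), sizes)
        got = merge_union(sets, min_overlap=1)
        expect = per_base_union(sets, sizes, min_overlap=1)
        assert [(r.chrom, r.start, r.end, b) for r, b in got] == \
            [(r.chrom, r.start, r.end, b) for r, b in expect]

    def test_coverage_conservation(self, rng):
        sizes = {"chrA": 20_000}
        sets = random_peaksets(rng, list("ABC"), sizes)
        regions = merge_union(sets)
        union_bp = sum(len(r) for r, _ in regions)
        cover = np.zeros(20_000, dtype=bool)
        for ps in sets:
            for iv in ps.intervals:
                cover[iv.start:iv.end] = True
        assert union_bp == int(cover.sum())


class TestGeneModels:
    def test_promoter_strand_aware(self):
        plus = GeneModel("g1", "chr1", 5000, 8000, "+")
        assert (plus.promoter.start, plus.promoter.end) == (4000, 5500)
        minus = GeneModel("g2", "chr1", 5000, 8000, "-")
        assert minus.tss == 7999
        assert (minus.promoter.start, minus.promoter.end) == (7500, 9000)

    def test_gtf_round_trip_coordinates(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
                       'chr1\tsrc\tgene\t501\t900\t.\t-\t.\tgene_id "g2";\n')
        genes = read_gene_models(gtf)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in genes] == \
            [("g1", 100, 200, "+"), ("g2", 500, 900, "-")]

    def test_bed12_read(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tg1\t0\t+\n")
        [g] = read_gene_models(bed)
        assert (g.gene_id, g.tss) == ("g1", 100)


def test_chrom_concordance_reports_extras():
    rep = chrom_concordance({"chr1", "chr2"}, {"chr1"}, {"chr1", "chrX"})
    assert rep["input_0"] == {"chr2"}
    assert rep["input_2"] == {"chrX"}
    assert "input_1" not in rep
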
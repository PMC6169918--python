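"""Depth tracks, sufficiency boundaries, and undercoverage calls."""

import numpy as np
import pysam
import pytest

from capaudit.coverage import (
    AuditThresholds,
    DepthTrack,
    RegionIndex,
    SampleCoverage,
    average_exon_coverage,
    call_undercovered_exons,
    call_undercovered_gene,
    count_region_reads,
    depth_track,
    filter_alignments,
    is_sufficient,
    mean_depth_in_loci,
    mean_depth_profile,
    read_coverage_tsv,
    read_depth_tsv,
    summarize_gene_coverage,
    undercovered_cohort,
    write_coverage_tsv,
    write_depth_tsv,
)
from capaudit.intervals import GenomeInterval
from capaudit.simulate import simulate_sam


def make_read(header, start, mapq=60, flag=0, cigar="100M", name="r"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar
    qlen = sum(l for op, l in a.cigartuples if op in (0, 1, 4, 7, 8))
    a.query_sequence = "A" * qlen
    return a


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


class TestThresholds:
    def test_defaults_match_audit_rules(self):
        t = AuditThresholds()
        assert (t.min_mapq, t.min_avg_depth) == (30, 25.0)
        assert (t.cohort_insufficiency_frac, t.base_depth_gt, t.qualifying_frac) == (
            0.75,
            20.0,
            0.80,
        )

    @pytest.mark.parametrize(
        "kwargs", [{"min_avg_depth": 0}, {"qualifying_frac": 1.5}, {"cohort_insufficiency_frac": 0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AuditThresholds(**kwargs)


class TestFilterAlignments:
    def test_mapq_boundary_strict_below(self, header):
        reads = [make_read(header, 10, mapq=29), make_read(header, 10, mapq=30)]
        kept = list(filter_alignments(reads))
        assert [r.mapping_quality for r in kept] == [30]

    @pytest.mark.parametrize("flag", [1024, 4, 256, 2048])
    def test_flagged_reads_dropped(self, header, flag):
        assert list(filter_alignments([make_read(header, 10, flag=flag)])) == []

    def test_missing_cigar_on_mapped_read_errors(self, header):
        bad = make_read(header, 10)
        bad.cigarstring = None
        with pytest.raises(ValueError, match="CIGAR"):
            list(filter_alignments([bad]))

    def test_planted_sam_attrition(self, toy_gene, tmp_path):
        sam = tmp_path / "reads.sam"
        planted = simulate_sam(sam, toy_gene, 300, rng=4)
        with pysam.AlignmentFile(str(sam)) as fh:
            kept = list(filter_alignments(fh))
        assert len(kept) == planted["kept"]


class TestDepthTrack:
    def test_single_read_inside_exon(self, header, single_exon_gene):
        # 100-base read fully inside the 200-base exon
        reads = [make_read(header, 1000)]
        track = depth_track(reads, single_exon_gene, "exon")
        assert track.depths[:100].tolist() == [1] * 100
        assert track.depths[100:].tolist() == [0] * 100

    def test_read_straddling_exon_boundary(self, header, toy_gene):
        # read covers 150..250: only exon1 bases 150..200 are in-region
        reads = [make_read(header, 150)]
        track = depth_track(reads, toy_gene, "exon")
        assert track.depths.sum() == 50

    def test_deletion_bases_not_counted(self, header, single_exon_gene):
        reads = [make_read(header, 1000, cigar="50M10D50M")]
        track = depth_track(reads, single_exon_gene, "exon")
        assert track.depths.sum() == 100
        assert track.depths[50:60].tolist() == [0] * 10

    def test_no_records_all_zero(self, toy_gene):
        track = depth_track([], toy_gene, "exon")
        assert track.depths.sum() == 0 and len(track) == 150

    def test_cds_mode_on_noncoding_errors(self):
        from capaudit.intervals import GeneModel

        nc = GeneModel("NC", "chr1", "+", (GenomeInterval("chr1", 0, 100),), ())
        with pytest.raises(ValueError, match="empty region"):
            depth_track([], nc, "cds")

    def test_track_sum_equals_aligned_bases_in_region(self, toy_gene, tmp_path):
        """Read-based and depth-based base accounting agree exactly."""
        sam = tmp_path / "reads.sam"
        simulate_sam(sam, toy_gene, 200, rng=8)
        with pysam.AlignmentFile(str(sam)) as fh:
            kept = list(filter_alignments(fh))
        track = depth_track(kept, toy_gene, "exon")
        index = RegionIndex(toy_gene, "exon")
        expected = sum(
            hi - lo
            for rec in kept
            for bs, be in [(b, e) for b, e in rec.get_blocks()]
            for lo, hi in index.project(bs, be)
        )
        assert int(track.depths.sum()) == expected
        assert count_region_reads(kept, toy_gene) <= len(kept)


class TestSufficiency:
    def test_average(self):
        assert average_exon_coverage(DepthTrack("G", "exon", [10, 20, 30, 40])) == 25

    @pytest.mark.parametrize("avg,ok", [(24.9, False), (25.0, True), (6.4, False), (0, False)])
    def test_boundary_inclusive_at_25(self, avg, ok):
        assert is_sufficient(avg) is ok

    @pytest.mark.parametrize(
        "n_insufficient,n,expected", [(76, 100, True), (75, 100, False), (0, 10, False)]
    )
    def test_undercovered_cohort_strictly_over_75(self, n_insufficient, n, expected):
        flags = [False] * n_insufficient + [True] * (n - n_insufficient)
        assert undercovered_cohort(flags) is expected
        assert undercovered_cohort(flags[::-1]) is expected  # order-invariant

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="no samples"):
            undercovered_cohort([])


class TestMeanProfileAndCalls:
    def test_mean_profile_elementwise(self):
        tracks = [DepthTrack("G", "exon", [10, 30]), DepthTrack("G", "exon", [40, 10])]
        assert mean_depth_profile(tracks).tolist() == [25, 20]
        assert mean_depth_profile(tracks[:1]).tolist() == [10, 30]

    def test_mean_profile_length_mismatch(self):
        tracks = [DepthTrack("G", "exon", [1, 2]), DepthTrack("G", "exon", [1, 2, 3])]
        with pytest.raises(ValueError, match="share"):
            mean_depth_profile(tracks)

    def test_base_at_exactly_20_does_not_qualify(self):
        call = call_undercovered_gene(np.array([25.0, 20.0]), "G")
        assert call.qualifying_fraction == 0.5
        assert call.status == "undercovered_incomplete"

    def test_zero_profile_is_absent(self):
        call = call_undercovered_gene(np.zeros(100), "G")
        assert call.status == "undercovered_absent"
        assert call.qualifying_fraction == 0.0

    def test_incomplete_at_45_percent(self):
        profile = np.array([30.0] * 45 + [5.0] * 55)
        call = call_undercovered_gene(profile, "G")
        assert call.qualifying_fraction == pytest.approx(0.45)
        assert call.status == "undercovered_incomplete"

    def test_covered_at_80_percent_boundary(self):
        profile = np.array([30.0] * 80 + [5.0] * 20)
        assert call_undercovered_gene(profile, "G").status == "covered"

    def test_exon_flags(self):
        profiles = [np.zeros(10), np.full(10, 30.0), np.full(10, 30.0)]
        flags, all_under = call_undercovered_exons(profiles)
        assert flags == (True, False, False) and not all_under
        flags, all_under = call_undercovered_exons([np.zeros(5), np.zeros(8)])
        assert all_under

    def test_absent_gene_implies_all_exons_flagged(self):
        profile = np.zeros(150)
        slices = [slice(0, 100), slice(100, 150)]
        call = call_undercovered_gene(profile, "G", exon_slices=slices)
        assert call.status == "undercovered_absent"
        assert call.all_exons_undercovered

    def test_single_exon_gene_consistency(self):
        profile = np.array([30.0] * 5 + [1.0] * 5)
        call = call_undercovered_gene(profile, "G", exon_slices=[slice(0, 10)])
        assert call.exon_flags == (call.status != "covered",)

    @pytest.mark.parametrize("mode", ["base", "frac"])
    def test_threshold_monotonicity(self, mode):
        rng = np.random.default_rng(17)
        profiles = [rng.poisson(25, size=200).astype(float) for _ in range(20)]
        prev_under = None
        for cut in range(10, 41, 5):
            if mode == "base":
                thr = AuditThresholds(base_depth_gt=float(cut))
            else:
                thr = AuditThresholds(qualifying_frac=cut / 50.0)
            under = {
                i
                for i, p in enumerate(profiles)
                if call_undercovered_gene(p, str(i), thr).status != "covered"
            }
            if prev_under is not None:
                assert prev_under <= under  # stricter thresholds only add genes
            prev_under = under


class TestLociAndIO:
    def test_mean_depth_in_loci(self, single_exon_gene):
        depths = np.zeros(200)
        depths[10:13] = [5, 10, 15]
        track = DepthTrack("TOY2", "exon", depths)
        loci = [GenomeInterval("chr1", 1010, 1013), GenomeInterval("chr1", 1100, 1110)]
        means = mean_depth_in_loci(track, single_exon_gene, loci)
        assert means == [10.0, 0.0]

    def test_constant_depth(self, single_exon_gene):
        track = DepthTrack("TOY2", "exon", np.full(200, 60))
        (mean,) = mean_depth_in_loci(track, single_exon_gene, [GenomeInterval("chr1", 1000, 1200)])
        assert mean == 60.0

    def test_locus_outside_region_named_in_error(self, single_exon_gene):
        track = DepthTrack("TOY2", "exon", np.zeros(200))
        with pytest.raises(ValueError, match="chr1:500-600"):
            mean_depth_in_loci(track, single_exon_gene, [GenomeInterval("chr1", 500, 600)])

    def test_depth_tsv_fills_missing_positions(self, tmp_path, toy_gene):
        p = tmp_path / "depth.tsv"
        # 1-based positions 101..103 within exon1 (region offsets 0..2)
        p.write_text("chr1\t101\t7\nchr1\t102\t8\nchr1\t103\t9\n")
        tracks = read_depth_tsv(p, [toy_gene], "exon")
        track = tracks["S1"]["TOY1"]
        assert track.depths[:3].tolist() == [7, 8, 9]
        assert track.depths[3:].sum() == 0 and len(track) == 150

    def test_depth_tsv_duplicate_position_errors(self, tmp_path, toy_gene):
        p = tmp_path / "depth.tsv"
        p.write_text("chr1\t101\t7\nchr1\t101\t8\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_depth_tsv(p, [toy_gene])

    def test_depth_tsv_outside_positions_skipped(self, tmp_path, toy_gene, caplog):
        p = tmp_path / "depth.tsv"
        p.write_text("chr1\t50\t3\n")
        with caplog.at_level("WARNING"):
            tracks = read_depth_tsv(p, [toy_gene])
        assert tracks["S1"]["TOY1"].depths.sum() == 0
        assert "outside" in caplog.text

    def test_depth_tsv_round_trip(self, tmp_path, toy_gene):
        rng = np.random.default_rng(2)
        tracks = {
            sid: {"TOY1": DepthTrack("TOY1", "exon", rng.poisson(30, 150))}
            for sid in ("a", "b")
        }
        p = tmp_path / "depth.tsv"
        write_depth_tsv(p, [toy_gene], tracks)
        back = read_depth_tsv(p, [toy_gene], "exon")
        for sid in ("a", "b"):
            assert np.array_equal(back[sid]["TOY1"].depths, tracks[sid]["TOY1"].depths)

    def test_coverage_tsv_round_trip_recomputes_sufficiency(self, tmp_path):
        rows = [
            SampleCoverage("s1", "G", 120, 30.0, True, "C", "k"),
            SampleCoverage("s2", "G", 10, 2.5, False, "C", "k"),
        ]
        p = tmp_path / "cov.tsv"
        write_coverage_tsv(rows, p)
        back = read_coverage_tsv(p)
        assert [r.sufficient for r in back] == [True, False]
        strict = read_coverage_tsv(p, AuditThresholds(min_avg_depth=50))
        assert [r.sufficient for r in strict] == [False, False]

    def test_summarize_gene_coverage(self):
        rows = [
            SampleCoverage(f"s{i}", "G", c, c / 10, c / 10 >= 25, "C", "k")
            for i, c in enumerate([5, 12, 40, 1500, 12])
        ]
        s = summarize_gene_coverage(rows, read_count_below=1000)
        assert s["n_samples"] == 5
        assert s["n_below_read_count"] == 4
        assert s["median_read_count"] == 12
        assert s["max_avg_coverage"] == 150.0
        assert s["n_sufficient"] == 1
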
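import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import per_base_cigar_gaps

from fusionlens.alignment_analysis import (
    SplitReadEvent,
    compute_coverage,
    count_junctions,
    count_library_size,
    displayed_junctions,
    extract_split_reads,
    filter_split_reads,
    gaps_and_flanks,
    normalize_rpm,
    summarize_fusion_support,
)


def cigartuples(cigar: str):
    import re

    ops = "MIDNSHP=X"
    return [(ops.index(op), int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]


class TestGapsAndFlanks:
    def test_single_gap_with_flanks(self):
        gaps, flanks = gaps_and_flanks(cigartuples("4M100N50M"), 96)
        assert gaps == [(100, 200)]
        assert flanks == [(4, 50)]

    def test_ungapped_read_has_no_gaps(self):
        gaps, _ = gaps_and_flanks(cigartuples("50M"), 0)
        assert gaps == []

    def test_middle_segment_counts_for_both_gaps(self):
        gaps, flanks = gaps_and_flanks(cigartuples("10M20N10M30N10M"), 0)
        assert gaps == [(10, 30), (40, 70)]
        assert flanks == [(10, 10), (10, 10)]

    def test_deletion_consumes_reference_but_not_flank(self):
        gaps, flanks = gaps_and_flanks(cigartuples("5M2D3M10N6M"), 0)
        assert gaps == [(10, 20)]
        assert flanks == [(8, 6)]  # D adds 2 to ref walk but not to flank

    def test_soft_clips_do_not_consume_reference(self):
        gaps, flanks = gaps_and_flanks(cigartuples("3S7M10N5M2S"), 100)
        assert gaps == [(107, 117)]
        assert flanks == [(7, 5)]

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.integers(0, 500),
        st.lists(
            st.tuples(st.sampled_from([0, 2, 3, 7, 8, 1, 4]), st.integers(1, 30)),
            min_size=1,
            max_size=8,
        ),
    )
    def test_agrees_with_per_base_oracle(self, pos, ops):
        # drop adjacent N ops (aligners never emit them) and leading/trailing clip oddities
        cleaned = []
        for op, ln in ops:
            if cleaned and op == 3 and cleaned[-1][0] == 3:
                continue
            cleaned.append((op, ln))
        expected = per_base_cigar_gaps(cleaned, pos)
        assert gaps_and_flanks(cleaned, pos) == expected


class TestExtractSplitReads:
    def test_only_gapped_primary_reads_yield_events(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            {"REF": 1000},
            [
                {"name": "split", "ref": "REF", "pos": 96, "cigar": "4M100N50M"},
                {"name": "plain", "ref": "REF", "pos": 0, "cigar": "50M"},
                {"name": "secondary", "ref": "REF", "pos": 96, "cigar": "4M100N50M", "flag": 256},
                {"name": "supp", "ref": "REF", "pos": 96, "cigar": "4M100N50M", "flag": 2048},
            ],
        )
        events = extract_split_reads(str(sam), "REF")
        assert [e.read_id for e in events] == ["split"]
        assert events[0].gaps == [(100, 200)]
        assert events[0].flank_per_gap == [(4, 50)]


def event(flanks, gaps=None, refname="REF", read_id="r"):
    gaps = gaps or [(100 * (i + 1), 100 * (i + 1) + 50) for i in range(len(flanks))]
    return SplitReadEvent(read_id=read_id, refname=refname, gaps=gaps, flank_per_gap=flanks)


class TestFlankFilter:
    def test_four_base_flank_removed_five_retained(self):
        events = [event([(4, 50)], read_id="a"), event([(5, 50)], read_id="b")]
        retained = filter_split_reads(events, min_flank=5)
        assert [e.read_id for e in retained] == ["b"]

    def test_zero_threshold_retains_all(self):
        events = [event([(1, 1)]), event([(4, 50)])]
        assert filter_split_reads(events, min_flank=0) == events

    def test_worst_gap_governs_multi_gap_reads(self):
        ev = event([(20, 20), (3, 20)])
        assert filter_split_reads([ev], min_flank=5) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=1, max_size=5))
    def test_monotone_in_threshold(self, flank_list):
        events = [event([f]) for f in flank_list]
        sizes = [len(filter_split_reads(events, min_flank=k)) for k in range(8)]
        assert sizes == sorted(sizes, reverse=True)


class TestCountJunctions:
    def test_support_counts_and_threshold(self):
        events = [event([(10, 10)], gaps=[(100, 200)], read_id=f"a{i}") for i in range(3)]
        events += [event([(10, 10)], gaps=[(300, 400)], read_id=f"b{i}") for i in range(2)]
        junctions = count_junctions(events)
        by_key = {(j.start, j.end): j.support for j in junctions}
        assert by_key == {(100, 200): 3, (300, 400): 2}
        shown = displayed_junctions(junctions, min_support=3)
        assert [(j.start, j.end) for j in shown] == [(100, 200)]

    def test_boundary_crossing_flag(self):
        events = [
            event([(10, 10)], gaps=[(480, 620)], read_id="x"),
            event([(10, 10)], gaps=[(100, 200)], read_id="y"),
        ]
        junctions = count_junctions(events, boundary=500)
        flags = {(j.start, j.end): j.crosses_boundary for j in junctions}
        assert flags == {(480, 620): True, (100, 200): False}

    def test_motif_from_reference_sequence(self):
        refseq = "A" * 100 + "GT" + "C" * 96 + "AG" + "A" * 100
        events = [event([(10, 10)], gaps=[(100, 200)])]
        (junction,) = count_junctions(events, refseq=refseq)
        assert junction.motif == "GT/AG"

    def test_support_sum_equals_gap_observations(self):
        events = [
            event([(10, 10), (10, 10)], gaps=[(10, 20), (30, 40)], read_id="two-gap"),
            event([(10, 10)], gaps=[(10, 20)], read_id="one-gap"),
        ]
        junctions = count_junctions(events)
        assert sum(j.support for j in junctions) == 3

    def test_monotone_in_min_support(self):
        events = [
            event([(10, 10)], gaps=[(100, 200)], read_id=f"r{i}") for i in range(4)
        ] + [event([(10, 10)], gaps=[(300, 400)], read_id="solo")]
        junctions = count_junctions(events)
        sizes = [len(displayed_junctions(junctions, min_support=k)) for k in range(6)]
        assert sizes == sorted(sizes, reverse=True)


class TestCoverage:
    def test_gap_contributes_no_depth(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            {"REF": 300},
            [{"name": "r", "ref": "REF", "pos": 96, "cigar": "4M100N50M"}],
        )
        track = compute_coverage(str(sam), "REF")
        assert track.values[96:100].tolist() == [1] * 4
        assert track.values[100:200].sum() == 0
        assert track.values[200:250].tolist() == [1] * 50

    def test_empty_alignments_give_zero_track(self, tmp_path, sam_writer):
        sam = sam_writer(tmp_path / "a.sam", {"REF": 100}, [])
        track = compute_coverage(str(sam), "REF")
        assert track.values.sum() == 0 and len(track.values) == 100

    def test_stacked_reads_sum(self, tmp_path, sam_writer):
        recs = [{"name": f"r{i}", "ref": "REF", "pos": 10, "cigar": "20M"} for i in range(2)]
        sam = sam_writer(tmp_path / "a.sam", {"REF": 100}, recs)
        track = compute_coverage(str(sam), "REF")
        assert track.values[10:30].tolist() == [2] * 20

    def test_depth_sum_equals_aligned_bases(self, tmp_path, sam_writer):
        recs = [
            {"name": "a", "ref": "REF", "pos": 0, "cigar": "10M5N10M"},
            {"name": "b", "ref": "REF", "pos": 3, "cigar": "7M2D8M"},
            {"name": "sec", "ref": "REF", "pos": 0, "cigar": "30M", "flag": 256},
        ]
        sam = sam_writer(tmp_path / "a.sam", {"REF": 200}, recs)
        track = compute_coverage(str(sam), "REF")
        assert track.values.sum() == (10 + 10) + (7 + 8)  # secondary excluded


class TestRpm:
    def test_closed_form(self, tmp_path, sam_writer):
        sam = sam_writer(
            tmp_path / "a.sam",
            {"REF": 50},
            [{"name": "r", "ref": "REF", "pos": 0, "cigar": "10M"}],
        )
        track = compute_coverage(str(sam), "REF")
        rpm = normalize_rpm(track, library_size=2_000_000)
        assert rpm.values[0] == pytest.approx(0.5)
        assert rpm.scale == "rpm" and rpm.library_size == 2_000_000

    def test_million_read_library_is_identity(self):
        from fusionlens.alignment_analysis import CoverageTrack

        track = CoverageTrack(refname="REF", values=np.array([10, 0, 3]))
        rpm = normalize_rpm(track, 10**6)
        assert rpm.values.tolist() == [10.0, 0.0, 3.0]

    def test_double_normalization_is_error(self):
        from fusionlens.alignment_analysis import CoverageTrack

        track = CoverageTrack(refname="REF", values=np.array([1.0]))
        rpm = normalize_rpm(track, 100)
        with pytest.raises(ValueError, match="already"):
            normalize_rpm(rpm, 100)

    def test_zero_library_is_error(self):
        from fusionlens.alignment_analysis import CoverageTrack

        with pytest.raises(ValueError):
            normalize_rpm(CoverageTrack(refname="REF", values=np.array([1])), 0)

    def test_library_size_counts_each_primary_read_once(self, tmp_path, sam_writer):
        recs = [
            {"name": "a", "ref": "REF", "pos": 0, "cigar": "10M"},
            {"name": "a", "ref": "REF", "pos": 20, "cigar": "10M", "flag": 256},
            {"name": "b", "ref": "REF", "pos": 0, "cigar": "5M3N5M"},
        ]
        sam = sam_writer(tmp_path / "a.sam", {"REF": 100}, recs)
        assert count_library_size(str(sam)) == 2


class TestSummarizeFusionSupport:
    def junction(self, start, end, support, crosses=True):
        from fusionlens.alignment_analysis import Junction

        return Junction(
            refname="F", start=start, end=end, support=support, crosses_boundary=crosses
        )

    def test_single_crossing_junction(self):
        table, total = summarize_fusion_support([self.junction(480, 620, 7)], [(479, 620)])
        assert total == 7
        assert table.loc[0, "distance_to_expected"] == 0

    def test_no_crossing_junctions_flags_no_support(self):
        table, total = summarize_fusion_support([self.junction(10, 20, 9, crosses=False)])
        assert total == 0 and table.empty

    def test_two_isoforms_sum_and_nearest_match(self):
        junctions = [self.junction(480, 620, 5), self.junction(400, 620, 3)]
        expected = [(479, 620), (399, 620)]
        table, total = summarize_fusion_support(junctions, expected)
        assert total == 8 and len(table) == 2
        assert table["distance_to_expected"].tolist() == [0, 0]
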
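"""Internal junction extraction, correction, and event classification."""

from __future__ import annotations

import pytest

from circas.backsplice import BackSpliceJunction
from circas.events import (
    AnnotationIndex,
    DetectParams,
    InternalJunction,
    assign_reads_to_circ,
    call_sample,
    classify_events,
    correct_junctions,
    extract_internal_junctions,
)
from circas.io import AlignedRead, ExonModel, GenomeRef, Segment


def _read(name, blocks, chrom="chrT", mate=1, strand="+"):
    qlen = sum(e - s + 1 for s, e in blocks)
    return AlignedRead(
        read_name=name, chrom=chrom, strand=strand, blocks=tuple(blocks),
        clip5=0, clip3=0, mate_number=mate, query_len=qlen,
    )


def _junction(donor, acceptor, support=3, chrom="chrT", ids=None):
    ids = ids if ids is not None else frozenset((f"j{donor}-{i}", 1) for i in range(support))
    return InternalJunction(
        chrom=chrom, donor=donor, acceptor=acceptor, support=support,
        motif_ok=True, corrected=True, read_ids=ids,
    )


class TestJunctionExtraction:
    def test_gap_arithmetic_with_canonical_flanks(self, toy_genome):
        reads = [_read("a", [(101, 150), (1151, 1200)])]
        (j,) = extract_internal_junctions(reads, toy_genome)
        assert (j.donor, j.acceptor) == (150, 1151)
        assert j.support == 1

    def test_noncanonical_gap_dropped(self, toy_genome):
        # gap at 300..900 has AA/AA flanks in the toy genome
        reads = [_read("a", [(250, 300), (901, 950)])]
        assert extract_internal_junctions(reads, toy_genome) == []

    def test_distinct_read_support(self, toy_genome):
        reads = [
            _read("a", [(101, 150), (1151, 1200)]),
            _read("a", [(120, 150), (1151, 1230)], mate=2),
            _read("b", [(130, 150), (1151, 1210)]),
        ]
        (j,) = extract_internal_junctions(reads, toy_genome)
        assert j.support == 3

    def test_sub_threshold_gap_is_not_a_junction(self, toy_genome):
        reads = [_read("a", [(101, 150), (170, 220)])]  # gap 19 < 30
        assert extract_internal_junctions(reads, toy_genome) == []


class TestCorrection:
    @pytest.fixture()
    def index(self):
        m = ExonModel("t1", "g1", "G1", "chrT", "+", ((101, 200), (301, 400), (501, 600)))
        return AnnotationIndex([m])

    def test_donor_matching_exon_end_kept(self, index):
        (j,) = correct_junctions([_junction(200, 450)], index)
        assert j.corrected

    def test_acceptor_matching_exon_start_kept(self, index):
        (j,) = correct_junctions([_junction(250, 301)], index)
        assert j.corrected

    def test_both_sides_unmatched_discarded(self, index):
        assert correct_junctions([_junction(250, 450)], index) == []

    def test_offset_by_three_discarded(self, index):
        # boundaries shifted +3 from every annotated edge
        assert correct_junctions([_junction(203, 304)], index) == []

    def test_keep_uncorrected_flagging(self, index):
        (j,) = correct_junctions([_junction(250, 450)], index, keep_uncorrected=True)
        assert not j.corrected


def _circ(start=100, end=2000, strand="+", chrom="chrT"):
    return BackSpliceJunction(chrom, start, end, strand, 10, "GTAG" if strand == "+" else "CTAC")


class TestClassification:
    def test_a5ss_from_shared_acceptor(self):
        # donors 500 and 533 share acceptor 2000: a 33 bp alternative segment
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (2000, 2100)))]
        )
        events = classify_events(
            [_junction(500, 2000, 4), _junction(533, 2000, 2)], [], index, circ
        )
        (ev,) = events
        assert ev.event_type == "A5SS"
        assert (ev.alt_start, ev.alt_end) == (501, 533)
        assert ev.alt_len == 33
        assert ev.incl_reads == 2 and ev.excl_reads == 4
        assert ev.shared_site == 2000 and ev.pair_side == "right"

    def test_a3ss_from_shared_donor(self):
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (1200, 2000)))]
        )
        events = classify_events(
            [_junction(500, 1200, 5), _junction(500, 1255, 3)], [], index, circ
        )
        (ev,) = events
        assert ev.event_type == "A3SS"
        assert (ev.alt_start, ev.alt_end) == (1200, 1254)
        assert ev.incl_reads == 5 and ev.excl_reads == 3

    def test_pair_naming_follows_strand(self):
        # same junction geometry on a minus-strand circle swaps the label
        circ = _circ(strand="-")
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "-", ((100, 500), (2000, 2100)))]
        )
        (ev,) = classify_events(
            [_junction(500, 2000, 4), _junction(533, 2000, 2)], [], index, circ
        )
        assert ev.event_type == "A3SS"

    def test_skipped_exon_with_junction_evidence(self):
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (900, 994), (1500, 2000)))]
        )
        junctions = [
            _junction(500, 1500, 3),  # skipping junction over exon (900, 994)
            _junction(500, 900, 4),   # inclusion junctions
            _junction(994, 1500, 5),
        ]
        events = classify_events(junctions, [], index, circ)
        assert [ev.event_type for ev in events] == ["SE"]
        (ev,) = events
        assert (ev.alt_start, ev.alt_end) == (900, 994)
        assert ev.alt_len == 95
        assert ev.excl_reads == 3 and ev.incl_reads == 9

    def test_se_suppresses_spurious_pair_calls(self):
        # the skip junction shares boundaries with each inclusion junction;
        # those pairs must not surface as A5SS/A3SS
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (900, 994), (1500, 2000)))]
        )
        junctions = [_junction(500, 1500, 3), _junction(500, 900, 4), _junction(994, 1500, 5)]
        events = classify_events(junctions, [], index, circ)
        assert {ev.event_type for ev in events} == {"SE"}

    def test_retained_intron_needs_spanning_read(self):
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (601, 2000)))]
        )
        junctions = [_junction(500, 601, 6)]
        no_span = classify_events(junctions, [_read("x", [(450, 520)])], index, circ)
        assert no_span == []
        spanning = [_read("x", [(440, 610)])]  # single block across the intron
        (ev,) = classify_events(junctions, spanning, index, circ)
        assert ev.event_type == "RI"
        assert (ev.alt_start, ev.alt_end) == (501, 600)
        assert ev.alt_len == 100
        assert ev.incl_reads == 1 and ev.excl_reads == 6

    def test_single_junction_no_events(self):
        circ = _circ()
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (1500, 2000)))]
        )
        assert classify_events([_junction(500, 1500, 9)], [], index, circ) == []

    def test_event_outside_circle_discarded(self):
        circ = _circ(start=600, end=2000)
        index = AnnotationIndex(
            [ExonModel("t", "g", "G", "chrT", "+", ((100, 500), (2000, 2100)))]
        )
        events = classify_events(
            [_junction(500, 2000, 4), _junction(533, 2000, 2)], [], index, circ
        )
        assert events == []  # alternative segment 501..533 lies before the circle

    def test_host_tiebreak_prefers_coding(self):
        circ = _circ()
        coding = ExonModel("tc", "gc", "CODY", "chrT", "+", ((100, 500), (2000, 2100)),
                           biotype="mRNA")
        lnc = ExonModel("tl", "gl", "LINCY", "chrT", "+", ((100, 500), (2000, 2090)),
                        biotype="lncRNA")
        index = AnnotationIndex([lnc, coding])
        (ev,) = classify_events(
            [_junction(500, 2000, 4), _junction(533, 2000, 2)], [], index, circ
        )
        assert ev.host_gene == "CODY" and ev.host_biotype == "mRNA"


class TestAssignment:
    def _bsj_read(self, name, circ, mate=1):
        first = (circ.end - 91, circ.end)
        second = (circ.start, circ.start + 57)
        return AlignedRead(
            read_name=name, chrom=circ.chrom, strand="+", blocks=(first,),
            clip5=0, clip3=58, mate_number=mate, query_len=92,
            supplementary=[Segment(circ.chrom, "+", (second,), 92, 58)],
        )

    def test_spanning_read_and_internal_mate_assigned(self):
        circ = _circ(start=1000, end=5000)
        r1 = self._bsj_read("p", circ, mate=1)
        r2 = _read("p", [(2000, 2099)], mate=2)
        assigned = assign_reads_to_circ(circ, [r1, r2])
        assert {r.read_id for r in assigned} == {("p", 1), ("p", 2)}

    def test_external_mate_excluded(self):
        circ = _circ(start=1000, end=5000)
        r1 = self._bsj_read("p", circ, mate=1)
        r2 = _read("p", [(5500, 5599)], mate=2)  # 500 bp outside the circle
        assigned = assign_reads_to_circ(circ, [r1, r2])
        assert {r.read_id for r in assigned} == {("p", 1)}

    def test_unlinked_background_read_not_assigned(self):
        circ = _circ(start=1000, end=5000)
        bg = _read("bg", [(1500, 1599)])
        assert assign_reads_to_circ(circ, [bg]) == []

    def test_simulated_assignment_matches_truth(self, small_bundle, small_reads, small_run):
        bsjs, _ = small_run
        by_circ = {(b.chrom, b.start, b.end): b for b in bsjs}
        for circle in small_bundle.circles:
            bsj = by_circ[(circle.chrom, circle.start, circle.end)]
            assigned = assign_reads_to_circ(bsj, small_reads)
            assert assigned, "every planted circle has assigned reads"
            for read in assigned:
                assert not read.read_name.startswith("bg")


class TestCallSample:
    def test_empty_input_empty_output(self, small_bundle):
        bsjs, events = call_sample([], small_bundle.genome, small_bundle.models)
        assert bsjs == [] and events == []

    def test_deterministic_rerun(self, small_bundle, small_reads):
        run1 = call_sample(small_reads, small_bundle.genome, small_bundle.models)
        run2 = call_sample(small_reads, small_bundle.genome, small_bundle.models)
        assert [b for b in run1[0]] == [b for b in run2[0]]
        assert [e.key for e in run1[1]] == [e.key for e in run2[1]]

    def test_event_invariants(self, small_run):
        bsjs, events = small_run
        for ev in events:
            assert ev.circ.start <= ev.alt_start <= ev.alt_end <= ev.circ.end
            assert ev.incl_reads >= 1 and ev.excl_reads >= 1
            assert ev.alt_len > 0
            assert ev.circ.motif in ("GTAG", "CTAC")

    def test_no_correct_keeps_novel_junction_events(self, small_bundle, small_reads):
        # the planted annotation-unmatched decoy pair only surfaces when
        # correction is explicitly disabled
        params = DetectParams(correct=False)
        _, events = call_sample(
            small_reads, small_bundle.genome, small_bundle.models, params=params
        )
        uc = {(d.wb_alt_start, d.wb_alt_end) for d in small_bundle.decoys
              if d.kind == "uncorrected"}
        got = {(ev.alt_start, ev.alt_end) for ev in events}
        assert uc & got, "uncorrected decoy pair should appear without correction"
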
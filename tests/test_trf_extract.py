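"""Staged tRF extraction: CCA selection, positional classification, spanner
isolation, snoRF capture and stage-count conservation."""

import numpy as np
import pytest

from trnafrag.io_preprocess import Read, ReadSet
from trnafrag.matcher import Alignment, MatchIndex
from trnafrag.refbuild import ReferenceEntry, ReferenceSet, build_cca_edited
from trnafrag.simulate import truth_evaluate
from trnafrag.trf_extract import (
    TRFClass,
    classify_trf,
    extract_snorfs,
    extract_spanners,
    run_trf_workflow,
    select_cca_reads,
)

RNG = np.random.default_rng(17)


def random_seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


class TestSelectCCA:
    @pytest.mark.parametrize("seq,is_cca", [
        ("ACGTCCA", True), ("ACGTCCG", False), ("CCA", True),
        ("ACGTCCAA", False), ("CCAACGT", False),
    ])
    def test_partition_rule(self, seq, is_cca):
        cca, non_cca = select_cca_reads(ReadSet([Read("r", seq)], "s"))
        assert (len(cca), len(non_cca)) == ((1, 0) if is_cca else (0, 1))


def anchors(edited=False, ms=25, ep=100):
    seq = random_seq(180 + (3 if edited else 0))
    if edited:
        seq = seq[:ep] + "CCA" + seq[ep : 180]
    return ReferenceEntry("t", seq, leader_len=ms, mature_start=ms,
                          editing_point=ep, trailer_len=80, edited=edited)


def aln(start, length):
    return Alignment("r", "t", start, start + length, length, "first", 1)


class TestClassify:
    # non-edited coordinates; mature_start=25, editing_point=100
    @pytest.mark.parametrize("start,length,expected", [
        (25, 18, TRFClass.FIVE_PRIME),    # at the mature 5' end
        (27, 18, TRFClass.FIVE_PRIME),    # within the tolerance window
        (100, 20, TRFClass.TRF1),         # at the RNase Z cleavage point
        (98, 20, TRFClass.TRF1),
        (103, 20, TRFClass.TARF),         # downstream of the junction
        (140, 20, TRFClass.TARF),
        (10, 15, TRFClass.LEADER),        # confined to the 5' leader
        (8, 17, TRFClass.LEADER),         # ragged end ending at ms+tolerance? end=25
        (40, 20, TRFClass.I_TRF),         # strictly internal
        (28, 20, TRFClass.I_TRF),
        (20, 20, TRFClass.UNCLASSIFIED),  # straddles the mature start oddly
        (90, 20, TRFClass.UNCLASSIFIED),  # crosses the junction (spanner geometry)
    ])
    def test_non_edited_positions(self, start, length, expected):
        assert classify_trf(aln(start, length), anchors(), w=2) is expected

    def test_three_prime_cca_on_edited_reference(self):
        a = anchors(edited=True)
        read_end = a.editing_point + 3
        sequence = a.sequence[read_end - 18 : read_end]
        assert sequence.endswith("CCA")
        got = classify_trf(aln(read_end - 18, 18), a, w=2, sequence=sequence)
        assert got is TRFClass.THREE_PRIME_CCA

    def test_edited_placement_off_junction_is_unclassified(self):
        a = anchors(edited=True)
        got = classify_trf(aln(30, 18), a, w=2, sequence=a.sequence[30:48])
        assert got is TRFClass.UNCLASSIFIED

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_trf(aln(25, 18), anchors(), w=-1)


class TestSpannerOracle:
    def test_spanners_equal_junction_overlap_set(self, trf_collection,
                                                 reference_sets, clipped_reads):
        """extract_spanners must equal {non-CCA placements whose interval
        strictly contains the editing point}, including body-only and
        trailer-only controls which must match the edited set."""
        ne = reference_sets["non_edited"]
        ne_ix, ed_ix = MatchIndex(ne), MatchIndex(reference_sets["cca_edited"])
        by_id = {r.read_id: r for r in clipped_reads}
        noncca = [
            Alignment(r.read_id, r.ref_name, r.start, r.end,
                      r.end - r.start, "random", 1)
            for r in trf_collection.records if r.reference_kind == "non_edited"
        ]
        predicted = {r.read_id for r in
                     extract_spanners(noncca, by_id, ed_ix, ne_ix)}
        anchors = ne.anchors
        oracle = {a.read_id for a in noncca
                  if a.start < anchors[a.ref_name].editing_point < a.end}
        assert predicted == oracle
        assert predicted  # fixture contains spanners

    def test_body_and_trailer_reads_are_not_spanners(self, reference_sets):
        ne = reference_sets["non_edited"]
        ed_ix = MatchIndex(reference_sets["cca_edited"])
        ne_ix = MatchIndex(ne)
        entry = ne.entries[0]
        ep = entry.editing_point
        body_read = Read("body", entry.sequence[30:50])
        trailer_read = Read("trail", entry.sequence[ep + 5 : ep + 25])
        alns = [Alignment("body", entry.name, 30, 50, 20, "first", 1),
                Alignment("trail", entry.name, ep + 5, ep + 25, 20, "first", 1)]
        out = extract_spanners(alns, {"body": body_read, "trail": trailer_read},
                               ed_ix, ne_ix)
        assert out == []


class TestWorkflow:
    def test_all_classes_recovered_and_counts_conserved(self, trf_collection, simulated):
        _, truth = simulated
        conf, metrics = truth_evaluate(trf_collection, truth)
        assert (metrics["recall"] == 1.0).all()
        assert (metrics["precision"] == 1.0).all()
        c = trf_collection.stage_counts
        assert c["post_rRNA"] == c["input"] - c["rRNA"]
        assert (c["snoRF"] + c["non_CCA_tRF"] + c["CCA_tRF"] + c["unmatched"]
                == c["post_rRNA"])

    def test_no_duplicate_read_ids_in_all_trfs(self, trf_collection):
        ids = [r.read_id for r in trf_collection.records]
        assert len(ids) == len(set(ids))

    def test_every_placement_gets_exactly_one_class(self, trf_collection):
        assert all(isinstance(r.trf_class, TRFClass) for r in trf_collection.records)

    def test_library_without_trna_reads_exits_unmatched(self, reference_sets):
        reads = ReadSet([Read(f"r{i}", random_seq(20)) for i in range(10)], "s")
        coll = run_trf_workflow(reads, None, None, None,
                                reference_sets["non_edited"],
                                reference_sets["cca_edited"], seed=1)
        assert coll.records == [] and coll.snorf_records == []
        assert coll.stage_counts["unmatched"] == 10

    def test_read_matching_snorna_and_trna_stops_at_snorna_stage(self):
        shared = random_seq(20)
        body = random_seq(40) + shared + random_seq(40)  # 100-nt "gene body"
        ne = ReferenceSet([ReferenceEntry("t1", random_seq(25) + body + random_seq(80),
                                          mature_start=25, editing_point=125)],
                          "non_edited")
        ed = build_cca_edited(ne)
        sno = ReferenceSet([ReferenceEntry("sno1", random_seq(30) + shared + random_seq(30),
                                           leader_len=0, mature_start=0,
                                           editing_point=0, trailer_len=0)],
                           "snoRNA_CD")
        reads = ReadSet([Read("r", shared)], "s")
        coll = run_trf_workflow(reads, None, sno, None, ne, ed, seed=1)
        assert [s.read_id for s in coll.snorf_records] == ["r"]
        assert coll.records == []

    def test_mismatched_reference_sets_rejected(self, reference_sets):
        ne = reference_sets["non_edited"]
        truncated = ReferenceSet(reference_sets["cca_edited"].entries[:-1],
                                 "cca_edited")
        with pytest.raises(ValueError, match="different genes"):
            run_trf_workflow(ReadSet([Read("r", "ACGT" * 5)], "s"),
                             None, None, None, ne, truncated, seed=1)


class TestSnoRF:
    def test_box_and_half_labels(self, reference_sets):
        cd_ix = MatchIndex(reference_sets["snoRNA_CD"])
        haca_ix = MatchIndex(reference_sets["snoRNA_HACA"])
        cd_entry = reference_sets["snoRNA_CD"].entries[0]
        haca_entry = reference_sets["snoRNA_HACA"].entries[0]
        reads = ReadSet([
            Read("cd3p", cd_entry.sequence[-20:]),
            Read("cd5p", cd_entry.sequence[:20]),
            Read("haca", haca_entry.sequence[5:25]),
        ], "s")
        records, remaining = extract_snorfs(reads, cd_ix, haca_ix, seed=0)
        by_id = {r.read_id: r for r in records}
        assert by_id["cd3p"].box == "CD" and by_id["cd3p"].half == "three_prime"
        assert by_id["cd5p"].box == "CD" and by_id["cd5p"].half == "five_prime"
        assert by_id["haca"].box == "HACA"
        assert len(remaining) == 0

    def test_no_snorna_reads_empty(self, reference_sets):
        reads = ReadSet([Read("r", random_seq(20))], "s")
        records, remaining = extract_snorfs(
            reads, MatchIndex(reference_sets["snoRNA_CD"]),
            MatchIndex(reference_sets["snoRNA_HACA"]), seed=0)
        assert records == [] and len(remaining) == 1
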
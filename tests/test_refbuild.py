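"""Reference construction: annotation parsing, extension, CCA insertion,
mature collapsing, genome masking and the snoRNA length split."""

import pytest
from Bio.Seq import Seq

from trnafrag.matcher import MatchIndex
from trnafrag.refbuild import (
    ReferenceSet,
    TRNAGene,
    build_cca_edited,
    build_extended_reference,
    build_non_trna_space,
    build_unique_mature,
    gene_sequence,
    parse_trna_annotation,
    spliced_sequence,
    split_snorna_by_length,
)

import numpy as np

RNG = np.random.default_rng(2024)


def random_seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


@pytest.fixture()
def small_genome():
    return {"chr1": random_seq(600), "chrM": random_seq(300)}


def write_gff(tmp_path, lines):
    p = tmp_path / "trna.gff3"
    p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return p


class TestAnnotationParsing:
    def test_plus_strand_gene_lengths(self, tmp_path, small_genome):
        gff = write_gff(tmp_path, ["chr1\tx\ttRNA\t101\t175\t.\t+\t.\tID=g1"])
        (gene,) = parse_trna_annotation(gff, small_genome)
        assert (gene.start, gene.end) == (100, 175)
        assert gene.mature_length_genomic == 75
        assert gene.mature_length_spliced == 75

    def test_minus_strand_sequence_is_reverse_complement(self, tmp_path, small_genome):
        gff = write_gff(tmp_path, ["chr1\tx\ttRNA\t101\t175\t.\t-\t.\tID=g1"])
        (gene,) = parse_trna_annotation(gff, small_genome)
        expected = str(Seq(small_genome["chr1"][100:175]).reverse_complement())
        assert gene_sequence(gene, small_genome) == expected

    def test_intron_splice_arithmetic(self, tmp_path, small_genome):
        # 42-nt intron inside a 117-nt genomic body -> 75-nt spliced mature
        gff = write_gff(tmp_path, [
            "chr1\tx\ttRNA\t101\t217\t.\t+\t.\tID=g1",
            "chr1\tx\tintron\t138\t179\t.\t+\t.\tParent=g1",
        ])
        (gene,) = parse_trna_annotation(gff, small_genome)
        assert gene.mature_length_genomic == 117
        assert gene.introns == [(37, 79)]
        assert gene.mature_length_spliced == 75
        spliced = spliced_sequence(gene, small_genome)
        body = small_genome["chr1"][100:217]
        assert spliced == body[:37] + body[79:]

    def test_bed6_with_intron_companion(self, tmp_path, small_genome):
        bed = tmp_path / "trna.bed"
        bed.write_text("chr1\t100\t217\tg1\t0\t+\n")
        (tmp_path / "trna.bed.introns.bed").write_text("chr1\t137\t179\tg1\n")
        (gene,) = parse_trna_annotation(bed, small_genome)
        assert gene.introns == [(37, 79)]

    def test_compartment_from_contig_allow_list(self, tmp_path, small_genome):
        gff = write_gff(tmp_path, ["chrM\tx\ttRNA\t51\t130\t.\t+\t.\tID=mt1"])
        (gene,) = parse_trna_annotation(gff, small_genome)
        assert gene.compartment == "mito"

    def test_coordinate_outside_contig_is_hard_error(self, tmp_path, small_genome):
        gff = write_gff(tmp_path, ["chr1\tx\ttRNA\t550\t700\t.\t+\t.\tID=bad"])
        with pytest.raises(ValueError, match="bad"):
            parse_trna_annotation(gff, small_genome)

    def test_missing_strand_is_hard_error(self, tmp_path, small_genome):
        gff = write_gff(tmp_path, ["chr1\tx\ttRNA\t101\t175\t.\t.\t.\tID=g1"])
        with pytest.raises(ValueError, match="strand"):
            parse_trna_annotation(gff, small_genome)


class TestExtendedReference:
    def test_intronless_75nt_gene_gives_180nt_entry(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 175, "+")
        (entry,) = build_extended_reference([gene], small_genome)
        assert len(entry) == 25 + 75 + 80 == 180
        assert entry.mature_start == 25
        assert entry.editing_point == 100
        assert not entry.clamped

    def test_zero_extensions_yield_gene_body(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 175, "+")
        (entry,) = build_extended_reference([gene], small_genome, up=0, down=0)
        assert entry.sequence == small_genome["chr1"][100:175]

    def test_trailer_clamped_at_contig_end(self, small_genome):
        end = len(small_genome["chr1"])
        gene = TRNAGene("g1", "chr1", end - 85, end - 10, "+")  # 10 nt left
        (entry,) = build_extended_reference([gene], small_genome)
        assert entry.clamped
        assert entry.trailer_len == 10
        assert len(entry) == 25 + 75 + 10

    def test_minus_strand_anchors_read_left_to_right(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 175, "-")
        (entry,) = build_extended_reference([gene], small_genome)
        expected = str(Seq(small_genome["chr1"][100 - 80 : 175 + 25]).reverse_complement())
        assert entry.sequence == expected
        assert entry.mature_start == 25
        assert entry.sequence[25:100] == gene_sequence(gene, small_genome)


class TestCCAEdited:
    def test_insertion_at_editing_point(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 175, "+")
        ne = build_extended_reference([gene], small_genome)
        (edited,) = build_cca_edited(ne)
        ep = ne.entries[0].editing_point
        assert edited.sequence[ep : ep + 3] == "CCA"
        assert len(edited) == len(ne.entries[0]) + 3

    def test_round_trip_string_surgery(self, reference_sets):
        ne, ed = reference_sets["non_edited"], reference_sets["cca_edited"]
        for entry in ed:
            ep = entry.editing_point
            restored = entry.sequence[:ep] + entry.sequence[ep + 3 :]
            assert restored == ne.get(entry.name).sequence

    def test_missing_anchor_is_hard_error(self):
        from trnafrag.refbuild import ReferenceEntry
        bare = ReferenceSet([ReferenceEntry("x", "ACGT" * 10, leader_len=0,
                                            mature_start=0, editing_point=0,
                                            trailer_len=0)], "non_edited")
        with pytest.raises(ValueError, match="anchor"):
            build_cca_edited(bare)


class TestUniqueMature:
    def test_identical_spliced_sequences_collapse(self, small_genome):
        # two copies of the same 75-mer at different loci
        seq = small_genome["chr1"]
        genome = {"chr1": seq[:300] + seq[100:175] + seq[300:]}
        genes = [TRNAGene("gB", "chr1", 100, 175, "+"),
                 TRNAGene("gA", "chr1", 300, 375, "+")]
        (entry,) = build_unique_mature(genes, genome)
        assert entry.name == "gA;gB"  # sorted members

    def test_intron_spliced_and_cca_appended(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 217, "+", introns=[(37, 79)])
        (entry,) = build_unique_mature([gene], small_genome)
        assert len(entry) == 117 - 42 + 3
        assert entry.sequence.endswith("CCA")
        assert entry.sequence[:-3] == spliced_sequence(gene, small_genome)

    def test_append_cca_false(self, small_genome):
        gene = TRNAGene("g1", "chr1", 100, 175, "+")
        (entry,) = build_unique_mature([gene], small_genome, append_cca=False)
        assert entry.sequence == small_genome["chr1"][100:175]

    def test_no_duplicate_sequences(self, toy_refs):
        refset = build_unique_mature(toy_refs.genes, toy_refs.genome)
        seqs = [e.sequence for e in refset]
        assert len(seqs) == len(set(seqs))


class TestNonTRNASpace:
    def test_reads_from_gene_intervals_never_match(self, toy_refs):
        masked, bed = build_non_trna_space(toy_refs.genome, toy_refs.genes)
        index = MatchIndex(masked)
        rng = np.random.default_rng(5)
        for g in toy_refs.genes:
            for _ in range(5):
                L = int(rng.integers(15, 30))
                start = int(rng.integers(g.start, max(g.start + 1, g.end - L)))
                read = toy_refs.genome[g.chrom][start : start + L]
                assert index.enumerate_matches(read) == []

    def test_reads_from_outside_match_at_source(self, toy_refs):
        masked, _ = build_non_trna_space(toy_refs.genome, toy_refs.genes)
        index = MatchIndex(masked)
        read = toy_refs.genome["chr_toy"][10:30]  # inside the leading spacer
        assert ("chr_toy", 10) in index.enumerate_matches(read)

    def test_empty_gene_list_is_identity(self, small_genome):
        masked, bed = build_non_trna_space(small_genome, [])
        assert {e.name: e.sequence for e in masked} == small_genome
        assert bed == []


class TestSnoRNASplit:
    @pytest.mark.parametrize("length,box", [(120, "CD"), (121, "HACA"), (80, "CD")])
    def test_threshold(self, length, box):
        cd, haca = split_snorna_by_length([("s", "A" * length)])
        target = cd if box == "CD" else haca
        other = haca if box == "CD" else cd
        assert len(target) == 1 and len(other) == 0

    def test_partition_of_input(self, toy_refs):
        cd, haca = split_snorna_by_length(toy_refs.snorna)
        names = {e.name for e in cd} | {e.name for e in haca}
        assert names == {n for n, _ in toy_refs.snorna}
        assert all(len(e) <= 120 for e in cd)
        assert all(len(e) > 120 for e in haca)

    def test_empty_input(self):
        cd, haca = split_snorna_by_length([])
        assert len(cd) == 0 and len(haca) == 0


def test_nonclamped_length_invariant(reference_sets, toy_refs):
    """Every non-clamped entry obeys 25 + genomic body + 80, edited +3."""
    bodies = {g.gene_id: g.mature_length_genomic for g in toy_refs.genes}
    for entry in reference_sets["non_edited"]:
        if not entry.clamped:
            assert len(entry) == 25 + bodies[entry.name] + 80
    for entry in reference_sets["cca_edited"]:
        ne = reference_sets["non_edited"].get(entry.name)
        assert len(entry) == len(ne) + 3
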
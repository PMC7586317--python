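"""Staged tRF extraction and classification.

The workflow mirrors the biogenesis of tRNA fragments. Reads are first
depleted of rRNA, then snoRNA-derived fragments are captured. The remainder
is aligned to the non-edited (genomic) extended tRNA reference: hits are the
non-CCA fragment classes (5'-tRFs, i-tRFs, tRF-1, taRFs, leader fragments,
spanners). Reads that still fail to align but end in CCA are then aligned to
the CCA-edited reference, recovering 3'-tRFs whose terminal CCA is not
genome-templated. Spanners — fragments produced before CCA addition that
cross the editing point — are isolated as the non-CCA hits with no placement
on the edited reference.

Classification is positional, relative to two anchors of the extended
reference: ``mature_start`` (RNase P cleavage, end of the 5' leader) and
``editing_point`` (RNase Z cleavage, CCA insertion point). A tolerance
window ``w`` (default 2 nt) absorbs ragged fragment ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .io_preprocess import Read, ReadSet
from .matcher import Alignment, MatchIndex, align_reads
from .refbuild import ReferenceSet

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 2


class TRFClass(str, Enum):
    FIVE_PRIME = "FIVE_PRIME"
    THREE_PRIME_CCA = "THREE_PRIME_CCA"
    I_TRF = "I_TRF"
    TRF1 = "TRF1"
    SPANNER = "SPANNER"
    TARF = "TARF"
    LEADER = "LEADER"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class TRFRecord:
    read_id: str
    sequence: str
    ref_name: str
    start: int
    end: int
    reference_kind: str  # non_edited | cca_edited
    trf_class: TRFClass
    compartment: str


@dataclass
class SnoRFRecord:
    read_id: str
    sequence: str
    ref_name: str
    start: int
    end: int
    box: str   # CD | HACA
    half: str  # five_prime | three_prime


@dataclass
class TRFCollection:
    sample_id: str
    records: list[TRFRecord] = field(default_factory=list)
    snorf_records: list[SnoRFRecord] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def by_class(self) -> dict[TRFClass, list[TRFRecord]]:
        out: dict[TRFClass, list[TRFRecord]] = {c: [] for c in TRFClass}
        for rec in self.records:
            out[rec.trf_class].append(rec)
        return out


def select_cca_reads(reads: ReadSet) -> tuple[ReadSet, ReadSet]:
    """Partition reads by whether their last 3 nt are exactly CCA."""
    cca, non_cca = [], []
    for r in reads:
        (cca if r.sequence.endswith("CCA") else non_cca).append(r)
    return (ReadSet(cca, reads.sample_id, provenance=list(reads.provenance)),
            ReadSet(non_cca, reads.sample_id, provenance=list(reads.provenance)))


def classify_trf(alignment: Alignment, anchors, w: int = DEFAULT_TOLERANCE,
                 sequence: str = "") -> TRFClass:
    """Positional class of one placement given its reference entry's anchors.

    On non-edited coordinates, in evaluation order: LEADER (fragment confined
    to the 5' leader), FIVE_PRIME (starts at the mature 5' end), TRF1 (starts
    at the RNase Z junction, i.e. the released 3' trailer), TARF (starts
    further downstream — improper Pol-III termination), I_TRF (strictly
    internal to the mature body). On CCA-edited coordinates: THREE_PRIME_CCA
    when the fragment ends at the editing point + 3 and carries the CCA.
    SPANNER is assigned only by :func:`extract_spanners`. Anything else is
    UNCLASSIFIED.
    """
    if w < 0:
        raise ValueError("tolerance must be non-negative")
    ms, ep = anchors.mature_start, anchors.editing_point
    start, end = alignment.start, alignment.end
    if anchors.edited:
        if abs(end - (ep + 3)) <= w and sequence.endswith("CCA"):
            return TRFClass.THREE_PRIME_CCA
        return TRFClass.UNCLASSIFIED
    if end <= ms + w and start < ms:
        return TRFClass.LEADER
    if abs(start - ms) <= w:
        return TRFClass.FIVE_PRIME
    if abs(start - ep) <= w:
        return TRFClass.TRF1
    if start > ep + w:
        return TRFClass.TARF
    if start > ms + w and end < ep - w:
        return TRFClass.I_TRF
    return TRFClass.UNCLASSIFIED


def extract_spanners(
    noncca_alignments: list[Alignment],
    reads_by_id: dict[str, Read],
    cca_edited_index: MatchIndex,
    non_edited_index: MatchIndex,
) -> list[TRFRecord]:
    """Spanner tRFs: non-CCA placements whose read has no placement on the
    CCA-edited reference. A fragment crossing the editing point cannot match
    the edited sequence (the inserted CCA breaks the exact match), so these
    reads are re-placed on the non-edited reference and labelled SPANNER."""
    out = []
    anchors = non_edited_index.refset.anchors
    for aln in noncca_alignments:
        read = reads_by_id[aln.read_id]
        if cca_edited_index.enumerate_matches(read):
            continue
        a = anchors[aln.ref_name]
        out.append(TRFRecord(
            read_id=aln.read_id, sequence=read.sequence, ref_name=aln.ref_name,
            start=aln.start, end=aln.end, reference_kind="non_edited",
            trf_class=TRFClass.SPANNER, compartment=a.compartment,
        ))
    return out


def extract_snorfs(
    reads: ReadSet,
    cd_index: MatchIndex | None,
    haca_index: MatchIndex | None,
    seed: int = 0,
) -> tuple[list[SnoRFRecord], ReadSet]:
    """Place reads on the snoRNA sets (box C/D first, then H/ACA) and label
    each hit with its box and snoRNA half (5' vs 3', by fragment start)."""
    records: list[SnoRFRecord] = []
    remaining = reads
    for box, index in (("CD", cd_index), ("HACA", haca_index)):
        if index is None:
            continue
        alns, remaining = align_reads(remaining, index, mode="random",
                                      seed=seed + (1 if box == "HACA" else 0))
        seqs = {r.name: r.sequence for r in index.refset}
        by_id = {r.read_id: r for r in reads}
        for a in alns:
            half = "five_prime" if a.start < len(seqs[a.ref_name]) / 2 else "three_prime"
            records.append(SnoRFRecord(a.read_id, by_id[a.read_id].sequence,
                                       a.ref_name, a.start, a.end, box, half))
    return records, remaining


def run_trf_workflow(
    reads: ReadSet,
    rrna: ReferenceSet | MatchIndex | None,
    snorna_cd: ReferenceSet | MatchIndex | None,
    snorna_haca: ReferenceSet | MatchIndex | None,
    non_edited: ReferenceSet | MatchIndex,
    cca_edited: ReferenceSet | MatchIndex,
    seed: int = 0,
    w: int = DEFAULT_TOLERANCE,
) -> TRFCollection:
    """Run the full staged extraction and classify every placed fragment.

    Stages: (1) rRNA depletion; (2) snoRF capture; (3) alignment to the
    non-edited reference (non-CCA tRFs); (4) CCA-suffix selection among the
    remainder; (5) alignment of those to the CCA-edited reference (3'-tRFs);
    (6) merge into ALL-tRFs; (7) spanner isolation among stage-3 hits.
    Stage counts are conserved at every split.
    """
    def as_index(rs):
        if rs is None or isinstance(rs, MatchIndex):
            return rs
        return MatchIndex(rs)

    rrna_ix = as_index(rrna)
    cd_ix = as_index(snorna_cd)
    haca_ix = as_index(snorna_haca)
    ne_ix = as_index(non_edited)
    ed_ix = as_index(cca_edited)

    ne_names = set(ne_ix.refset.anchors)
    ed_names = set(ed_ix.refset.anchors)
    if ne_names != ed_names:
        raise ValueError("non-edited and CCA-edited sets cover different genes")

    counts: dict[str, int] = {"input": len(reads)}

    # (1) rRNA depletion
    if rrna_ix is not None:
        rrna_hits, reads = align_reads(reads, rrna_ix, mode="first")
        counts["rRNA"] = len(rrna_hits)
    else:
        counts["rRNA"] = 0
    counts["post_rRNA"] = len(reads)

    # (2) snoRNA-derived fragments
    snorfs, reads = extract_snorfs(reads, cd_ix, haca_ix, seed=seed)
    counts["snoRF"] = len(snorfs)

    # (3) non-CCA tRFs on the non-edited reference
    noncca_alns, unaligned = align_reads(reads, ne_ix, mode="random", seed=seed)
    counts["non_CCA_tRF"] = len(noncca_alns)
    by_id = {r.read_id: r for r in reads}

    # (4) CCA-suffix selection among still-unaligned reads
    cca_reads, non_cca_rest = select_cca_reads(unaligned)
    counts["cca_selected"] = len(cca_reads)

    # (5) 3'-tRFs on the CCA-edited reference
    cca_alns, cca_unmatched = align_reads(cca_reads, ed_ix, mode="random",
                                          seed=seed + 1)
    counts["CCA_tRF"] = len(cca_alns)
    counts["unmatched"] = len(non_cca_rest) + len(cca_unmatched)

    # (7) spanners among the stage-3 placements
    spanners = extract_spanners(noncca_alns, by_id, ed_ix, ne_ix)
    spanner_ids = {rec.read_id for rec in spanners}
    counts["spanner"] = len(spanners)

    ne_anchors = ne_ix.refset.anchors
    ed_anchors = ed_ix.refset.anchors
    records: list[TRFRecord] = list(spanners)
    for a in noncca_alns:
        if a.read_id in spanner_ids:
            continue
        anc = ne_anchors[a.ref_name]
        records.append(TRFRecord(
            a.read_id, by_id[a.read_id].sequence, a.ref_name, a.start, a.end,
            "non_edited", classify_trf(a, anc, w, by_id[a.read_id].sequence),
            anc.compartment,
        ))
    cca_by_id = {r.read_id: r for r in cca_reads}
    for a in cca_alns:
        anc = ed_anchors[a.ref_name]
        records.append(TRFRecord(
            a.read_id, cca_by_id[a.read_id].sequence, a.ref_name, a.start,
            a.end, "cca_edited",
            classify_trf(a, anc, w, cca_by_id[a.read_id].sequence),
            anc.compartment,
        ))

    seen = set()
    for rec in records:  # merged ALL-tRFs must not duplicate a read
        if rec.read_id in seen:
            raise RuntimeError(f"read {rec.read_id} placed twice in ALL-tRFs")
        seen.add(rec.read_id)

    return TRFCollection(reads.sample_id if hasattr(reads, "sample_id")
                         else "sample", records, snorfs, counts)


# ---------------------------------------------------------------------------
# persistence


def write_trf_table(collection: TRFCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsequence\tref_name\tstart\tend\tclass\t"
                 "compartment\treference_kind\n")
        for r in collection.records:
            fh.write(f"{r.read_id}\t{r.sequence}\t{r.ref_name}\t{r.start}\t"
                     f"{r.end}\t{r.trf_class.value}\t{r.compartment}\t"
                     f"{r.reference_kind}\n")


def write_class_fastas(collection: TRFCollection, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cls, recs in collection.by_class().items():
        if not recs:
            continue
        p = outdir / f"trf_{cls.value.lower()}.fa"
        with open(p, "w") as fh:
            for r in recs:
                fh.write(f">{r.read_id}\n{r.sequence}\n")
        written.append(p)
    return written


def write_stage_counts(collection: TRFCollection, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection.stage_counts, indent=2) + "\n")
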
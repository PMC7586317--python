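"""Synthetic genomes, reference sets and labelled read libraries.

The generator emulates the structural features the pipeline depends on — a
multi-contig genome with nuclear and mitochondrial tRNA genes (a fraction
carrying 40-44 nt introns), auxiliary ncRNA sets, snoRNAs straddling the
120 nt box C/D vs H/ACA threshold, and reads of every tRF class sampled at
their defining coordinates with a 3' sequencing adapter appended.

To make class truth unambiguous (so that 100% recall is a property, not a
statistic), every generated sequence unit is rejection-sampled until all of
its 15-mers — on both strands — are globally unique across the fixture.
Every simulated read is additionally verified to place exactly at its
intended site and nowhere else, and resampled otherwise.

The generator does not model sequencing error, reverse-transcription stops at
modified nucleotides, or ligation bias; fixtures are noise-free by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_preprocess import Read, ReadSet
from .matcher import MatchIndex
from .refbuild import (
    ReferenceSet,
    TRNAGene,
    build_cca_edited,
    build_extended_reference,
    plain_reference_set,
    split_snorna_by_length,
)
from .trf_extract import TRFClass

logger = logging.getLogger(__name__)

KMER = 15
MAX_UNIT_TRIES = 200
MAX_READ_TRIES = 50

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: classes the simulator can sample, plus snoRNA-derived fragments
SIMULATABLE = [c.value for c in TRFClass if c is not TRFClass.UNCLASSIFIED] + ["SNORF"]


def _default_class_mix() -> dict[str, int]:
    return {
        TRFClass.FIVE_PRIME.value: 100,
        TRFClass.THREE_PRIME_CCA.value: 100,
        TRFClass.I_TRF.value: 100,
        TRFClass.TRF1.value: 100,
        TRFClass.SPANNER.value: 100,
        TRFClass.TARF.value: 100,
        TRFClass.LEADER.value: 100,
        "SNORF": 100,
    }


@dataclass
class FixtureSpec:
    seed: int
    n_nuclear_trnas: int = 10
    n_mito_trnas: int = 2
    intron_fraction: float = 0.2
    intron_length: tuple[int, int] = (40, 44)
    n_snornas: int = 6
    class_mix: dict[str, int] = field(default_factory=_default_class_mix)
    adapter: str = DEFAULT_ADAPTER
    error_free: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class counts must be non-negative")
        if not self.error_free:
            raise NotImplementedError("sequencing-error models are not implemented")
        unknown = set(self.class_mix) - set(SIMULATABLE)
        if unknown:
            raise ValueError(f"cannot simulate classes {sorted(unknown)}")


@dataclass
class FixtureRefs:
    genome: dict[str, str]
    genes: list[TRNAGene]
    snorna: list[tuple[str, str]]
    rrna: list[tuple[str, str]]
    mirna: list[tuple[str, str]]
    te: list[tuple[str, str]]
    ncrna: list[tuple[str, str]]
    genic: list[tuple[str, str]]
    intergenic: list[tuple[str, str]]

    def reference_sets(self) -> dict[str, ReferenceSet]:
        non_edited = build_extended_reference(self.genes, self.genome)
        cd, haca = split_snorna_by_length(self.snorna)
        return {
            "non_edited": non_edited,
            "cca_edited": build_cca_edited(non_edited),
            "snoRNA_CD": cd,
            "snoRNA_HACA": haca,
            "rRNA": plain_reference_set(self.rrna, "rRNA"),
            "miRNA": plain_reference_set(self.mirna, "miRNA"),
            "TE": plain_reference_set(self.te, "TE"),
            "ncRNA": plain_reference_set(self.ncrna, "ncRNA"),
            "genic": plain_reference_set(self.genic, "genic"),
            "intergenic": plain_reference_set(self.intergenic, "intergenic"),
        }


def _kmers(seq: str, k: int = KMER) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _unique_seq(rng: np.random.Generator, length: int, seen: set[str]) -> str:
    """Random sequence whose 15-mers (both strands) are new and internally
    unique; rejection-sampled with bounded retries."""
    bases = np.array(list("ACGT"))
    for _ in range(MAX_UNIT_TRIES):
        seq = "".join(rng.choice(bases, size=length))
        fwd = _kmers(seq)
        rev = _kmers(str(Seq(seq).reverse_complement()))
        n_expected = 2 * max(0, length - KMER + 1)
        both = fwd | rev
        if len(fwd) + len(rev) == n_expected and len(both) == n_expected \
                and not (both & seen):
            seen |= both
            return seq
    raise ValueError(
        "could not satisfy the non-substring constraint; "
        "use longer or fewer sequences"
    )


def _junction_clean(body: str, trailer: str,
                    min_len: int = 15, max_len: int = 29) -> bool:
    """True when no junction-crossing window survives CCA insertion.

    A fragment spanning the editing point must fail to match the edited
    sequence, but the insertion is locally invisible when the flanks mimic it
    (e.g. a trailer starting with C). Enumerate every window of 15-29 nt that
    crosses the body/trailer junction and require that none occurs in the
    edited local string body + CCA + trailer.
    """
    edited = body + "CCA" + trailer
    for L in range(min_len, max_len + 1):
        for a in range(max(1, L - len(trailer)), min(L, len(body) + 1)):
            window = body[len(body) - a :] + trailer[: L - a]
            if window in edited:
                return False
    return True


def make_toy_references(spec: FixtureSpec) -> FixtureRefs:
    """Build a deterministic toy genome + annotation + auxiliary sets.

    tRNA bodies are 70-90 nt with the anticodon recorded at mature positions
    34-36; the requested fraction of nuclear genes (deterministic rounding,
    assigned to the first genes) carries an intron of 40-44 nt opening at
    mature position 37, the canonical intron site. Mitochondrial genes sit on
    a ``chrM`` contig. Strands alternate so minus-strand handling is always
    exercised.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()

    n_intronic = int(round(spec.n_nuclear_trnas * spec.intron_fraction))
    genes: list[TRNAGene] = []
    genome: dict[str, str] = {}

    def build_contig(chrom: str, n_genes: int, intronic: int, compartment: str):
        margin, gap = 120, 150

        def spacer_seq(length: int, trial: set[str]) -> str:
            # spacer edges feed gene trailers on either strand; a leading C
            # (or trailing G, its minus-strand image) would mimic the CCA
            # insertion and make junction-spanning reads ambiguous
            for _ in range(MAX_UNIT_TRIES):
                inner = set(trial)
                s = _unique_seq(rng, length, inner)
                if s[0] != "C" and s[-1] != "G":
                    trial.clear()
                    trial.update(inner)
                    return s
            raise ValueError("could not satisfy the non-substring constraint; "
                             "use longer or fewer sequences")

        parts, pos = [], 0
        parts.append(spacer_seq(margin, seen))
        pos += margin
        for i in range(n_genes):
            mature = int(rng.integers(70, 91))
            ilen = int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1)) \
                if i < intronic else 0
            glen = mature + ilen
            strand = "+" if i % 2 == 0 else "-"
            # resample until the CCA editing junction is unambiguous: no
            # junction-crossing read may also match the edited reference
            upstream = "".join(parts)[-80:]
            for _ in range(MAX_UNIT_TRIES):
                trial = set(seen)
                body = _unique_seq(rng, glen, trial)
                next_spacer = spacer_seq(gap, trial)
                if strand == "+":
                    sense_body, sense_trailer = body, next_spacer[:80]
                else:
                    sense_body = str(Seq(body).reverse_complement())
                    sense_trailer = str(Seq(upstream).reverse_complement())
                if _junction_clean(sense_body, sense_trailer):
                    seen.clear()
                    seen.update(trial)
                    break
            else:
                raise ValueError("could not generate an unambiguous editing "
                                 "junction; use longer sequences")
            introns = []
            if ilen:
                iv = (37, 37 + ilen)
                if strand == "-":
                    iv = (glen - iv[1], glen - iv[0])
                introns = [iv]
            anticodon = sense_body[34:37]
            prefix = "mt:" if compartment == "mito" else ""
            genes.append(TRNAGene(
                gene_id=f"{prefix}tRNA-{anticodon}-{len(genes) + 1}",
                chrom=chrom, start=pos, end=pos + glen, strand=strand,
                anticodon=anticodon, compartment=compartment, introns=introns,
            ))
            parts.append(body)
            pos += glen
            parts.append(next_spacer)
            pos += gap
        genome[chrom] = "".join(parts)

    build_contig("chr_toy", spec.n_nuclear_trnas, n_intronic, "nuclear")
    if spec.n_mito_trnas:
        build_contig("chrM", spec.n_mito_trnas, 0, "mito")

    def aux(prefix: str, lengths: Sequence[int]) -> list[tuple[str, str]]:
        return [(f"{prefix}{i + 1}", _unique_seq(rng, L, seen))
                for i, L in enumerate(lengths)]

    n_cd = (spec.n_snornas + 1) // 2
    sno_lengths = [int(rng.integers(80, 121)) for _ in range(n_cd)] + \
                  [int(rng.integers(121, 161)) for _ in range(spec.n_snornas - n_cd)]
    return FixtureRefs(
        genome=genome,
        genes=genes,
        snorna=aux("snoRNA-", sno_lengths),
        rrna=aux("rRNA-", [150, 200]),
        mirna=aux("miR-", [22, 22, 21, 22, 23]),
        te=aux("TE-", [300, 250]),
        ncrna=aux("ncRNA-", [200, 180]),
        genic=aux("gene-", [300, 300]),
        intergenic=aux("intergenic-", [300, 300]),
    )


def _sample_read(rng: np.random.Generator, cls: str, entry_ne, entry_ed,
                 sno: tuple[str, str] | None) -> tuple[str, str, int, int, str]:
    """One candidate read: (ref_name, sequence, start, end, reference_kind)."""
    if cls == "SNORF":
        name, seq = sno
        L = int(rng.integers(15, min(30, len(seq) + 1)))
        start = int(rng.integers(0, len(seq) - L + 1))
        return name, seq[start : start + L], start, start + L, "snoRNA"
    ms, ep = entry_ne.mature_start, entry_ne.editing_point
    seq_ne, seq_ed = entry_ne.sequence, entry_ed.sequence
    if cls == TRFClass.LEADER.value:
        L = int(rng.integers(15, min(26, ms + 1)))
        start = ms - L
        return entry_ne.name, seq_ne[start:ms], start, ms, "non_edited"
    if cls == TRFClass.FIVE_PRIME.value:
        L = int(rng.integers(15, 30))
        return entry_ne.name, seq_ne[ms : ms + L], ms, ms + L, "non_edited"
    if cls == TRFClass.I_TRF.value:
        L = int(rng.integers(15, min(30, ep - ms - 6 + 1)))
        start = int(rng.integers(ms + 3, ep - 3 - L + 1))
        return entry_ne.name, seq_ne[start : start + L], start, start + L, "non_edited"
    if cls == TRFClass.TRF1.value:
        L = int(rng.integers(15, min(30, len(seq_ne) - ep + 1)))
        return entry_ne.name, seq_ne[ep : ep + L], ep, ep + L, "non_edited"
    if cls == TRFClass.TARF.value:
        L = int(rng.integers(15, min(30, len(seq_ne) - ep - 3 + 1)))
        start = int(rng.integers(ep + 3, len(seq_ne) - L + 1))
        return entry_ne.name, seq_ne[start : start + L], start, start + L, "non_edited"
    if cls == TRFClass.SPANNER.value:
        L = int(rng.integers(15, 30))
        overhang = int(rng.integers(2, L - 1))  # nt past the editing point
        start = ep - (L - overhang)
        return entry_ne.name, seq_ne[start : start + L], start, start + L, "non_edited"
    if cls == TRFClass.THREE_PRIME_CCA.value:
        L = int(rng.integers(15, 30))
        start = ep + 3 - L
        return entry_ed.name, seq_ed[start : ep + 3], start, ep + 3, "cca_edited"
    raise ValueError(f"cannot simulate class {cls!r}")


def simulate_trf_reads(
    spec: FixtureSpec, refs: FixtureRefs
) -> tuple[ReadSet, pd.DataFrame]:
    """Sample the requested class mix, append the adapter, and return the
    reads plus a truth table (read_id, class, ref_name, start, end,
    reference_kind).

    Each read is verified against the built indexes — it must place exactly
    at its intended site and hit no other reference set — and is resampled on
    any collision so downstream recall is exact by construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sets = refs.reference_sets()
    ne, ed = sets["non_edited"], sets["cca_edited"]
    ne_ix, ed_ix = MatchIndex(ne), MatchIndex(ed)
    sno_ix = {
        "CD": MatchIndex(sets["snoRNA_CD"]) if len(sets["snoRNA_CD"]) else None,
        "HACA": MatchIndex(sets["snoRNA_HACA"]) if len(sets["snoRNA_HACA"]) else None,
    }
    other_ix = [MatchIndex(sets[k]) for k in
                ("rRNA", "miRNA", "TE", "ncRNA", "genic", "intergenic")
                if len(sets[k])]

    def clean_elsewhere(seq: str) -> bool:
        return not any(ix.enumerate_matches(seq) for ix in other_ix)

    def verify(cls: str, ref: str, seq: str, start: int) -> bool:
        if not clean_elsewhere(seq):
            return False
        ne_hits = ne_ix.enumerate_matches(seq)
        ed_hits = ed_ix.enumerate_matches(seq)
        sno_hits = [h for ix in sno_ix.values() if ix
                    for h in ix.enumerate_matches(seq)]
        if cls == "SNORF":
            own = [ix for ix in sno_ix.values()
                   if ix and ref in ix.refset.anchors][0]
            return (own.enumerate_matches(seq) == [(ref, start)]
                    and not ne_hits and not ed_hits
                    and len(sno_hits) == 1)
        if sno_hits:
            return False
        if cls == TRFClass.THREE_PRIME_CCA.value:
            return ed_hits == [(ref, start)] and not ne_hits
        if cls == TRFClass.SPANNER.value:
            return ne_hits == [(ref, start)] and not ed_hits
        return ne_hits == [(ref, start)]

    reads, truth_rows = [], []
    anchors_ne, anchors_ed = ne.anchors, ed.anchors
    gene_names = [g.gene_id for g in refs.genes]
    counter = 0
    for cls, n in sorted(spec.class_mix.items()):
        for i in range(n):
            for attempt in range(MAX_READ_TRIES):
                if cls == "SNORF":
                    sno = refs.snorna[int(rng.integers(len(refs.snorna)))]
                    gene_ne = gene_ed = None
                else:
                    gname = gene_names[int(rng.integers(len(gene_names)))]
                    gene_ne, gene_ed = anchors_ne[gname], anchors_ed[gname]
                    sno = None
                ref, seq, start, end, kind = _sample_read(rng, cls, gene_ne,
                                                          gene_ed, sno)
                if len(seq) == end - start and verify(cls, ref, seq, start):
                    break
            else:
                raise ValueError(f"class {cls}: geometrically impossible or "
                                 "ambiguous after bounded retries")
            counter += 1
            rid = f"sim{counter:05d}_{cls}"
            reads.append(Read(rid, seq + spec.adapter, "fixture"))
            truth_rows.append((rid, cls, ref, start, end, kind))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "class", "ref_name", "start", "end", "reference_kind"],
    ).set_index("read_id")
    return ReadSet(reads, "fixture"), truth


def truth_evaluate(predicted, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (truth class x predicted class plus ``missed``) and
    per-class recall/precision for a TRFCollection against the truth table."""
    pred_class: dict[str, str] = {}
    for rec in predicted.records:
        pred_class[rec.read_id] = rec.trf_class.value
    for rec in predicted.snorf_records:
        pred_class[rec.read_id] = "SNORF"
    unknown = set(pred_class) - set(truth.index)
    if unknown:
        raise ValueError(f"predictions for unknown read ids: {sorted(unknown)[:5]}")

    truth_classes = sorted(truth["class"].unique())
    pred_classes = sorted(set(pred_class.values()) | set(truth_classes)) + ["missed"]
    conf = pd.DataFrame(0, index=truth_classes, columns=pred_classes)
    for rid, row in truth.iterrows():
        conf.loc[row["class"], pred_class.get(rid, "missed")] += 1

    stats = []
    for cls in truth_classes:
        tp = conf.loc[cls, cls] if cls in conf.columns else 0
        truth_n = conf.loc[cls].sum()
        pred_n = conf[cls].sum() if cls in conf.columns else 0
        stats.append((cls, tp / truth_n if truth_n else np.nan,
                      tp / pred_n if pred_n else np.nan))
    metrics = pd.DataFrame(stats, columns=["class", "recall", "precision"]
                           ).set_index("class")
    return conf, metrics


# ---------------------------------------------------------------------------
# persistence


def write_fixture(refs: FixtureRefs, reads: ReadSet, truth: pd.DataFrame,
                  outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, GFF3 annotation, auxiliary FASTAs, reads FASTQ and
    the truth TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "genome.fa"
    with open(p, "w") as fh:
        for name, seq in refs.genome.items():
            fh.write(f">{name}\n{seq}\n")
    paths["genome"] = p

    p = outdir / "trna.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in refs.genes:
            fh.write(f"{g.chrom}\ttoy\ttRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};anticodon={g.anticodon};"
                     f"compartment={g.compartment}\n")
            for s, e in g.introns:
                gs, ge = (g.start + s, g.start + e) if g.strand == "+" else \
                         (g.end - e, g.end - s)
                fh.write(f"{g.chrom}\ttoy\tintron\t{gs + 1}\t{ge}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")
    paths["annotation"] = p

    for label in ("snorna", "rrna", "mirna", "te", "ncrna", "genic", "intergenic"):
        p = outdir / f"{label}.fa"
        with open(p, "w") as fh:
            for name, seq in getattr(refs, label):
                fh.write(f">{name}\n{seq}\n")
        paths[label] = p

    p = outdir / "reads.fastq"
    with open(p, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    paths["reads"] = p

    p = outdir / "truth.tsv"
    truth.to_csv(p, sep="\t")
    paths["truth"] = p
    return paths
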
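"""Reference-set construction for tRF analysis.

The pipeline aligns short reads against several purpose-built reference sets
derived from a genome and its tRNA gene annotation:

* ``non_edited`` — each tRNA gene extended by a genomic 5' leader (default
  25 nt) and 3' trailer (default 80 nt), intron retained. The junction
  between the gene body and the trailer is the RNase Z cleavage point, which
  coincides with the point where the non-templated CCA tag is added.
* ``cca_edited`` — the non-edited set with ``CCA`` inserted at that junction,
  so that CCA-tagged 3' fragments can be matched exactly.
* ``unique_mature`` — spliced mature sequences, deduplicated, optionally with
  a terminal CCA; avoids multimapping across identical tRNA gene copies.
* ``non_trna_space`` — the genome with every tRNA gene interval hard-masked
  to N, used to probe non-tRNA origins of short reads.
* snoRNA sets split at 120 nt into box C/D (<=120) and box H/ACA (>120).

All coordinates are 0-based half-open internally. BED input is read as
0-based, GFF3 as 1-based inclusive and converted. Minus-strand genes are
stored sense-strand so anchor offsets always read left-to-right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: contig names treated as mitochondrial unless overridden
DEFAULT_MITO_CONTIGS = frozenset({"mitochondrion_genome", "chrM", "MT"})

DEFAULT_LEADER = 25
DEFAULT_TRAILER = 80
SNORNA_CD_MAX_LEN = 120


@dataclass
class TRNAGene:
    """One annotated tRNA gene, always expressed on its sense strand.

    ``introns`` are gene-relative 0-based half-open intervals measured from
    the sense-strand gene start (i.e. already strand-flipped for minus-strand
    genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    isotype: str = ""
    anticodon: str = ""
    compartment: str = "nuclear"
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) <= start ({self.start})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: missing or invalid strand {self.strand!r}")
        if self.anticodon and len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be a 3-mer")
        glen = self.mature_length_genomic
        for s, e in self.introns:
            if not (0 <= s < e <= glen):
                raise ValueError(
                    f"{self.gene_id}: intron [{s},{e}) outside gene body of {glen} nt"
                )

    @property
    def mature_length_genomic(self) -> int:
        return self.end - self.start

    @property
    def mature_length_spliced(self) -> int:
        return self.mature_length_genomic - sum(e - s for s, e in self.introns)


@dataclass
class ReferenceEntry:
    """One reference sequence with the anchor coordinates classification uses.

    ``mature_start`` is the index of the first mature-body nucleotide (equals
    the actual, possibly clamped, leader length). ``editing_point`` is the
    junction after the last genomic body nucleotide — the RNase Z cleavage
    point and the CCA insertion point on the edited counterpart.
    """

    name: str
    sequence: str
    leader_len: int = DEFAULT_LEADER
    mature_start: int = DEFAULT_LEADER
    editing_point: int = 0
    trailer_len: int = DEFAULT_TRAILER
    edited: bool = False
    compartment: str = "nuclear"
    clamped: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.edited and self.sequence[self.editing_point : self.editing_point + 3] != "CCA":
            raise ValueError(f"{self.name}: edited entry lacks CCA at editing point")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    entries: list[ReferenceEntry]
    kind: str

    KINDS = {
        "non_edited", "cca_edited", "unique_mature", "rRNA", "snoRNA_CD",
        "snoRNA_HACA", "miRNA", "TE", "ncRNA", "genic", "intergenic",
        "non_trna_space",
    }

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown reference-set kind {self.kind!r}")
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate entry names in {self.kind} set")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> ReferenceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def anchors(self) -> dict[str, ReferenceEntry]:
        return {e.name: e for e in self.entries}


# ---------------------------------------------------------------------------
# genome / annotation ingestion


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a (small) multi-contig FASTA into an uppercase string dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _flip_intron(iv: tuple[int, int], gene_len: int) -> tuple[int, int]:
    s, e = iv
    return gene_len - e, gene_len - s


def parse_trna_annotation(
    annotation_file: str | Path,
    genome: dict[str, str] | str | Path,
    mito_contigs: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> list[TRNAGene]:
    """Parse a BED6 (+ companion intron BED) or GFF3 tRNA annotation.

    GFF3 files may carry ``tRNA`` features with child ``intron`` sub-features
    (via Parent=). BED6 intron companions are files named ``<bed>.introns.bed``
    whose name column matches the gene name. Compartment is inferred from the
    contig allow-list, or from a ``compartment=`` GFF attribute if present.

    Raises ValueError for coordinates outside their contig or a missing strand.
    """
    if not isinstance(genome, dict):
        genome = load_genome(genome)
    mito = set(mito_contigs)
    path = Path(annotation_file)
    if path.suffix.lower() in {".gff", ".gff3"}:
        genes = _parse_gff3(path, mito)
    else:
        genes = _parse_bed6(path, mito)
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"{g.gene_id}: contig {g.chrom!r} not in genome")
        if g.end > len(genome[g.chrom]):
            raise ValueError(
                f"{g.gene_id}: interval [{g.start},{g.end}) outside contig "
                f"{g.chrom} of length {len(genome[g.chrom])}"
            )
    return genes


def _parse_bed6(path: Path, mito: set[str]) -> list[TRNAGene]:
    genes: list[TRNAGene] = []
    by_name: dict[str, TRNAGene] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6 or f[5] not in {"+", "-"}:
                raise ValueError(f"{path}:{ln}: BED6 record lacks a strand")
            g = TRNAGene(
                gene_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5],
                compartment="mito" if f[0] in mito else "nuclear",
            )
            genes.append(g)
            by_name[g.gene_id] = g
    intron_bed = path.with_suffix(path.suffix + ".introns.bed")
    if intron_bed.exists():
        with open(intron_bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                g = by_name.get(f[3])
                if g is None:
                    raise ValueError(f"intron record for unknown gene {f[3]!r}")
                s, e = int(f[1]) - g.start, int(f[2]) - g.start
                if g.strand == "-":
                    s, e = _flip_intron((s, e), g.mature_length_genomic)
                g.introns.append((s, e))
        for g in genes:
            g.__post_init__()  # re-validate with introns attached
    return genes


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _parse_gff3(path: Path, mito: set[str]) -> list[TRNAGene]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{ln}: not a 9-column GFF3 record")
            rows.append((ln, f))

    genes: dict[str, TRNAGene] = {}
    for ln, f in rows:
        if f[2].lower() not in {"trna", "trna_gene", "gene"}:
            continue
        if f[6] not in {"+", "-"}:
            raise ValueError(f"{path}:{ln}: missing strand")
        attrs = _gff_attrs(f[8])
        gid = attrs.get("ID") or attrs.get("Name")
        if not gid:
            raise ValueError(f"{path}:{ln}: tRNA feature without ID")
        compartment = attrs.get("compartment") or ("mito" if f[0] in mito else "nuclear")
        genes[gid] = TRNAGene(
            gene_id=gid, chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
            strand=f[6], isotype=attrs.get("isotype", ""),
            anticodon=attrs.get("anticodon", ""), compartment=compartment,
        )
    for ln, f in rows:
        if f[2].lower() != "intron":
            continue
        parent = _gff_attrs(f[8]).get("Parent", "")
        g = genes.get(parent)
        if g is None:
            raise ValueError(f"{path}:{ln}: intron with unknown Parent {parent!r}")
        s, e = int(f[3]) - 1 - g.start, int(f[4]) - g.start
        if g.strand == "-":
            s, e = _flip_intron((s, e), g.mature_length_genomic)
        g.introns.append((s, e))
    out = list(genes.values())
    for g in out:
        g.introns.sort()
        g.__post_init__()
    return out


# ---------------------------------------------------------------------------
# sequence extraction helpers


def gene_sequence(gene: TRNAGene, genome: dict[str, str]) -> str:
    """Sense-strand genomic body sequence (intron retained)."""
    s = genome[gene.chrom][gene.start : gene.end]
    return str(Seq(s).reverse_complement()) if gene.strand == "-" else s


def spliced_sequence(gene: TRNAGene, genome: dict[str, str]) -> str:
    body = gene_sequence(gene, genome)
    if not gene.introns:
        return body
    out, pos = [], 0
    for s, e in sorted(gene.introns):
        out.append(body[pos:s])
        pos = e
    out.append(body[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# reference builders


def build_extended_reference(
    genes: Sequence[TRNAGene],
    genome: dict[str, str],
    up: int = DEFAULT_LEADER,
    down: int = DEFAULT_TRAILER,
) -> ReferenceSet:
    """Extend each gene with genomic leader/trailer; intron retained.

    Extensions are clamped at contig boundaries and the clamping recorded on
    the entry (mitochondrial contig edges commonly truncate the trailer).
    """
    if up < 0 or down < 0:
        raise ValueError("extensions must be non-negative")
    entries = []
    for g in genes:
        contig = genome[g.chrom]
        # in genomic coordinates the sense-strand leader of a minus-strand
        # gene lies downstream of the interval
        g_up, g_down = (up, down) if g.strand == "+" else (down, up)
        lo = max(0, g.start - g_up)
        hi = min(len(contig), g.end + g_down)
        seq = contig[lo:hi]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
            leader = hi - g.end
            trailer = g.start - lo
        else:
            leader = g.start - lo
            trailer = hi - g.end
        clamped = leader < up or trailer < down
        if clamped:
            logger.warning(
                "%s: extension clamped at contig boundary (leader %d/%d, trailer %d/%d)",
                g.gene_id, leader, up, trailer, down,
            )
        entries.append(
            ReferenceEntry(
                name=g.gene_id, sequence=seq, leader_len=leader,
                mature_start=leader,
                editing_point=leader + g.mature_length_genomic,
                trailer_len=trailer, edited=False,
                compartment=g.compartment, clamped=clamped,
            )
        )
    return ReferenceSet(entries, "non_edited")


def build_cca_edited(non_edited: ReferenceSet) -> ReferenceSet:
    """Insert ``CCA`` at each entry's editing point (3' CCA edition point)."""
    if non_edited.kind != "non_edited":
        raise ValueError("input must be a non_edited reference set")
    entries = []
    for e in non_edited:
        if e.editing_point <= 0:
            raise ValueError(f"{e.name}: missing editing-point anchor")
        seq = e.sequence[: e.editing_point] + "CCA" + e.sequence[e.editing_point :]
        entries.append(
            ReferenceEntry(
                name=e.name, sequence=seq, leader_len=e.leader_len,
                mature_start=e.mature_start, editing_point=e.editing_point,
                trailer_len=e.trailer_len, edited=True,
                compartment=e.compartment, clamped=e.clamped,
            )
        )
    return ReferenceSet(entries, "cca_edited")


def build_unique_mature(
    genes: Sequence[TRNAGene],
    genome: dict[str, str],
    append_cca: bool = True,
) -> ReferenceSet:
    """Spliced mature sequences, deduplicated; identical sequences collapse
    into one entry named by the sorted, ';'-joined member gene ids."""
    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(spliced_sequence(g, genome), []).append(g.gene_id)
    compartments = {g.gene_id: g.compartment for g in genes}
    entries = []
    for seq, ids in groups.items():
        ids = sorted(ids)
        full = seq + "CCA" if append_cca else seq
        entries.append(
            ReferenceEntry(
                name=";".join(ids), sequence=full, leader_len=0,
                mature_start=0, editing_point=len(seq),
                trailer_len=0, edited=append_cca,
                compartment=compartments[ids[0]],
            )
        )
    entries.sort(key=lambda e: e.name)
    return ReferenceSet(entries, "unique_mature")


def build_non_trna_space(
    genome: dict[str, str], genes: Sequence[TRNAGene]
) -> tuple[ReferenceSet, list[tuple[str, int, int, str]]]:
    """Hard-mask every tRNA gene interval to N.

    Returns the masked genome as a reference set plus the masked intervals as
    BED-style tuples (chrom, start, end, name).
    """
    masked = {c: list(s) for c, s in genome.items()}
    bed = []
    for g in genes:
        masked[g.chrom][g.start : g.end] = "N" * (g.end - g.start)
        bed.append((g.chrom, g.start, g.end, g.gene_id))
    entries = [
        ReferenceEntry(name=c, sequence="".join(s), leader_len=0, mature_start=0,
                       editing_point=0, trailer_len=0)
        for c, s in masked.items()
    ]
    return ReferenceSet(entries, "non_trna_space"), bed


def split_snorna_by_length(
    snorna_fasta: str | Path | Iterable[tuple[str, str]],
    threshold: int = SNORNA_CD_MAX_LEN,
) -> tuple[ReferenceSet, ReferenceSet]:
    """Partition snoRNAs at the length threshold: <=120 nt box C/D (guides of
    2'-O-methylation), >120 nt box H/ACA (guides of pseudouridylation)."""
    if isinstance(snorna_fasta, (str, Path)):
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(snorna_fasta), "fasta")]
    else:
        records = [(n, s.upper()) for n, s in snorna_fasta]
    cd, haca = [], []
    for name, seq in records:
        entry = ReferenceEntry(name=name, sequence=seq, leader_len=0,
                               mature_start=0, editing_point=0, trailer_len=0)
        (cd if len(seq) <= threshold else haca).append(entry)
    return ReferenceSet(cd, "snoRNA_CD"), ReferenceSet(haca, "snoRNA_HACA")


def plain_reference_set(
    fasta: str | Path | Iterable[tuple[str, str]], kind: str
) -> ReferenceSet:
    """Wrap an auxiliary FASTA (rRNA, miRNA, TE, ...) as an anchor-less set."""
    if isinstance(fasta, (str, Path)):
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(fasta), "fasta")]
    else:
        records = [(n, s.upper()) for n, s in fasta]
    entries = [
        ReferenceEntry(name=n, sequence=s, leader_len=0, mature_start=0,
                       editing_point=0, trailer_len=0)
        for n, s in records
    ]
    return ReferenceSet(entries, kind)


# ---------------------------------------------------------------------------
# persistence


def write_reference_set(refset: ReferenceSet, fasta_path: str | Path,
                        anchors_path: str | Path | None = None) -> None:
    """Write a set as FASTA plus an anchor TSV sidecar."""
    with open(fasta_path, "w") as fh:
        for e in refset:
            fh.write(f">{e.name}\n{e.sequence}\n")
    if anchors_path is not None:
        with open(anchors_path, "w") as fh:
            fh.write("name\tleader_len\tmature_start\tediting_point\ttrailer_len"
                     "\tedited\tcompartment\tclamped\n")
            for e in refset:
                fh.write(f"{e.name}\t{e.leader_len}\t{e.mature_start}\t"
                         f"{e.editing_point}\t{e.trailer_len}\t{int(e.edited)}\t"
                         f"{e.compartment}\t{int(e.clamped)}\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
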
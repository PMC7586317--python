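"""Small-RNA read IO and preprocessing: adapter clipping, length filtering,
replicate merging.

The downstream pipeline is exact-match only, so qualities are parsed but
never used: a single miscalled base already prevents alignment, which makes
quality trimming redundant here.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

MIN_READ_LEN = 15
MAX_READ_LEN = 29
DEFAULT_MIN_OVERLAP = 7


@dataclass
class Read:
    read_id: str
    sequence: str
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    reads: list[Read]
    sample_id: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def load_reads(file: str | Path, sample_id: str) -> ReadSet:
    """Load FASTA or FASTQ (optionally gzipped); format sniffed from the
    extension or the first byte. N-containing reads are retained — they
    simply never exact-match anything."""
    path = Path(file)
    fmt = _sniff_format(path)
    reads: list[Read] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            reads.append(Read(rec.id, str(rec.seq), sample_id))
    if not reads:
        logger.warning("%s: no reads parsed from %s", sample_id, path)
    return ReadSet(reads, sample_id, provenance=[str(path)])


def write_fasta(readset: ReadSet, path: str | Path) -> None:
    opener = gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")
    with opener as fh:
        for r in readset:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def clip_adapter(
    reads: ReadSet,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    keep_unclipped: bool = False,
) -> ReadSet:
    """Remove the 3' adapter and everything downstream of it.

    The leftmost exact occurrence of the full adapter wins; failing that, an
    adapter prefix of >= ``min_overlap`` nt flush with the read end counts as
    evidence. Reads without adapter evidence are dropped by default: in a
    size-selected library a missing adapter implies an insert longer than the
    read, which would contaminate length profiles.
    """
    adapter = adapter.upper()
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    out = []
    n_dropped = 0
    for r in reads:
        seq = r.sequence
        pos = seq.find(adapter)
        if pos == -1:
            # adapter prefix running off the 3' end
            max_part = min(len(adapter) - 1, len(seq))
            for plen in range(max_part, min_overlap - 1, -1):
                if seq.endswith(adapter[:plen]):
                    pos = len(seq) - plen
                    break
        if pos >= 1:
            out.append(Read(r.read_id, seq[:pos], r.source_sample))
        elif pos == 0:
            n_dropped += 1  # adapter dimer, no insert
        elif keep_unclipped:
            out.append(Read(r.read_id, seq, r.source_sample))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d reads without a usable insert",
                    reads.sample_id, n_dropped)
    return ReadSet(out, reads.sample_id, provenance=list(reads.provenance))


def filter_by_length(
    reads: ReadSet, min: int = MIN_READ_LEN, max: int = MAX_READ_LEN
) -> ReadSet:
    """Keep reads with min <= length <= max (defaults 15-29 nt; min=17
    reproduces the exclusion of the smallest 15-16 nt fragments)."""
    if min > max:
        raise ValueError("min must be <= max")
    kept, discarded = [], Counter()
    for r in reads:
        if min <= len(r) <= max:
            kept.append(r)
        else:
            discarded[len(r)] += 1
    if discarded:
        logger.info("%s: discarded by length: %s", reads.sample_id,
                    dict(sorted(discarded.items())))
    return ReadSet(kept, reads.sample_id, provenance=list(reads.provenance))


def merge_replicates(readsets: Sequence[ReadSet], merged_id: str) -> ReadSet:
    """Concatenate replicate libraries tail-to-head; read ids are prefixed
    with the replicate index so they stay unique."""
    if not readsets:
        raise ValueError("need at least one ReadSet")
    reads, provenance = [], []
    for i, rs in enumerate(readsets, 1):
        provenance.extend(rs.provenance)
        for r in rs:
            reads.append(Read(f"rep{i}.{r.read_id}", r.sequence, merged_id))
    return ReadSet(reads, merged_id, provenance=provenance)
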
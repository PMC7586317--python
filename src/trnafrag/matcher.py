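"""Exact-match (zero-mismatch) placement of short reads on reference sets.

Everything in the pipeline is full-length exact matching: no mismatches, no
indels, no soft-clipping. Reads containing N never match. Multi-site reads
are resolved by one of two policies: deterministic first site (smallest
(ref_name, start) — used wherever only the aligned/unaligned partition
matters) or a seeded uniform-random site (used for coverage maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_preprocess import Read, ReadSet
from .refbuild import ReferenceSet

MIN_QUERY_LEN = 15
MAX_QUERY_LEN = 29


@dataclass(frozen=True)
class Alignment:
    read_id: str
    ref_name: str
    start: int
    end: int
    read_length: int
    policy: str
    n_candidate_sites: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.read_length:
            raise ValueError("end - start must equal read length")
        if self.n_candidate_sites < 1:
            raise ValueError("n_candidate_sites must be >= 1")


class MatchIndex:
    """Seed-and-verify substring index over a reference set.

    All ``min_len``-mers are hashed to their positions; a query of length
    >= min_len is seeded with its first min_len nt and verified in full.
    Shorter queries fall back to a direct scan, giving identical answers to a
    naive sliding-window search for any query length.
    """

    def __init__(self, refset: ReferenceSet, min_len: int = MIN_QUERY_LEN,
                 max_len: int = MAX_QUERY_LEN) -> None:
        if len(refset) == 0:
            raise ValueError("empty reference set")
        self.refset = refset
        self.min_len = min_len
        self.max_len = max_len
        self._seqs: dict[str, str] = {e.name: e.sequence for e in refset}
        self._seed: dict[str, list[tuple[str, int]]] = {}
        k = min_len
        for name, seq in self._seqs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._seed.setdefault(kmer, []).append((name, i))

    def enumerate_matches(self, read: Read | str) -> list[tuple[str, int]]:
        """All (ref_name, start) placements of the read, sorted."""
        seq = read.sequence if isinstance(read, Read) else read.upper()
        if "N" in seq:
            return []
        if len(seq) < self.min_len:
            return self._scan(seq)
        hits = []
        for name, i in self._seed.get(seq[: self.min_len], ()):
            if self._seqs[name][i : i + len(seq)] == seq:
                hits.append((name, i))
        hits.sort()
        return hits

    def _scan(self, seq: str) -> list[tuple[str, int]]:
        hits = []
        for name, ref in self._seqs.items():
            i = ref.find(seq)
            while i != -1:
                hits.append((name, i))
                i = ref.find(seq, i + 1)
        hits.sort()
        return hits


def build_index(refset: ReferenceSet, min_len: int = MIN_QUERY_LEN,
                max_len: int = MAX_QUERY_LEN) -> MatchIndex:
    return MatchIndex(refset, min_len, max_len)


def enumerate_matches(read: Read | str,
                      refset: ReferenceSet | MatchIndex) -> list[tuple[str, int]]:
    index = refset if isinstance(refset, MatchIndex) else MatchIndex(refset)
    return index.enumerate_matches(read)


def align_reads(
    reads: ReadSet,
    index: MatchIndex,
    mode: str = "first",
    seed: int | None = None,
) -> tuple[list[Alignment], ReadSet]:
    """Place each read at one site, or report it unaligned.

    ``first`` picks the lexicographically smallest (ref_name, start);
    ``random`` picks uniformly among all candidate sites from one seeded
    stream consumed in input read order, so reruns with the same seed are
    byte-identical.
    """
    if mode not in {"first", "random"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "random":
        if seed is None:
            raise ValueError("mode='random' requires a seed")
        rng = np.random.default_rng(seed)
    alignments: list[Alignment] = []
    unaligned: list[Read] = []
    for r in reads:
        sites = index.enumerate_matches(r)
        if not sites:
            unaligned.append(r)
            continue
        if mode == "first":
            name, start = sites[0]
        else:
            name, start = sites[int(rng.integers(len(sites)))]
        alignments.append(
            Alignment(r.read_id, name, start, start + len(r), len(r),
                      mode, len(sites))
        )
    return alignments, ReadSet(unaligned, reads.sample_id,
                               provenance=list(reads.provenance))


def write_alignments_tsv(alignments: Sequence[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_name\tstart\tend\tlength\tn_candidate_sites\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.ref_name}\t{a.start}\t{a.end}\t"
                     f"{a.read_length}\t{a.n_candidate_sites}\n")


def write_alignments_sam(alignments: Sequence[Alignment], index: MatchIndex,
                         path: str | Path) -> None:
    """Emit placements as plain-text SAM (flag 0, MAPQ 255, NM:i:0)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in index._seqs.items()],
    })
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.query_sequence = index._seqs[a.ref_name][a.start : a.end]
            seg.flag = 0
            seg.reference_id = header.get_tid(a.ref_name)
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.read_length}M"
            seg.set_tag("NM", 0, "i")
            out.write(seg)
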
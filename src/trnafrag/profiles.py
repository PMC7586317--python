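"""Descriptive profiles: per-class size distributions, scaled per-base
coverage, scale-regions metaprofiles, and 3'-anchored sequence logos.

Coverage is computed from single-site placements (multi-mappers randomly
placed with a fixed seed) and scaled by 1/NF, matching how the normalized
read maps are built. The logo is a position-frequency matrix over the last
15 nt of every fragment, right-aligned so the 3'-terminal CCA signature of
3'-tRFs lines up.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matcher import Alignment
from .refbuild import ReferenceSet
from .trf_extract import TRFClass, TRFCollection

logger = logging.getLogger(__name__)

LOGO_ALPHABET = ("A", "C", "G", "T")
DEFAULT_LOGO_K = 15
DEFAULT_BINS = 100
LENGTH_RANGE = range(15, 30)


def size_distribution(
    collection: TRFCollection, scale: float = 1.0
) -> pd.DataFrame:
    """Scaled read counts per (length, class): lengths 15-29 as rows, tRF
    classes as columns."""
    lengths = [len(r.sequence) for r in collection.records]
    if lengths and (min(lengths) < LENGTH_RANGE.start or max(lengths) >= LENGTH_RANGE.stop):
        raise ValueError("fragment lengths outside the 15-29 nt range")
    table = pd.DataFrame(
        0.0, index=list(LENGTH_RANGE), columns=[c.value for c in TRFClass]
    )
    table.index.name = "length"
    for rec in collection.records:
        table.loc[len(rec.sequence), rec.trf_class.value] += scale
    return table


def coverage_track(
    alignments: Sequence[Alignment],
    refset: ReferenceSet,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-base scaled depth for every reference entry.

    Each placed read adds ``scale`` over its interval, so the total signal of
    a track set equals scale x the summed lengths of its placed reads.
    """
    tracks = {e.name: np.zeros(len(e.sequence)) for e in refset}
    for a in alignments:
        tracks[a.ref_name][a.start : a.end] += scale
    return tracks


def metaprofile(
    tracks: Mapping[str, np.ndarray],
    regions: Sequence[tuple[str, int, int]] | Sequence[tuple[str, int, int, str]],
    bins: int = DEFAULT_BINS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scale-regions metaprofile: each region's depth vector is stretched to
    ``bins`` bins (bin value = mean of the bases falling in the bin), then
    averaged column-wise across regions.

    ``regions`` are BED-style (ref_name, start, end[, label]) tuples on track
    coordinates. Empty or unknown regions are skipped with a warning. Returns
    the regions x bins matrix and the mean profile.
    """
    rows, labels = [], []
    for region in regions:
        name, start, end = region[0], int(region[1]), int(region[2])
        label = region[3] if len(region) > 3 else f"{name}:{start}-{end}"
        if name not in tracks or end <= start:
            logger.warning("skipping empty or unknown region %s", label)
            continue
        depth = np.asarray(tracks[name][start:end], dtype=float)
        edges = np.floor(np.arange(bins + 1) * len(depth) / bins).astype(int)
        binned = np.empty(bins)
        for b in range(bins):
            lo, hi = edges[b], edges[b + 1]
            # a bin narrower than one base reuses the base it falls on
            binned[b] = depth[lo:hi].mean() if hi > lo else depth[min(lo, len(depth) - 1)]
        rows.append(binned)
        labels.append(label)
    matrix = pd.DataFrame(rows, index=labels,
                          columns=[f"bin{b}" for b in range(bins)])
    mean_profile = matrix.to_numpy().mean(axis=0) if len(matrix) else np.zeros(bins)
    return matrix, mean_profile


def logo_last_k(sequences: Iterable[str], k: int = DEFAULT_LOGO_K) -> pd.DataFrame:
    """Position-frequency matrix over the last ``k`` nt, right-aligned.

    Sequences shorter than k contribute only to their available rightmost
    positions; U is folded onto T. Every column with at least one
    contributing sequence sums to 1; empty columns are all-zero.
    """
    counts = np.zeros((k, 4))
    index = {b: i for i, b in enumerate(LOGO_ALPHABET)}
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        tail = seq[-k:]
        offset = k - len(tail)
        for pos, base in enumerate(tail):
            if base in index:
                counts[offset + pos, index[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
    table = pd.DataFrame(freqs, columns=list(LOGO_ALPHABET),
                         index=[f"-{k - i}" for i in range(k)])
    table.index.name = "position"
    return table


# ---------------------------------------------------------------------------
# persistence


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded bedGraph of the depth tracks."""
    with open(path, "w") as fh:
        for name in sorted(tracks):
            depth = tracks[name]
            if len(depth) == 0:
                continue
            run_start, run_val = 0, depth[0]
            for i in range(1, len(depth)):
                if depth[i] != run_val:
                    if run_val != 0:
                        fh.write(f"{name}\t{run_start}\t{i}\t{run_val:g}\n")
                    run_start, run_val = i, depth[i]
            if run_val != 0:
                fh.write(f"{name}\t{run_start}\t{len(depth)}\t{run_val:g}\n")


def plot_logo(pfm: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar frequency logo rendering of a PFM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(pfm)), 2.5))
    x = np.arange(len(pfm))
    bottom = np.zeros(len(pfm))
    for base in LOGO_ALPHABET:
        ax.bar(x, pfm[base].to_numpy(), bottom=bottom, color=colors[base],
               label=base, width=0.9)
        bottom += pfm[base].to_numpy()
    ax.set_xticks(x, pfm.index, rotation=90, fontsize=6)
    ax.set_ylabel("frequency")
    ax.legend(ncol=4, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
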
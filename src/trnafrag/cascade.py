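"""Annotation cascade: ordered first-match assignment of reads to reference
categories, each read counted exactly once.

Two published category orders are shipped as named profiles. The ``methods``
order runs tRNA references first; the ``figure`` order runs them last, after
miRNA/ncRNA/genic categories. Because a read can match several categories,
the order is an explicit, reported knob — reordering the cascade is a known
source of annotation bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_preprocess import ReadSet
from .matcher import MatchIndex
from .refbuild import ReferenceSet

#: category orders as published; rRNA is assumed depleted beforehand
ORDER_PROFILES: dict[str, list[str]] = {
    "methods": ["tRNA", "tRNA_CCA_edited", "miRNA", "TE", "ncRNA",
                "genes", "intergenic"],
    "figure": ["miRNA", "ncRNA", "intergenic", "genes", "TE", "snoRNA",
               "tRF_non_CCA", "tRF_CCA"],
}


@dataclass
class AnnotationSummary:
    sample_id: str
    categories: list[tuple[str, int]]
    depth: int
    unmatched: int
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.categories) + self.unmatched
        if total != self.depth:
            raise ValueError("category counts + unmatched must equal depth")
        if self.depth > 0 and not self.fractions:
            self.fractions = {name: c / self.depth for name, c in self.categories}
            self.fractions["unmatched"] = self.unmatched / self.depth


def annotate_cascade(
    reads: ReadSet,
    ordered_refsets: Sequence[tuple[str, ReferenceSet | MatchIndex]],
    order_profile: str | None = None,
) -> AnnotationSummary:
    """Assign each read to the first category whose reference set it matches
    (zero mismatches, mode=first — within a category the site is irrelevant).

    ``ordered_refsets`` is a list of (category name, reference set) pairs; if
    ``order_profile`` is given, the pairs are reordered to that published
    profile and every profile category must be present.
    """
    names = [n for n, _ in ordered_refsets]
    if len(names) != len(set(names)):
        raise ValueError("duplicate category names in cascade")
    if order_profile is not None:
        wanted = ORDER_PROFILES[order_profile]
        by_name = dict(ordered_refsets)
        missing = [w for w in wanted if w not in by_name]
        if missing:
            raise ValueError(f"profile {order_profile!r} needs categories {missing}")
        ordered_refsets = [(w, by_name[w]) for w in wanted]

    depth = len(reads)
    remaining = list(reads)
    categories: list[tuple[str, int]] = []
    for name, refset in ordered_refsets:
        index = refset if isinstance(refset, MatchIndex) else MatchIndex(refset)
        matched, passed = [], []
        for r in remaining:
            (matched if index.enumerate_matches(r) else passed).append(r)
        categories.append((name, len(matched)))
        remaining = passed
    return AnnotationSummary(reads.sample_id, categories, depth, len(remaining))


def summary_to_fractions(summary: AnnotationSummary) -> list[tuple[str, float]]:
    """Category percentages of library depth, rounded to 2 decimals."""
    if summary.depth <= 0:
        raise ValueError("depth must be positive")
    rows = [(name, round(100 * count / summary.depth, 2))
            for name, count in summary.categories]
    rows.append(("unmatched", round(100 * summary.unmatched / summary.depth, 2)))
    return rows


def write_summary(summary: AnnotationSummary, tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("category\tcount\tpercent\n")
        for (name, count), (_, pct) in zip(
            summary.categories + [("unmatched", summary.unmatched)],
            summary_to_fractions(summary),
        ):
            fh.write(f"{name}\t{count}\t{pct:.2f}\n")
    if json_path is not None:
        payload = {
            "sample_id": summary.sample_id,
            "depth": summary.depth,
            "categories": dict(summary.categories),
            "unmatched": summary.unmatched,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_pie(summary: AnnotationSummary, path: str | Path,
             max_depth: int | None = None) -> None:
    """Pie chart whose radius scales with library depth (sqrt-area scaling)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [n for n, c in summary.categories if c] + (
        ["unmatched"] if summary.unmatched else [])
    sizes = [c for _, c in summary.categories if c] + (
        [summary.unmatched] if summary.unmatched else [])
    radius = (summary.depth / (max_depth or summary.depth)) ** 0.5
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(sizes, labels=labels, radius=radius, autopct="%1.2f%%")
    ax.set_title(f"{summary.sample_id} ({summary.depth / 1e6:.2f} M reads)")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
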
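"""Count tables, median-of-ratios (DESeq geometric) normalization, and the
heatmap / genotype-ratio tables.

Count tables are pandas DataFrames with features as the index and samples as
columns. The per-sample normalization factor NF is the median, over features
with all-positive counts, of the ratio of the sample's count to the feature's
geometric mean across samples; maps and tables are scaled by 1/NF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matcher import Alignment
from .trf_extract import TRFCollection

logger = logging.getLogger(__name__)


@dataclass
class SizeFactorSet:
    """Per-sample normalization factor NF and its reciprocal scale = 1/NF."""

    factors: pd.Series  # indexed by sample

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def scales(self) -> pd.Series:
        return 1.0 / self.factors

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def count_hits(
    placements: Iterable[Alignment] | TRFCollection | dict,
    group_by: str = "reference",
) -> pd.DataFrame:
    """Tally placements into a features x samples count table.

    ``placements`` may be a single sample's alignment list, a TRFCollection,
    or a dict of sample_id -> either of those. ``group_by`` is ``reference``
    (one row per reference name) or ``reference+class`` (rows keyed
    ``ref/CLASS``; requires TRF records).
    """
    if group_by not in {"reference", "reference+class"}:
        raise ValueError(f"unknown group_by {group_by!r}")
    if not isinstance(placements, dict):
        sample = getattr(placements, "sample_id", "sample")
        placements = {sample: placements}
    columns = {}
    for sample, item in placements.items():
        if isinstance(item, TRFCollection):
            if group_by == "reference":
                keys = [r.ref_name for r in item.records]
            else:
                keys = [f"{r.ref_name}/{r.trf_class.value}" for r in item.records]
        else:
            if group_by != "reference":
                raise ValueError("alignments carry no class; use group_by='reference'")
            item = list(item)
            n_multi = sum(a.n_candidate_sites > 1 for a in item)
            if n_multi:
                # counting against the extended reference multimaps across
                # identical tRNA copies; the unique-mature set avoids this
                # at the cost of losing tRF-1
                logger.warning("%s: %d/%d placements had multiple candidate "
                               "sites (multimapping)", sample, n_multi, len(item))
            keys = [a.ref_name for a in item]
        columns[sample] = pd.Series(keys).value_counts() if keys else pd.Series(dtype=int)
    table = pd.DataFrame(columns).fillna(0).astype(int)
    table = table.sort_index()
    table.index.name = "feature"
    return table


def deseq_size_factors(table: pd.DataFrame) -> SizeFactorSet:
    """Median-of-ratios size factors.

    For each feature with all-positive counts, compute its geometric mean
    across samples; a sample's factor is the median of its counts divided by
    those geometric means. Features with any zero count are excluded. With an
    even number of usable features the median is the mean of the two central
    ratios.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    counts = table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot normalize: no feature has all-positive counts")
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    ratios = np.exp(log_counts - log_geomean)
    factors = pd.Series(np.median(ratios, axis=0), index=table.columns,
                        name="NF")
    return SizeFactorSet(factors)


def scale_counts(table: pd.DataFrame, factors: SizeFactorSet) -> pd.DataFrame:
    """Divide each sample column by its size factor (scale by 1/NF)."""
    missing = [s for s in table.columns if s not in factors.factors.index]
    if missing:
        raise KeyError(f"no size factor for samples {missing}")
    return table / factors.factors[table.columns]


def genotype_ratio(
    scaled: pd.DataFrame, sample_a: str, sample_b: str
) -> pd.DataFrame:
    """Per-feature expression ratio sample_a / sample_b on scaled counts.

    Zero in the denominator yields ratio NA with ``undefined`` flagged —
    never a silent infinity. Sort the result on the ``ratio`` column to rank
    gains and losses between genotypes.
    """
    for s in (sample_a, sample_b):
        if s not in scaled.columns:
            raise KeyError(f"unknown sample {s!r}")
    a, b = scaled[sample_a], scaled[sample_b]
    ratio = a / b.where(b != 0)
    return pd.DataFrame({
        sample_a: a, sample_b: b,
        "ratio": ratio, "undefined": (b == 0),
    })


def heatmap_table(scaled: pd.DataFrame, sort_key: str = "row_sum") -> pd.DataFrame:
    """log2(value + 1) transform, rows ordered for heatmap display.

    ``sort_key``: ``row_sum`` (descending total, default), ``name``, or a
    sample name (descending on that column). The transform is monotone, so
    within-column ordering of features is preserved.
    """
    if (scaled.to_numpy() < 0).any():
        raise ValueError("heatmap input must be non-negative")
    logged = np.log2(scaled + 1.0)
    if sort_key == "row_sum":
        order = logged.sum(axis=1).sort_values(ascending=False).index
    elif sort_key == "name":
        order = sorted(logged.index)
    elif sort_key in logged.columns:
        order = logged[sort_key].sort_values(ascending=False).index
    else:
        raise ValueError(f"unknown sort key {sort_key!r}")
    return logged.loc[order]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def write_size_factors(factors: SizeFactorSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tNF\tscale\n")
        for sample, nf in factors.factors.items():
            fh.write(f"{sample}\t{nf:.10g}\t{1.0 / nf:.10g}\n")
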
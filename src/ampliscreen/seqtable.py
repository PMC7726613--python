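"""Unique-sequence count tables and the abundance/depth filters.

One table per locus: rows are exact unique merged sequences, columns are
samples, cells are read counts.  Exact dereplication plays the role of ASV
inference for this pipeline (denoising is out of scope); the rare-sequence
filter (< 10 reads across all samples) suppresses error sequences, and the
per-sample depth filters implement the locus-specific floors (5000 reads for
bacterial 16S community analysis, 1000 for the genotyping/blood-meal loci).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping  # noqa: F401 (part of the documented signatures)

import pandas as pd

from .references import BACTERIA_16S, COX1, KDR, MAMMAL_16S, S200X6

MIN_GLOBAL_COUNT = 10

# Per-sample read-depth floors by locus; loci absent here (the parasite/virus
# panel) have no per-sample floor.
DEPTH_THRESHOLDS = {
    BACTERIA_16S: 5000,
    KDR: 1000,
    S200X6: 1000,
    COX1: 1000,
    MAMMAL_16S: 1000,
}


@dataclass
class UniqueSeqTable:
    """Unique sequences x samples count matrix for one locus."""

    locus: str
    counts: pd.DataFrame  # index: sequence strings; columns: sample ids; int counts

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sequences in table index")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __len__(self) -> int:
        return len(self.counts)


def dereplicate(
    seqs_by_sample: Mapping[str, Iterable[str] | Counter],
    locus: str,
    drop_n: bool = True,
) -> UniqueSeqTable:
    """Collapse per-sample sequence lists (or Counters) to a count table.

    Exact string grouping; sequences containing N are dropped first (they
    cannot be confidently dereplicated).  Empty input yields an empty table.
    """
    cols: dict[str, Counter] = {}
    for sample, seqs in seqs_by_sample.items():
        counter = Counter(seqs) if not isinstance(seqs, Counter) else seqs
        if drop_n:
            counter = Counter({s: n for s, n in counter.items() if "N" not in s})
        cols[sample] = counter
    df = pd.DataFrame(cols).fillna(0).astype(int)
    df = df.sort_index()
    df = df[sorted(df.columns)]
    return UniqueSeqTable(locus, df)


def filter_rare(table: UniqueSeqTable, min_total: int = MIN_GLOBAL_COUNT) -> UniqueSeqTable:
    """Drop sequences observed fewer than ``min_total`` times across all samples."""
    keep = table.row_totals >= min_total
    return UniqueSeqTable(table.locus, table.counts.loc[keep])


def sample_depth_filter(
    table: UniqueSeqTable, threshold: int | None = None
) -> tuple[UniqueSeqTable, list[str]]:
    """Drop samples whose total reads fall below the locus floor.

    Returns the filtered table and the excluded sample ids.  With no explicit
    ``threshold`` the locus-specific floor is looked up; loci without a
    configured floor raise ``KeyError``.
    """
    if threshold is None:
        if table.locus not in DEPTH_THRESHOLDS:
            raise KeyError(
                f"no depth threshold configured for locus {table.locus!r}; pass threshold="
            )
        threshold = DEPTH_THRESHOLDS[table.locus]
    totals = table.sample_totals
    keep = totals >= threshold
    excluded = sorted(totals.index[~keep])
    return UniqueSeqTable(table.locus, table.counts.loc[:, keep]), excluded


def write_table(table: UniqueSeqTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "sequence"
    df.to_csv(path, sep="\t")


def read_table(path, locus: str) -> UniqueSeqTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return UniqueSeqTable(locus, df.astype(int))
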
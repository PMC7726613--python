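"""Read routing: sample assignment, locus identification, pair merging, trimming.

Reads are assigned to samples by an exact match of the read-1 prefix against
the barcode table (no mismatch tolerance) and to loci by an exact, anchored
primer match immediately after the barcode.  Pairs are merged over the
best-scoring ungapped overlap; merged amplicons are primer-trimmed and length
filtered before dereplication.
"""

from __future__ import annotations

import functools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import Locus, PanelDesign
from .references import revcomp

UNASSIGNED = "UNASSIGNED"
UNKNOWN = "UNKNOWN"

# disposition codes
MERGED = "merged"
UNMERGED_KEPT = "unmerged-kept"
DISCARDED_SHORT = "discarded-short"
DISCARDED_UNROUTABLE = "discarded-unroutable"

MIN_OVERLAP = 12
MAX_MISMATCH_FRAC = 0.25
MIN_KEEP_LEN = 90  # kept only when strictly longer
SHORT_AMPLICON_MAX = 300  # loci under this expected length get the 50-bp 5' trim
HEAD_TRIM = 50


def assign_sample(read1_seq: str, barcode_to_sample: Mapping[str, str], barcode_length: int) -> str:
    """Exact barcode lookup on the read-1 prefix; no mismatch tolerance."""
    if len(read1_seq) < barcode_length:
        return UNASSIGNED
    return barcode_to_sample.get(read1_seq[:barcode_length], UNASSIGNED)


def identify_locus(seq_after_barcode: str, primers: Mapping[str, str]) -> str:
    """Anchored exact forward-primer match; the longest matching primer wins."""
    best = UNKNOWN
    best_len = -1
    for locus, fwd in primers.items():
        if len(fwd) > best_len and seq_after_barcode.startswith(fwd):
            best, best_len = locus, len(fwd)
    return best


def merge_pairs(
    read1: str,
    read2: str,
    qual1: str | None = None,
    qual2: str | None = None,
    min_overlap: int = MIN_OVERLAP,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
) -> str | None:
    """Consensus of the best-scoring ungapped overlap, or None.

    ``read2`` is supplied as sequenced and reverse-complemented internally.
    Candidate overlaps of length >= ``min_overlap`` are scored by mismatch
    fraction; the lowest fraction wins, ties going to the longer overlap.  At
    mismatched overlap positions the higher-quality base is taken (read 1 on
    quality ties).

    Both orientations are searched: the usual "innie" layout (read 1 suffix
    against the start of reverse-complemented read 2) and the dovetailed
    "outie" layout that arises when the amplicon is shorter than the read
    length and both reads run through it; in the outie case the overhang of
    read 2 past the amplicon start is adapter/barcode read-through and is
    dropped, so the merged sequence is the read-1 frame.
    """
    rc2 = revcomp(read2)
    rq2 = qual2[::-1] if qual2 is not None else None
    n1, n2 = len(read1), len(rc2)
    if min(n1, n2) < min_overlap:
        return None
    best = _best_overlap(read1, rc2, min_overlap, max_mismatch_frac)
    if best is None:
        return None
    o, orientation = best
    if orientation == "innie":
        mism = [i for i in range(o) if read1[n1 - o + i] != rc2[i]]
    else:
        mism = [i for i in range(o) if read1[i] != rc2[n2 - o + i]]
    if orientation == "innie":
        if not mism:
            return read1 + rc2[o:]
        head = read1[: n1 - o]
        overlap = list(read1[n1 - o:])
        for i in mism:
            q1 = qual1[n1 - o + i] if qual1 is not None else "!"
            q2 = rq2[i] if rq2 is not None else "!"
            if q2 > q1:
                overlap[i] = rc2[i]
        return head + "".join(overlap) + rc2[o:]
    if not mism:
        return read1
    overlap = list(read1[:o])
    for i in mism:
        q1 = qual1[i] if qual1 is not None else "!"
        q2 = rq2[n2 - o + i] if rq2 is not None else "!"
        if q2 > q1:
            overlap[i] = rc2[n2 - o + i]
    return "".join(overlap) + read1[o:]


def _best_overlap(
    read1: str, rc2: str, min_overlap: int, max_mismatch_frac: float
) -> tuple[int, str] | None:
    """Best ungapped overlap between read1 and reverse-complemented read 2.

    Scores every admissible overlap in both orientations at once: the outer
    equality matrix's diagonal sums give the match count for each offset.
    Returns (overlap length, orientation) minimizing the mismatch fraction,
    ties to the longer overlap, then to the innie orientation.
    """
    x = np.frombuffer(read1.encode(), dtype=np.uint8)
    y = np.frombuffer(rc2.encode(), dtype=np.uint8)
    n1, n2 = len(x), len(y)
    eq = (x[:, None] == y[None, :]).ravel()
    # diagonal index (col - row) shifted to [0, n1+n2-2]
    idx = _diag_index(n1, n2)
    diag_matches = np.bincount(idx, weights=eq, minlength=n1 + n2 - 1)
    o_max = min(n1, n2)
    os_ = np.arange(min_overlap, o_max + 1)
    # innie overlap o lies on diagonal col-row = o-n1; outie on col-row = n2-o
    m_in = diag_matches[os_ - n1 + (n1 - 1)]
    m_out = diag_matches[(n2 - os_) + (n1 - 1)]
    frac_in = (os_ - m_in) / os_
    frac_out = (os_ - m_out) / os_
    if n1 == n2:
        frac_out[-1] = np.inf  # o=n duplicates the innie full overlap
    best = None  # (frac, -o, orient_rank, o, orientation)
    for frac, orient, rank in ((frac_in, "innie", 0), (frac_out, "outie", 1)):
        ok = frac <= max_mismatch_frac
        if not ok.any():
            continue
        k = np.lexsort((np.full(ok.sum(), rank), -os_[ok], frac[ok]))[0]
        cand = (frac[ok][k], -os_[ok][k], rank, int(os_[ok][k]), orient)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return None
    return best[3], best[4]


@functools.lru_cache(maxsize=8)
def _diag_index(n1: int, n2: int) -> np.ndarray:
    r = np.arange(n1)
    c = np.arange(n2)
    return (c[None, :] - r[:, None] + (n1 - 1)).ravel()


def trim_amplicon(merged: str, locus: Locus) -> str | None:
    """Remove primers from a merged amplicon.

    The forward primer must be present at the start (else the sequence is
    unroutable -> None).  If the reverse primer is found the insert between
    the primers is returned; otherwise short-amplicon loci (expected length
    under 300 bp) additionally lose 50 bp from the 5' end as a quality guard,
    and long-amplicon loci are returned untrimmed past the forward primer.
    """
    if not merged.startswith(locus.fwd_primer):
        return None
    rest = merged[len(locus.fwd_primer):]
    rc_rev = revcomp(locus.rev_primer)
    idx = rest.find(rc_rev)
    if idx >= 0:
        return rest[:idx]
    if locus.expected_len < SHORT_AMPLICON_MAX:
        return rest[HEAD_TRIM:]
    return rest


def length_filter(seq: str, min_len: int = MIN_KEEP_LEN) -> bool:
    """Keep only sequences strictly longer than ``min_len``."""
    return len(seq) > min_len


@dataclass
class RoutingResult:
    """Per-locus, per-sample counts of routed amplicon sequences plus tallies."""

    sequences: dict[str, dict[str, Counter]]  # locus -> sample -> Counter(seq -> reads)
    dispositions: Counter = field(default_factory=Counter)
    n_pairs: int = 0

    def summary_frame(self):
        import pandas as pd

        rows = [{"disposition": k, "pairs": v} for k, v in sorted(self.dispositions.items())]
        return pd.DataFrame(rows)


def route_pairs(
    pairs: Iterable[tuple[str, str, str, str]],
    panel: PanelDesign,
    min_overlap: int = MIN_OVERLAP,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
    min_len: int = MIN_KEEP_LEN,
) -> RoutingResult:
    """Route an iterable of (read1, qual1, read2, qual2) pairs.

    Every pair lands in exactly one tally: UNASSIGNED, UNKNOWN locus,
    merged, unmerged-kept, discarded-short, or discarded-unroutable.
    Unmerged pairs continue as read-1-only sequences through the same trim
    and length rules.
    """
    bc_len = panel.barcode_length
    bc2sample = panel.barcode_to_sample()
    primers = {name: loc.fwd_primer for name, loc in panel.loci.items()}
    result = RoutingResult({name: {} for name in panel.loci})
    tally = result.dispositions
    # Processing a pair is a pure function of its sequences/qualities, so
    # identical pairs (the common case at zero/low error rate) are cached.
    cache: dict[tuple, tuple] = {}

    for r1, q1, r2, q2 in pairs:
        result.n_pairs += 1
        sample = assign_sample(r1, bc2sample, bc_len)
        if sample == UNASSIGNED:
            tally[UNASSIGNED] += 1
            continue
        key = (r1[bc_len:], q1[bc_len:], r2, q2)
        hit = cache.get(key)
        if hit is None:
            hit = _process_pair(key[0], key[1], r2, q2, panel, primers,
                                min_overlap, max_mismatch_frac, min_len)
            cache[key] = hit
        locus, disposition, seq = hit
        tally[disposition] += 1
        if seq is not None:
            result.sequences[locus].setdefault(sample, Counter())[seq] += 1
    return result


def _process_pair(r1, q1, r2, q2, panel, primers, min_overlap, max_mismatch_frac, min_len):
    locus_name = identify_locus(r1, primers)
    if locus_name == UNKNOWN:
        return (UNKNOWN, UNKNOWN, None)
    locus = panel.loci[locus_name]
    merged = merge_pairs(r1, r2, q1, q2, min_overlap, max_mismatch_frac)
    disposition = MERGED
    if merged is None:
        merged = r1  # unmerged pairs continue as read-1-only sequences
        disposition = UNMERGED_KEPT
    trimmed = trim_amplicon(merged, locus)
    if trimmed is None:
        return (locus_name, DISCARDED_UNROUTABLE, None)
    if not length_filter(trimmed, min_len):
        return (locus_name, DISCARDED_SHORT, None)
    return (locus_name, disposition, trimmed)


def route_run(
    fastq1: str,
    fastq2: str,
    panel: PanelDesign,
    **kwargs,
) -> RoutingResult:
    """Route a paired FASTQ run (optionally gzipped) through the panel."""
    with _open(fastq1) as fh1, _open(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        pairs = ((s1, q1, s2, q2) for (_, s1, q1), (_, s2, q2) in zip(it1, it2))
        return route_pairs(pairs, panel, **kwargs)


def _open(path: str):
    if str(path).endswith(".gz"):
        import gzip

        return gzip.open(path, "rt")
    return open(path)


def write_fasta_dir(result: RoutingResult, out_dir: str) -> None:
    """One FASTA per locus of routed unique sequences (sample and count in header)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for locus, by_sample in result.sequences.items():
        path = os.path.join(out_dir, f"{locus}.fasta")
        with open(path, "w") as fh:
            for sample in sorted(by_sample):
                for i, (seq, n) in enumerate(sorted(by_sample[sample].items())):
                    fh.write(f">{sample}|u{i + 1}|count={n}\n{seq}\n")
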
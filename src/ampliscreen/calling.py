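"""Per-mosquito biological calls from unique-sequence tables.

Four callers share two primitives: a read-depth floor (1000 reads for the
genotyping and blood-meal loci) and reference matching by end-gap-free global
alignment with a 70% identity floor.

kdr genotyping uses the two most abundant unique sequences per sample, Seq1
and Seq2, and the ratio Seq2/(Seq1+Seq2): near 0 for homozygotes (Seq2 is
then sequencing error), near 0.5 for heterozygotes.  Ratios below 0.15 call a
homozygote (RR when Seq1 matches the resistant L1014F allele, else SS),
ratios above 0.35 a heterozygote, and the band in between is left uncalled.

Species calls come from the S200X6.1 marker, with cox1 as a fallback for
samples S200X6.1 fails to amplify (An. nili); two distinct high-abundance
S200X6.1 alleles mapping to different species flag an F1 hybrid, reusing the
heterozygosity ratio cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner

from .references import KDR_RESISTANT, PARASITE_GROUPS, SPECIES
from .seqtable import UniqueSeqTable

MIN_CALL_READS = 1000
MIN_IDENTITY = 0.70
MIN_QUERY_LEN = 20
RATIO_HOM_MAX = 0.15  # ratio strictly below -> homozygous
RATIO_HET_MIN = 0.35  # ratio strictly above -> heterozygous

NO_CALL = "NO_CALL"


# ---------------------------------------------------------------------------
# Reference matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    name: str
    identity: float  # fraction in [0, 1]


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    a.end_insertion_score = 0  # reference overhang beyond the query is free
    return a


_ALIGNER = _aligner()


def _identity(query: str, reference: str) -> float:
    """Identity = matches / alignment span of the full query (end-gap-free)."""
    aln = _ALIGNER.align(query, reference)[0]
    c = aln.counts()
    span = (
        c.identities
        + c.mismatches
        + c.internal_insertions
        + c.internal_deletions
        + c.left_deletions
        + c.right_deletions
    )
    return c.identities / span if span else 0.0


def match_reference(
    query: str,
    reference_set: Mapping[str, str],
    min_identity: float = MIN_IDENTITY,
) -> list[Hit]:
    """Rank references by global identity to ``query``; hits under the floor
    are suppressed and exact ties at the top are all retained in the output.

    Queries shorter than 20 nt are unalignable and return no hits.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    if len(query) < MIN_QUERY_LEN:
        return []
    hits = [
        Hit(name, _identity(query, ref))
        for name, ref in reference_set.items()
    ]
    hits = [h for h in hits if h.identity >= min_identity]
    hits.sort(key=lambda h: (-h.identity, h.name))
    return hits


def _top_hits(hits: Sequence[Hit], tol: float = 1e-12) -> list[Hit]:
    if not hits:
        return []
    best = hits[0].identity
    return [h for h in hits if best - h.identity <= tol]


# ---------------------------------------------------------------------------
# kdr genotype
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    sample_id: str
    allele1: str | None
    allele2: str | None
    seq1_count: int
    seq2_count: int
    ratio: float
    call: str  # RR | SS | RS | NO_CALL
    total_reads: int
    reason: str = ""


def _top_two(column) -> tuple[str | None, int, str | None, int]:
    """Two most abundant sequences in a sample; count ties break lexicographically."""
    nonzero = column[column > 0]
    if nonzero.empty:
        return None, 0, None, 0
    ordered = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    s1, c1 = ordered[0]
    if len(ordered) == 1:
        return s1, int(c1), None, 0
    s2, c2 = ordered[1]
    return s1, int(c1), s2, int(c2)


def call_kdr(
    table: UniqueSeqTable,
    reference_db: Mapping[str, Mapping[str, str]],
    min_reads: int = MIN_CALL_READS,
) -> dict[str, GenotypeCall]:
    """Genotype every sample in a kdr unique-sequence table.

    The ratio Seq2/(Seq1+Seq2) is 0 when a sample has a single unique
    sequence (the natural limit of the formula).  Samples under the read
    floor, in the ambiguous ratio band, or whose top allele matches no kdr
    reference are NO_CALL with a reason.
    """
    kdr_refs = reference_db["kdr"]
    out: dict[str, GenotypeCall] = {}
    for sample in table.counts.columns:
        col = table.counts[sample]
        total = int(col.sum())
        s1, c1, s2, c2 = _top_two(col)
        ratio = c2 / (c1 + c2) if (c1 + c2) > 0 else 0.0
        if total == 0:
            out[sample] = GenotypeCall(sample, None, None, 0, 0, 0.0, NO_CALL, 0, "no reads")
            continue
        if total < min_reads:
            out[sample] = GenotypeCall(
                sample, s1, s2, c1, c2, ratio, NO_CALL, total, f"depth {total} < {min_reads}"
            )
            continue
        if ratio < RATIO_HOM_MAX:
            hits = _top_hits(match_reference(s1, kdr_refs))
            if not hits:
                call, reason = NO_CALL, "top sequence matches no kdr allele"
            else:
                call = "RR" if hits[0].name == KDR_RESISTANT else "SS"
                reason = ""
            out[sample] = GenotypeCall(sample, s1, None, c1, c2, ratio, call, total, reason)
        elif ratio > RATIO_HET_MIN:
            out[sample] = GenotypeCall(sample, s1, s2, c1, c2, ratio, "RS", total)
        else:
            out[sample] = GenotypeCall(
                sample, s1, s2, c1, c2, ratio, NO_CALL, total,
                f"ambiguous ratio {ratio:.3f} in [{RATIO_HOM_MAX}, {RATIO_HET_MIN}]",
            )
    return out


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

@dataclass
class SpeciesCall:
    sample_id: str
    species: str  # species label, hybrid label, or NO_CALL
    evidence_locus: str | None  # "s200x6" | "cox1" | None
    read_count: int
    hybrid: bool = False
    reason: str = ""


def _hybrid_label(a: str, b: str) -> str:
    order = {sp: i for i, sp in enumerate(SPECIES)}
    first, second = sorted((a, b), key=lambda s: order.get(s, len(order)))
    return f"{first}_x_{second.removeprefix('Anopheles_')}"


def call_species(
    s200_table: UniqueSeqTable,
    cox1_table: UniqueSeqTable,
    reference_db: Mapping[str, Mapping[str, str]],
    min_reads: int = MIN_CALL_READS,
) -> dict[str, SpeciesCall]:
    """Species per sample from S200X6.1, with cox1 rescue when it fails.

    cox1 is consulted only for samples where S200X6.1 yields no call (under
    depth or unmatched) — primarily An. nili, which the S200X6.1 primers do
    not amplify.
    """
    s200_refs = reference_db["s200x6"]
    cox1_refs = reference_db["cox1"]
    samples = sorted(set(s200_table.counts.columns) | set(cox1_table.counts.columns))
    out: dict[str, SpeciesCall] = {}
    for sample in samples:
        call = None
        if sample in s200_table.counts.columns:
            col = s200_table.counts[sample]
            total = int(col.sum())
            if total >= min_reads:
                s1, c1, s2, c2 = _top_two(col)
                ratio = c2 / (c1 + c2) if (c1 + c2) > 0 else 0.0
                top1 = _top_hits(match_reference(s1, s200_refs))
                if top1:
                    sp1 = top1[0].name
                    if ratio > RATIO_HET_MIN and s2 is not None:
                        top2 = _top_hits(match_reference(s2, s200_refs))
                        sp2 = top2[0].name if top2 else None
                        if sp2 is not None and sp2 != sp1:
                            call = SpeciesCall(
                                sample, _hybrid_label(sp1, sp2), "s200x6", total, hybrid=True
                            )
                    if call is None:
                        call = SpeciesCall(sample, sp1, "s200x6", total)
        if call is None and sample in cox1_table.counts.columns:
            col = cox1_table.counts[sample]
            total = int(col.sum())
            if total >= min_reads:
                s1, _, _, _ = _top_two(col)
                if s1 is not None:
                    top = _top_hits(match_reference(s1, cox1_refs))
                    if top:
                        call = SpeciesCall(sample, top[0].name, "cox1", total)
        if call is None:
            call = SpeciesCall(sample, NO_CALL, None, 0, reason="both loci under depth or unmatched")
        out[sample] = call
    return out


# ---------------------------------------------------------------------------
# Blood meal
# ---------------------------------------------------------------------------

@dataclass
class BloodMealProfile:
    sample_id: str
    fed: bool
    hosts: dict[str, int]  # mammal -> reads; empty unless fed
    total_reads: int


def call_blood_meal(
    mammal_table: UniqueSeqTable,
    reference_db: Mapping[str, Mapping[str, str]],
    min_reads: int = MIN_CALL_READS,
) -> dict[str, BloodMealProfile]:
    """Blood-fed status and host composition from the mammalian 16S locus.

    A sample is fed iff its total mammalian reads reach the floor; host
    counts then come from reference-matching each unique sequence (identity
    ties resolved to the alphabetically first host).  Multi-host profiles are
    expected for mixed meals.
    """
    refs_m = reference_db["mammal_16s"]
    out: dict[str, BloodMealProfile] = {}
    for sample in mammal_table.counts.columns:
        col = mammal_table.counts[sample]
        total = int(col.sum())
        if total < min_reads:
            out[sample] = BloodMealProfile(sample, False, {}, total)
            continue
        hosts: dict[str, int] = {}
        for seq, n in col[col > 0].items():
            hits = _top_hits(match_reference(seq, refs_m))
            if hits:
                hosts[hits[0].name] = hosts.get(hits[0].name, 0) + int(n)
        out[sample] = BloodMealProfile(sample, True, hosts, total)
    return out


# ---------------------------------------------------------------------------
# Parasite / virus detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionRecord:
    sample_id: str
    group: str  # taxon group targeted (Apicomplexa, Nematoda, ...)
    species: tuple[str, ...]  # best-hit name(s); ties reported together
    identity: float  # percent identity of the best hit
    reads: int
    is_control: bool = False
    annotation: str = ""


def detect_infections(
    table: UniqueSeqTable,
    reference_db: Mapping[str, Mapping[str, str]],
    control_ids: Iterable[str] = (),
    groups: Mapping[str, str] | None = None,
) -> list[DetectionRecord]:
    """One record per (sample, best-hit set) from the parasite/virus panel.

    Assumes the rare-sequence filter already ran; no additional per-sample
    depth floor is applied.  Control samples are flagged, not excluded.
    """
    refs_p = reference_db["parasite_virus"]
    groups = dict(PARASITE_GROUPS if groups is None else groups)
    controls = set(control_ids)
    agg: dict[tuple[str, tuple[str, ...]], list] = {}
    for sample in table.counts.columns:
        col = table.counts[sample]
        for seq, n in col[col > 0].items():
            hits = _top_hits(match_reference(seq, refs_p))
            if not hits:
                continue
            names = tuple(sorted(h.name for h in hits))
            key = (sample, names)
            rec = agg.setdefault(key, [0, 0.0])
            rec[0] += int(n)
            rec[1] = max(rec[1], hits[0].identity)
    records = []
    for (sample, names), (reads, ident) in sorted(agg.items()):
        records.append(
            DetectionRecord(
                sample_id=sample,
                group=groups.get(names[0], "unknown"),
                species=names,
                identity=round(100.0 * ident, 2),
                reads=reads,
                is_control=sample in controls,
            )
        )
    return records


def flag_contamination(
    records: list[DetectionRecord], ratio_threshold: float = 2.0
) -> list[DetectionRecord]:
    """Annotate weak detections that controls suggest may be contamination.

    A non-control detection is annotated when its read count falls below
    ``ratio_threshold`` times the mean read count of control detections of
    the same best-hit set.  Without control detections nothing is annotated.
    """
    control_reads: dict[tuple[str, ...], list[int]] = {}
    for r in records:
        if r.is_control:
            control_reads.setdefault(r.species, []).append(r.reads)
    means = {k: sum(v) / len(v) for k, v in control_reads.items()}
    out = []
    for r in records:
        annotation = r.annotation
        if not r.is_control and r.species in means and r.reads < ratio_threshold * means[r.species]:
            annotation = "possible contamination"
        out.append(
            DetectionRecord(
                r.sample_id, r.group, r.species, r.identity, r.reads, r.is_control, annotation
            )
        )
    return out
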
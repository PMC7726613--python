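"""Panel design: loci, primers, sample barcodes and the per-locus reference set.

A :class:`PanelDesign` is the static description of a multiplexed run — which
loci are amplified, with which primers, and which barcode identifies each
sample.  Barcodes are matched exactly during demultiplexing, so the only hard
requirement on them is uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from . import references as refs

PRIMER_MIN_LEN = 18
PRIMER_MAX_LEN = 27
BARCODE_LENGTH = 8


@dataclass(frozen=True)
class Locus:
    """One amplified target: primers and the expected amplicon length (bp)."""

    name: str
    fwd_primer: str
    rev_primer: str
    expected_len: int

    def __post_init__(self):
        for p in (self.fwd_primer, self.rev_primer):
            if not (PRIMER_MIN_LEN <= len(p) <= PRIMER_MAX_LEN):
                raise ValueError(
                    f"primer for locus {self.name!r} has length {len(p)}; "
                    f"must be within {PRIMER_MIN_LEN}-{PRIMER_MAX_LEN} nt"
                )
            if set(p) - set("ACGT"):
                raise ValueError(f"primer for locus {self.name!r} contains non-ACGT characters")


@dataclass
class PanelDesign:
    """Loci, per-sample barcodes, and named reference sequences per locus."""

    loci: dict[str, Locus]
    barcodes: dict[str, str]  # sample id -> barcode
    reference_db: dict[str, dict[str, str]]  # locus -> {name -> insert seq}

    def __post_init__(self):
        seen = {}
        for sid, bc in self.barcodes.items():
            if bc in seen:
                raise ValueError(f"duplicate barcode {bc!r} for samples {seen[bc]!r} and {sid!r}")
            seen[bc] = sid
        lengths = {len(bc) for bc in self.barcodes.values()}
        if len(lengths) > 1:
            raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.barcodes)

    def barcode_to_sample(self) -> dict[str, str]:
        return {bc: sid for sid, bc in self.barcodes.items()}


def generate_barcodes(
    count: int, length: int = BARCODE_LENGTH, seed: int = 0, max_tries: int = 10_000_000
) -> list[str]:
    """Draw ``count`` unique random barcodes of ``length`` nt, deterministically.

    Raises ``ValueError`` when the requested count cannot be satisfied (the
    4^length alphabet is exhausted).
    """
    if count < 1:
        raise ValueError("barcode count must be >= 1")
    if count > 4 ** length:
        raise ValueError(f"cannot draw {count} unique barcodes of length {length}: alphabet exhausted")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    tries = 0
    while len(out) < count:
        bc = refs.random_seq(rng, length)
        tries += 1
        if tries > max_tries:
            raise ValueError("barcode generation exhausted the alphabet")
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def build_panel(
    reference_fasta_paths: Mapping[str, str] | None = None,
    barcode_count: int = 96,
    sample_ids: Sequence[str] | None = None,
    seed: int = 0,
    barcode_length: int = BARCODE_LENGTH,
) -> PanelDesign:
    """Assemble a :class:`PanelDesign` for the six-locus screening panel.

    ``reference_fasta_paths`` maps locus name to a FASTA of reference inserts;
    when omitted the packaged synthetic reference database is used.  Samples
    are named ``S001``... unless ``sample_ids`` is given, in which case
    ``barcode_count`` is ignored.
    """
    if reference_fasta_paths is None:
        db = {locus: dict(seqs) for locus, seqs in refs.reference_db().items()}
    else:
        db = {}
        for locus, path in reference_fasta_paths.items():
            records = {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
            if not records:
                raise ValueError(f"reference FASTA for locus {locus!r} is empty: {path}")
            db[locus] = records
    loci = {
        name: Locus(name, fwd, rev, refs.EXPECTED_AMPLICON_LEN.get(name, 250))
        for name, (fwd, rev) in refs.PRIMERS.items()
        if name in db
    }
    missing = set(db) - set(loci)
    if missing:
        raise ValueError(f"no primer definition for loci: {sorted(missing)}")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(barcode_count)]
    codes = generate_barcodes(len(sample_ids), length=barcode_length, seed=seed)
    barcodes = dict(zip(sample_ids, codes))
    return PanelDesign(loci=loci, barcodes=barcodes, reference_db=db)


def default_panel(sample_ids: Iterable[str], seed: int = 0) -> PanelDesign:
    """Panel over the packaged synthetic references for the given samples."""
    return build_panel(sample_ids=list(sample_ids), seed=seed)


def write_barcode_table(panel: PanelDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\n")
        for sid, bc in panel.barcodes.items():
            fh.write(f"{sid}\t{bc}\n")


def write_primer_table(panel: PanelDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tfwd_primer\trev_primer\texpected_len\n")
        for locus in panel.loci.values():
            fh.write(f"{locus.name}\t{locus.fwd_primer}\t{locus.rev_primer}\t{locus.expected_len}\n")
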
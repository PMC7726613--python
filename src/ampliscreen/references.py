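"""Synthetic marker reference database for the six-locus mosquito screening panel.

Every sequence here is generated deterministically from a fixed seed and is
*synthetic*: the sequences stand in for the marker regions the assay targets
(bacterial 16S V2, the S200X6.1 and cox1 species markers, the voltage-gated
sodium-channel fragment spanning the kdr L1014 codon, mammalian mitochondrial
16S, and the parasite 18S / flavivirus NS5 panel) but share no bases with any
real organism.  They are built so that the *relationships* the callers rely on
hold: each species or host has a well-separated reference, the two kdr alleles
differ at a single site, and the Anopheles nili S200X6.1 marker is absent
(that species does not amplify at S200X6.1 and is rescued via cox1).
"""

from __future__ import annotations

import functools

import numpy as np

_REF_SEED = 20160811  # fixed: the reference database is a constant of the package

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Locus names used throughout the package.
BACTERIA_16S = "bacteria_16s"
S200X6 = "s200x6"
COX1 = "cox1"
KDR = "kdr"
MAMMAL_16S = "mammal_16s"
PARASITE_VIRUS = "parasite_virus"

LOCUS_NAMES = (BACTERIA_16S, S200X6, COX1, KDR, MAMMAL_16S, PARASITE_VIRUS)

# Forward/reverse primers, 18-27 nt. Synthetic but length-realistic; no primer
# is a prefix of another, so locus identification is unambiguous.
PRIMERS = {
    BACTERIA_16S: ("AGTGGCGGACGGGTGAGTAA", "CTGCTGCCTCCCGTAGGAGT"),
    S200X6: ("TCGCCTTAGACCGATGAACCTT", "GTTCATCGGAACTTGGTCAGCA"),
    COX1: ("GGATTTGGAAATTGATTAGTTCCTT", "AAACTTCTGGGTGTCCAAAGAATCA"),
    KDR: ("CATTTTTCTTGGCCACTGTAGT", "GGAACTTCACGACACTGATTC"),
    MAMMAL_16S: ("CGGTTGGGGTGACCTCGGA", "GCTGTTATCCCTAGGGTAACT"),
    PARASITE_VIRUS: ("GTGCCAGCAGCCGCGGTAATTCC", "TGGCAAATGCTTTCGCAGTAG"),
}

# Expected amplicon lengths (bp, primers included); drives the 50-bp 5' trim
# rule for unmerged reads from short-amplicon loci.
EXPECTED_AMPLICON_LEN = {
    BACTERIA_16S: 270,
    S200X6: 225,
    COX1 : 250,
    KDR: 205,
    MAMMAL_16S: 180,
    PARASITE_VIRUS: 245,
}

SPECIES = (
    "Anopheles_gambiae",
    "Anopheles_coluzzii",
    "Anopheles_melas",
    "Anopheles_arabiensis",
    "Anopheles_nili",
)
HYBRID = "Anopheles_gambiae_x_coluzzii"

MAMMALS = ("Homo_sapiens", "Bos_taurus", "Ovis_aries", "Capra_hircus", "Canis_lupus")

KDR_RESISTANT = "kdr_L1014F"
KDR_SENSITIVE = "kdr_L1014L"

# Parasite / virus panel members and the taxon group each primer-set targets.
PARASITE_GROUPS = {
    "Plasmodium_falciparum": "Apicomplexa",
    "Theileria_sp": "Apicomplexa",
    "Loa_loa": "Nematoda",
    "Setaria_labiatopapillosa": "Nematoda",
    "Parathelohania_anopheles": "Microsporidia",
    "Microsporidium_sp": "Microsporidia",
    "Anopheles_flavivirus_1": "Flavivirus",
    "Anopheles_flavivirus_2": "Flavivirus",
}

_PHYLA = (
    ("Proteobacteria", 18),
    ("Firmicutes", 10),
    ("Actinobacteria", 6),
    ("Bacteroidetes", 3),
    ("Spirochaetes", 2),
    ("Tenericutes", 1),
)
_GENERA = {
    "Proteobacteria": ("Pseudomonas", "Serratia", "Acinetobacter", "Enterobacter"),
    "Firmicutes": ("Bacillus", "Staphylococcus", "Enterococcus"),
    "Actinobacteria": ("Corynebacterium", "Micrococcus"),
    "Bacteroidetes": ("Chryseobacterium", "Flavobacterium"),
    "Spirochaetes": ("Spirochaeta",),
    "Tenericutes": ("Spiroplasma",),
}


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Return ``seq`` with ``n_subs`` substitutions at distinct positions."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        alternatives = BASES[BASES != arr[p]]
        arr[p] = rng.choice(alternatives)
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")


@functools.lru_cache(maxsize=1)
def reference_db() -> dict[str, dict[str, str]]:
    """Map locus -> {reference name -> insert sequence (between primers)}.

    Deterministic: repeated calls return the identical database.
    """
    rng = np.random.default_rng(_REF_SEED)
    db: dict[str, dict[str, str]] = {}

    # S200X6.1: one well-separated allele per species, none for An. nili.
    db[S200X6] = {
        sp: random_seq(rng, 182) for sp in SPECIES if sp != "Anopheles_nili"
    }

    # cox1: closely related haplotypes (a shared backbone with a handful of
    # substitutions), mimicking the marker's shallow divergence; An. nili is
    # the most distinct.
    cox1_base = random_seq(rng, 205)
    db[COX1] = {
        "Anopheles_gambiae": cox1_base,
        "Anopheles_coluzzii": mutate(rng, cox1_base, 3),
        "Anopheles_melas": mutate(rng, cox1_base, 5),
        "Anopheles_arabiensis": mutate(rng, cox1_base, 4),
        "Anopheles_nili": mutate(rng, cox1_base, 20),
    }

    # kdr: sensitive and resistant alleles differ at one site (the L1014F
    # codon position).
    sensitive = random_seq(rng, 162)
    pos = 81
    resistant = sensitive[:pos] + ("T" if sensitive[pos] != "T" else "A") + sensitive[pos + 1:]
    db[KDR] = {KDR_SENSITIVE: sensitive, KDR_RESISTANT: resistant}

    db[MAMMAL_16S] = {m: random_seq(rng, 140) for m in MAMMALS}

    db[PARASITE_VIRUS] = {p: random_seq(rng, 200) for p in PARASITE_GROUPS}

    db[BACTERIA_16S] = {f"ASV{i + 1:03d}": random_seq(rng, 230) for i in range(sum(n for _, n in _PHYLA))}
    return db


@functools.lru_cache(maxsize=1)
def taxonomy_16s() -> dict[str, str]:
    """Semicolon-delimited taxonomy (kingdom;phylum;genus) per 16S reference."""
    rng = np.random.default_rng(_REF_SEED + 1)
    tax = {}
    asvs = sorted(reference_db()[BACTERIA_16S])
    i = 0
    for phylum, n in _PHYLA:
        genera = _GENERA[phylum]
        for _ in range(n):
            genus = genera[rng.integers(len(genera))]
            tax[asvs[i]] = f"Bacteria;{phylum};{genus}"
            i += 1
    return tax


@functools.lru_cache(maxsize=1)
def tree_16s_newick() -> str:
    """Random binary tree over the 16S references, as a newick string.

    Built by successive random joins with exponential branch lengths; leaves
    are the ASV reference names.
    """
    rng = np.random.default_rng(_REF_SEED + 2)
    nodes = sorted(reference_db()[BACTERIA_16S])
    lengths = {n: float(rng.exponential(0.08)) for n in nodes}
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        joined = f"({a}:{lengths.pop(a):.6f},{b}:{lengths.pop(b):.6f})"
        lengths[joined] = float(rng.exponential(0.08))
        nodes.append(joined)
    return nodes[0] + ";"


def write_reference_fastas(out_dir) -> dict[str, str]:
    """Write one FASTA per locus (plus the 16S tree) under ``out_dir``.

    Returns locus -> path. 16S headers carry the taxonomy string after the id.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    tax = taxonomy_16s()
    paths = {}
    for locus, refs in reference_db().items():
        path = os.path.join(out_dir, f"{locus}.fasta")
        with open(path, "w") as fh:
            for name in sorted(refs):
                header = name if locus != BACTERIA_16S else f"{name} {tax[name]}"
                fh.write(f">{header}\n{refs[name]}\n")
        paths[locus] = path
    tree_path = os.path.join(out_dir, "bacteria_16s_tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(tree_16s_newick() + "\n")
    paths["tree"] = tree_path
    return paths
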
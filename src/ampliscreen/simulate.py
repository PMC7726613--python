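"""Synthetic multiplexed amplicon runs with known per-mosquito ground truth.

The generator emulates the structure of a pooled field study: individual
wild-caught mosquitoes from several collection sites, each amplified at six
loci (bacterial 16S, S200X6.1, cox1, kdr, mammalian 16S, and a parasite/virus
panel), pooled with per-sample barcodes, and sequenced paired-end.  Extraction
controls carry no template of their own and receive reads only through a
configurable cross-contamination leak.

Ground truth per mosquito: collection site, species (five Anopheles species
plus F1 gambiae x coluzzii hybrids), kdr L1014F genotype (RR/SS/RS),
blood-meal host mixture, infection set, and a site-structured bacterial
community composition.  The between-site share of community variance is
planted via a calibrated spread of site centroids, so distance-based variance
partitions downstream have a known expected answer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import references as refs
from .panel import PanelDesign
from .references import (
    BACTERIA_16S,
    COX1,
    HYBRID,
    KDR,
    KDR_RESISTANT,
    KDR_SENSITIVE,
    MAMMAL_16S,
    PARASITE_VIRUS,
    S200X6,
    revcomp,
)

# ---------------------------------------------------------------------------
# Cohort ground truth
# ---------------------------------------------------------------------------

# Species frequencies follow the field proportions the assay was built around
# (An. gambiae dominant; rare arabiensis/nili; occasional F1 hybrid).
SPECIES_FREQS = {
    "Anopheles_gambiae": 0.745,
    "Anopheles_coluzzii": 0.108,
    "Anopheles_melas": 0.105,
    "Anopheles_arabiensis": 0.015,
    "Anopheles_nili": 0.013,
    HYBRID: 0.014,
}

# kdr genotype frequencies conditional on species: resistance alleles nearly
# fixed in An. gambiae, essentially absent in melas/arabiensis, mixed in
# coluzzii — mirroring the strong species-genotype correlation seen in West
# African populations.
KDR_FREQS = {
    "Anopheles_gambiae": {"RR": 0.90, "RS": 0.07, "SS": 0.03},
    "Anopheles_coluzzii": {"RR": 0.35, "RS": 0.30, "SS": 0.35},
    "Anopheles_melas": {"RR": 0.01, "RS": 0.04, "SS": 0.95},
    "Anopheles_arabiensis": {"RR": 0.01, "RS": 0.04, "SS": 0.95},
    "Anopheles_nili": {"RR": 0.02, "RS": 0.08, "SS": 0.90},
    HYBRID: {"RR": 0.30, "RS": 0.50, "SS": 0.20},
}

FED_PROB = 0.20  # ~1 in 5 mosquitoes carries a recent mammalian blood meal
BLOOD_MEAL_MIXTURES = (
    ({"Homo_sapiens": 1.0}, 0.78),
    ({"Bos_taurus": 1.0}, 0.09),
    ({"Homo_sapiens": 0.7, "Bos_taurus": 0.3}, 0.06),
    ({"Ovis_aries": 1.0}, 0.03),
    ({"Homo_sapiens": 0.6, "Ovis_aries": 0.4}, 0.04),
)

INFECTED_PROB = 0.19
INFECTION_WEIGHTS = {
    "Plasmodium_falciparum": 0.08,
    "Theileria_sp": 0.22,
    "Loa_loa": 0.07,
    "Setaria_labiatopapillosa": 0.10,
    "Parathelohania_anopheles": 0.27,
    "Microsporidium_sp": 0.20,
    "Anopheles_flavivirus_1": 0.03,
    "Anopheles_flavivirus_2": 0.03,
}
TWO_INFECTIONS_PROB = 0.2

N_ASVS_DEFAULT = 40
WITHIN_SITE_CONCENTRATION = 30.0  # Dirichlet concentration of samples around site centroids
_BASE_LOGNORMAL_SIGMA = 1.5

# Calibration of the planted between-site effect: site centroids are the base
# community perturbed by iid lognormal noise with scale sigma_b; this table
# maps sigma_b to the mean location R^2 a sequential Bray-Curtis PERMANOVA
# recovers at reference conditions (n=120, 6 sites, 40 ASVs, depth 5000,
# within-site concentration 30).  Values were computed by Monte-Carlo with
# scripts/calibrate_effect.py and frozen here; requested effect sizes are
# inverse-interpolated on this grid.
_EFFECT_CALIBRATION: list[tuple[float, float]] = [
    (0.0, 0.0431),
    (0.2, 0.0970),
    (0.4, 0.2291),
    (0.6, 0.3787),
    (0.8, 0.5057),
    (1.0, 0.6131),
    (1.2, 0.6910),
    (1.5, 0.7774),
    (2.0, 0.8573),
    (2.5, 0.9025),
]


def centroid_spread_for_effect(site_effect_size: float) -> float:
    """Centroid log-spread sigma_b whose expected location R^2 matches the target."""
    if not 0.0 <= site_effect_size < 1.0:
        raise ValueError("site_effect_size must be in [0, 1)")
    sigmas = np.array([s for s, _ in _EFFECT_CALIBRATION])
    r2s = np.array([r for _, r in _EFFECT_CALIBRATION])
    if site_effect_size > r2s[-1]:
        raise ValueError(
            f"site_effect_size {site_effect_size} exceeds the calibrated range (max {r2s[-1]:.2f})"
        )
    if site_effect_size <= r2s[0]:
        # Effects at or below the null expectation are indistinguishable from 0.
        return 0.0 if site_effect_size == 0.0 else float(np.interp(site_effect_size, r2s, sigmas))
    return float(np.interp(site_effect_size, r2s, sigmas))


@dataclass
class SampleTruth:
    """Ground truth for one sample (mosquito or extraction control)."""

    sample_id: str
    site: str
    species: str | None
    kdr_genotype: str | None
    blood_meal: dict[str, float]  # mammal -> template proportion; empty = unfed
    infections: tuple[str, ...]
    community: dict[str, float]  # ASV id -> relative abundance; empty for controls
    is_control: bool = False


@dataclass
class CohortTruth:
    """A simulated cohort: per-sample truth plus the planted site structure."""

    samples: list[SampleTruth]
    sites: list[str]
    asv_ids: list[str]
    site_effect_size: float
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def mosquitoes(self) -> list[SampleTruth]:
        return [s for s in self.samples if not s.is_control]

    def controls(self) -> list[SampleTruth]:
        return [s for s in self.samples if s.is_control]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "site": s.site,
                    "species": s.species or "",
                    "kdr_genotype": s.kdr_genotype or "",
                    "blood_meal": ",".join(f"{m}:{p:g}" for m, p in sorted(s.blood_meal.items())),
                    "infections": ";".join(s.infections),
                    "is_control": int(s.is_control),
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")


def _choice(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def simulate_cohort(
    n_samples: int,
    n_sites: int = 6,
    site_effect_size: float = 0.2,
    n_controls: int = 0,
    seed: int = 0,
    n_asvs: int = N_ASVS_DEFAULT,
    within_site_concentration: float = WITHIN_SITE_CONCENTRATION,
    centroid_spread: float | None = None,
) -> CohortTruth:
    """Draw a cohort of mosquitoes (plus controls) with planted site structure.

    Site centroid communities are the shared base composition perturbed on the
    log scale by ``sigma_b`` (looked up from ``site_effect_size`` via the
    frozen calibration); per-sample compositions are Dirichlet around the
    centroid.  ``site_effect_size = 0`` makes samples exchangeable across
    sites.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if n_samples < n_sites:
        raise ValueError(f"n_samples ({n_samples}) must be >= n_sites ({n_sites})")
    # centroid_spread overrides the calibrated lookup (used by the calibration
    # script itself and for custom effect models)
    sigma_b = (
        centroid_spread if centroid_spread is not None
        else centroid_spread_for_effect(site_effect_size)
    )
    rng = np.random.default_rng(seed)

    all_asvs = sorted(refs.reference_db()[BACTERIA_16S])
    if n_asvs > len(all_asvs):
        raise ValueError(f"n_asvs {n_asvs} exceeds the reference database ({len(all_asvs)} ASVs)")
    asv_ids = all_asvs[:n_asvs]
    base = rng.lognormal(0.0, _BASE_LOGNORMAL_SIGMA, size=n_asvs)
    base /= base.sum()

    sites = [f"Site{i + 1:02d}" for i in range(n_sites)]
    centroids = {}
    for site in sites:
        m = base * np.exp(sigma_b * rng.standard_normal(n_asvs))
        centroids[site] = m / m.sum()

    samples: list[SampleTruth] = []
    for i in range(n_samples):
        sid = f"M{i + 1:04d}"
        site = sites[i % n_sites]
        species = _choice(rng, SPECIES_FREQS)
        kdr = _choice(rng, KDR_FREQS[species])
        blood_meal: dict[str, float] = {}
        if rng.random() < FED_PROB:
            mixtures, weights = zip(*BLOOD_MEAL_MIXTURES)
            blood_meal = dict(mixtures[rng.choice(len(mixtures), p=np.array(weights) / sum(weights))])
        infections: tuple[str, ...] = ()
        if rng.random() < INFECTED_PROB:
            k = 2 if rng.random() < TWO_INFECTIONS_PROB else 1
            names = list(INFECTION_WEIGHTS)
            p = np.array([INFECTION_WEIGHTS[n] for n in names])
            picks = rng.choice(len(names), size=k, replace=False, p=p / p.sum())
            infections = tuple(sorted(names[j] for j in picks))
        comp = rng.dirichlet(within_site_concentration * centroids[site])
        community = {a: float(c) for a, c in zip(asv_ids, comp)}
        samples.append(SampleTruth(sid, site, species, kdr, blood_meal, infections, community))

    for i in range(n_controls):
        sid = f"CTL{i + 1:03d}"
        samples.append(SampleTruth(sid, "control", None, None, {}, (), {}, is_control=True))

    return CohortTruth(samples, sites, asv_ids, site_effect_size, seed)


def community_counts(truth: CohortTruth, depth: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Multinomial ASV read counts (ASV x sample) for the cohort's mosquitoes.

    A direct route from truth compositions to a count table, bypassing read
    simulation; used for community-statistics studies where the sequencing
    layer is not under test.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for s in truth.mosquitoes():
        p = np.array([s.community[a] for a in truth.asv_ids])
        cols[s.sample_id] = rng.multinomial(depth, p)
    return pd.DataFrame(cols, index=truth.asv_ids)


def metadata_frame(truth: CohortTruth) -> pd.DataFrame:
    """Per-mosquito factor table (site, species, kdr, fed, infected) from truth."""
    rows = {}
    for s in truth.mosquitoes():
        rows[s.sample_id] = {
            "location": s.site,
            "species": s.species,
            "kdr_genotype": s.kdr_genotype,
            "blood_meal": "fed" if s.blood_meal else "unfed",
            "infection": "infected" if s.infections else "uninfected",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

# Default per-locus mean depths follow the study-scale averages the assay
# reports (16S dominating the pool; ~1-3k reads for the genotyping loci).
DEFAULT_DEPTH_MEANS = {
    BACTERIA_16S: 11730,
    S200X6: 2917,
    COX1: 1181,
    KDR: 2436,
    MAMMAL_16S: 2500,
    PARASITE_VIRUS: 1876,
}


@dataclass
class RunConfig:
    """Sequencing-layer knobs for one simulated run."""

    depth_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DEPTH_MEANS))
    depth_shape: float = 10.0  # negative-binomial shape; larger = closer to Poisson
    error_rate: float = 0.0  # per-base substitution probability
    read_length: int = 200
    contamination_rate: float = 0.0  # fraction of each sample's reads leaked into controls
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if any(m < 0 for m in self.depth_means.values()):
            raise ValueError("depth means must be non-negative")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")


def _templates_for(sample: SampleTruth, locus: str, db) -> tuple[list[str], np.ndarray]:
    """Reference template names and proportions amplified at ``locus``."""
    if locus == BACTERIA_16S:
        names = sorted(sample.community)
        p = np.array([sample.community[n] for n in names])
    elif locus == S200X6:
        if sample.species is None or sample.species == "Anopheles_nili":
            return [], np.array([])  # S200X6.1 does not amplify An. nili
        if sample.species == HYBRID:
            names = ["Anopheles_gambiae", "Anopheles_coluzzii"]
            p = np.array([0.5, 0.5])
        else:
            names, p = [sample.species], np.array([1.0])
    elif locus == COX1:
        if sample.species is None:
            return [], np.array([])
        # F1 hybrids carry the maternal (gambiae) mitochondrial haplotype.
        sp = "Anopheles_gambiae" if sample.species == HYBRID else sample.species
        names, p = [sp], np.array([1.0])
    elif locus == KDR:
        if sample.kdr_genotype is None:
            return [], np.array([])
        if sample.kdr_genotype == "RR":
            names, p = [KDR_RESISTANT], np.array([1.0])
        elif sample.kdr_genotype == "SS":
            names, p = [KDR_SENSITIVE], np.array([1.0])
        else:  # heterozygote: 50/50 template mix
            names, p = [KDR_RESISTANT, KDR_SENSITIVE], np.array([0.5, 0.5])
    elif locus == MAMMAL_16S:
        if not sample.blood_meal:
            return [], np.array([])
        names = sorted(sample.blood_meal)
        p = np.array([sample.blood_meal[n] for n in names])
    elif locus == PARASITE_VIRUS:
        if not sample.infections:
            return [], np.array([])
        names = list(sample.infections)
        p = np.full(len(names), 1.0 / len(names))
    else:
        raise KeyError(f"unknown locus {locus!r}")
    return names, p / p.sum()


def _apply_errors(rng: np.random.Generator, seq: str, n_copies: int, rate: float) -> list[str]:
    """``n_copies`` reads of ``seq`` with iid per-base substitutions."""
    if rate == 0.0 or n_copies == 0:
        return [seq] * n_copies
    L = len(seq)
    n_err = rng.binomial(L, rate, size=n_copies)
    out = []
    arr0 = np.frombuffer(seq.encode(), dtype="S1")
    for k in n_err:
        if k == 0:
            out.append(seq)
            continue
        arr = arr0.copy()
        pos = rng.choice(L, size=k, replace=False)
        for pp in pos:
            alternatives = refs.BASES[refs.BASES != arr[pp]]
            arr[pp] = alternatives[rng.integers(3)]
        out.append(arr.tobytes().decode())
    return out


def emit_run(
    truth: CohortTruth,
    panel: PanelDesign,
    config: RunConfig,
    out_dir: str,
    prefix: str = "run",
) -> dict[str, str]:
    """Write the paired FASTQ files and truth tables for one simulated run.

    Each read pair is ``barcode + fwd primer + insert + revcomp(rev primer)``
    read from both ends at the configured read length.  Extraction controls
    receive only reads leaked from mosquito samples at ``contamination_rate``.
    Byte-identical output for identical (truth, panel, config).

    Returns a manifest of written paths.
    """
    missing = set(truth.sample_ids) - set(panel.barcodes)
    if missing:
        raise ValueError(f"samples missing from panel barcodes: {sorted(missing)[:5]}...")
    L = config.read_length
    max_primer = max(len(l.fwd_primer) for l in panel.loci.values())
    if L <= panel.barcode_length + max_primer:
        raise ValueError(
            f"read_length {L} must exceed barcode+primer length "
            f"({panel.barcode_length}+{max_primer})"
        )

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    control_ids = [s.sample_id for s in truth.controls()]
    loci = [name for name in refs.LOCUS_NAMES if name in panel.loci]

    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    pair_no = 0
    qual = "I" * L

    def write_reads(sample_id: str, locus_name: str, insert_name: str, n: int):
        nonlocal pair_no
        locus = panel.loci[locus_name]
        insert = panel.reference_db[locus_name][insert_name]
        template = (
            panel.barcodes[sample_id] + locus.fwd_primer + insert + revcomp(locus.rev_primer)
        )
        r1 = template[:L]
        r2 = revcomp(template)[:L]
        seqs1 = _apply_errors(rng, r1, n, config.error_rate)
        seqs2 = _apply_errors(rng, r2, n, config.error_rate)
        for s1, s2 in zip(seqs1, seqs2):
            pair_no += 1
            pid = f"P{pair_no:09d}"
            r1_chunks.append(f"@{pid}/1\n{s1}\n+\n{qual[:len(s1)]}\n")
            r2_chunks.append(f"@{pid}/2\n{s2}\n+\n{qual[:len(s2)]}\n")

    for sample in truth.mosquitoes():
        for locus_name in loci:
            mean = config.depth_means.get(locus_name, 0.0)
            names, p = _templates_for(sample, locus_name, panel.reference_db)
            if mean <= 0 or not names:
                continue
            shape = config.depth_shape
            depth = int(rng.negative_binomial(shape, shape / (shape + mean)))
            if depth == 0:
                continue
            counts = rng.multinomial(depth, p)
            for name, n in zip(names, counts):
                if n == 0:
                    continue
                n_leak = 0
                if control_ids and config.contamination_rate > 0:
                    n_leak = int(rng.binomial(n, config.contamination_rate))
                write_reads(sample.sample_id, locus_name, name, int(n - n_leak))
                if n_leak:
                    # index mis-assignment: leaked reads carry a control barcode
                    dest = control_ids[rng.integers(len(control_ids))]
                    write_reads(dest, locus_name, name, n_leak)

    paths = {
        "r1": os.path.join(out_dir, f"{prefix}_R1.fastq"),
        "r2": os.path.join(out_dir, f"{prefix}_R2.fastq"),
        "samples": os.path.join(out_dir, f"{prefix}_truth_samples.tsv"),
        "community": os.path.join(out_dir, f"{prefix}_truth_community.tsv"),
        "manifest": os.path.join(out_dir, f"{prefix}_manifest.json"),
    }
    with open(paths["r1"], "w") as fh:
        fh.write("".join(r1_chunks))
    with open(paths["r2"], "w") as fh:
        fh.write("".join(r2_chunks))
    truth.to_frame().to_csv(paths["samples"], sep="\t")
    comm = pd.DataFrame(
        {s.sample_id: [s.community.get(a, 0.0) for a in truth.asv_ids] for s in truth.mosquitoes()},
        index=pd.Index(truth.asv_ids, name="asv"),
    )
    comm.to_csv(paths["community"], sep="\t")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "n_samples": len(truth.mosquitoes()),
                "n_controls": len(truth.controls()),
                "controls": control_ids,
                "n_pairs": pair_no,
                "seed": config.seed,
                "read_length": L,
                "error_rate": config.error_rate,
                "contamination_rate": config.contamination_rate,
                "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest"},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
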
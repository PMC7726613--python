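"""End-to-end orchestration: routed reads -> tables -> calls -> community stats.

``run_pipeline`` drives one multiplexed run through every stage and writes
per-stage TSV outputs plus a consolidated JSON summary.  ``evaluate_concordance``
scores pipeline calls against a simulated cohort's ground truth and backs the
package's end-to-end validation: with a noise-free run every call must match.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calling, community, demux, references as refs, seqtable
from .permanova import N_PERM_DEFAULT, PermanovaResult, permanova
from .panel import PanelDesign
from .simulate import CohortTruth

FACTOR_ORDER = ("location", "species", "kdr_genotype", "blood_meal", "infection")


@dataclass
class PipelineConfig:
    """Paths, thresholds and statistical settings for one pipeline run."""

    fastq1: str
    fastq2: str
    output_dir: str
    metadata_path: str | None = None  # TSV with sample_id, site (collection metadata)
    min_overlap: int = demux.MIN_OVERLAP
    max_mismatch_frac: float = demux.MAX_MISMATCH_FRAC
    min_len: int = demux.MIN_KEEP_LEN
    min_global_count: int = seqtable.MIN_GLOBAL_COUNT
    community_depth: int = community.MIN_COMMUNITY_DEPTH
    call_depth: int = calling.MIN_CALL_READS
    factor_order: tuple[str, ...] = FACTOR_ORDER
    n_perm: int = N_PERM_DEFAULT
    seed: int = 0
    contamination_ratio: float = 2.0

    def validate(self) -> None:
        for path in (self.fastq1, self.fastq2, self.metadata_path):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)
        for name in ("min_global_count", "community_depth", "call_depth", "min_overlap", "min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.max_mismatch_frac <= 1:
            raise ValueError("max_mismatch_frac must be in [0, 1]")


@dataclass
class PipelineResult:
    routing: demux.RoutingResult
    tables: dict[str, seqtable.UniqueSeqTable]  # after rare-sequence filter
    genotypes: dict[str, calling.GenotypeCall]
    species: dict[str, calling.SpeciesCall]
    blood_meals: dict[str, calling.BloodMealProfile]
    detections: list[calling.DetectionRecord]
    asv_table: community.AbundanceTable | None
    permanova: PermanovaResult | None
    summary: dict


def _empty_table(locus: str) -> seqtable.UniqueSeqTable:
    return seqtable.UniqueSeqTable(locus, pd.DataFrame())


def call_stage(
    tables: dict[str, seqtable.UniqueSeqTable],
    panel: PanelDesign,
    control_ids=(),
    call_depth: int = calling.MIN_CALL_READS,
    contamination_ratio: float = 2.0,
):
    """Run the four callers on rare-filtered tables."""
    db = panel.reference_db
    kdr_t = tables.get(refs.KDR, _empty_table(refs.KDR))
    genotypes = calling.call_kdr(kdr_t, db, min_reads=call_depth) if len(kdr_t.counts.columns) else {}
    species = calling.call_species(
        tables.get(refs.S200X6, _empty_table(refs.S200X6)),
        tables.get(refs.COX1, _empty_table(refs.COX1)),
        db,
        min_reads=call_depth,
    )
    blood = calling.call_blood_meal(
        tables.get(refs.MAMMAL_16S, _empty_table(refs.MAMMAL_16S)), db, min_reads=call_depth
    )
    detections = calling.detect_infections(
        tables.get(refs.PARASITE_VIRUS, _empty_table(refs.PARASITE_VIRUS)), db, control_ids
    )
    detections = calling.flag_contamination(detections, contamination_ratio)
    return genotypes, species, blood, detections


def run_pipeline(
    config: PipelineConfig,
    panel: PanelDesign,
    control_ids=(),
    tree: str | None = None,
) -> PipelineResult:
    """Route, tabulate, call, and (when feasible) run the community statistics.

    The community stage needs collection metadata (a site per sample); the
    biological factors for the variance partition come from the pipeline's
    own calls, and samples with any uncalled factor are dropped from the
    PERMANOVA.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)

    routing = demux.route_run(
        config.fastq1,
        config.fastq2,
        panel,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        min_len=config.min_len,
    )

    tables = {}
    for locus, by_sample in routing.sequences.items():
        t = seqtable.dereplicate(by_sample, locus)
        tables[locus] = seqtable.filter_rare(t, config.min_global_count)

    genotypes, species, blood, detections = call_stage(
        tables, panel, control_ids, config.call_depth, config.contamination_ratio
    )

    asv_table = None
    pr = None
    sites = None
    if config.metadata_path is not None:
        sites = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
    if sites is not None and refs.BACTERIA_16S in tables and len(tables[refs.BACTERIA_16S].counts):
        t16 = tables[refs.BACTERIA_16S]
        mosquito_cols = [c for c in t16.counts.columns if c not in set(control_ids)]
        t16 = seqtable.UniqueSeqTable(refs.BACTERIA_16S, t16.counts[mosquito_cols])
        factors = _factor_frame(t16.counts.columns, sites, genotypes, species, blood, detections)
        complete = factors.dropna()
        taxonomy = _taxonomy_by_sequence(panel)
        try:
            asv_table = community.build_asv_table(
                seqtable.UniqueSeqTable(refs.BACTERIA_16S, t16.counts[list(complete.index.intersection(t16.counts.columns))]),
                complete,
                taxonomy=taxonomy,
                min_depth=config.community_depth,
            )
        except ValueError:
            asv_table = None
        if asv_table is not None and len(asv_table.sample_ids) >= 3:
            dm = community.bray_curtis(asv_table)
            pr = permanova(
                dm,
                asv_table.metadata,
                list(config.factor_order),
                n_perm=config.n_perm,
                seed=config.seed,
            )

    summary = _summarize(routing, tables, genotypes, species, blood, detections, pr)
    result = PipelineResult(routing, tables, genotypes, species, blood, detections, asv_table, pr, summary)
    _write_outputs(result, config, tree)
    return result


def _factor_frame(samples, sites: pd.DataFrame, genotypes, species, blood, detections) -> pd.DataFrame:
    infected = {r.sample_id for r in detections if not r.is_control}
    rows = {}
    for s in samples:
        g = genotypes.get(s)
        sp = species.get(s)
        b = blood.get(s)
        rows[s] = {
            "location": sites["site"].get(s, np.nan) if "site" in sites.columns else np.nan,
            "species": sp.species if sp and sp.species != calling.NO_CALL else np.nan,
            "kdr_genotype": g.call if g and g.call != calling.NO_CALL else np.nan,
            "blood_meal": "fed" if (b and b.fed) else "unfed",
            "infection": "infected" if s in infected else "uninfected",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _taxonomy_by_sequence(panel: PanelDesign) -> pd.Series:
    """Taxonomy keyed by reference *sequence* (tables are sequence-indexed)."""
    tax = refs.taxonomy_16s()
    db16 = panel.reference_db.get(refs.BACTERIA_16S, {})
    return pd.Series({seq: tax.get(name, "") for name, seq in db16.items()})


def _summarize(routing, tables, genotypes, species, blood, detections, pr) -> dict:
    from collections import Counter

    summary = {
        "n_pairs": routing.n_pairs,
        "dispositions": dict(sorted(routing.dispositions.items())),
        "tables": {
            locus: {"n_sequences": int(len(t.counts)), "n_samples": int(t.counts.shape[1])}
            for locus, t in sorted(tables.items())
        },
        "kdr_calls": dict(sorted(Counter(g.call for g in genotypes.values()).items())),
        "species_calls": dict(sorted(Counter(s.species for s in species.values()).items())),
        "n_blood_fed": sum(b.fed for b in blood.values()),
        "n_detections": len(detections),
        "n_samples_with_infection": len({r.sample_id for r in detections if not r.is_control}),
    }
    if pr is not None:
        summary["permanova"] = {
            f.name: {"df": f.df, "R2": round(f.r2, 6), "p_value": f.p_value} for f in pr.factors
        }
        summary["permanova"]["Residuals"] = {
            "df": pr.residual_df,
            "R2": round(pr.residual_ss / pr.total_ss, 6),
            "p_value": None,
        }
    return summary


def _write_outputs(result: PipelineResult, config: PipelineConfig, tree: str | None) -> None:
    out = config.output_dir
    result.routing.summary_frame().to_csv(os.path.join(out, "routing_summary.tsv"), sep="\t", index=False)
    for locus, t in result.tables.items():
        seqtable.write_table(t, os.path.join(out, f"table_{locus}.tsv"))
    pd.DataFrame(
        [
            {
                "sample_id": g.sample_id, "seq1_count": g.seq1_count, "seq2_count": g.seq2_count,
                "ratio": round(g.ratio, 6), "call": g.call, "total_reads": g.total_reads,
                "reason": g.reason,
            }
            for g in result.genotypes.values()
        ]
    ).to_csv(os.path.join(out, "genotypes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "species": s.species, "evidence_locus": s.evidence_locus or "",
                "read_count": s.read_count, "hybrid": int(s.hybrid), "reason": s.reason,
            }
            for s in result.species.values()
        ]
    ).to_csv(os.path.join(out, "species.tsv"), sep="\t", index=False)
    rows = []
    for b in result.blood_meals.values():
        if b.hosts:
            for host, n in sorted(b.hosts.items()):
                rows.append({"sample_id": b.sample_id, "fed": int(b.fed), "host": host,
                             "reads": n, "total_reads": b.total_reads})
        else:
            rows.append({"sample_id": b.sample_id, "fed": int(b.fed), "host": "", "reads": 0,
                         "total_reads": b.total_reads})
    pd.DataFrame(rows).to_csv(os.path.join(out, "blood_meal.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id, "group": r.group, "species": "/".join(r.species),
                "identity_pct": r.identity, "reads": r.reads, "is_control": int(r.is_control),
                "annotation": r.annotation,
            }
            for r in result.detections
        ]
    ).to_csv(os.path.join(out, "detections.tsv"), sep="\t", index=False)
    if result.permanova is not None:
        result.permanova.to_frame().to_csv(os.path.join(out, "permanova.tsv"), sep="\t", index=False)
    if result.asv_table is not None and tree is None:
        # ordination on Bray-Curtis for the report bundle
        dm = community.bray_curtis(result.asv_table)
        res = community.pcoa(dm)
        res.coordinates.to_csv(os.path.join(out, "pcoa_coordinates.tsv"), sep="\t")
        with open(os.path.join(out, "pcoa_variance.json"), "w") as fh:
            json.dump([float(x) for x in res.proportion_explained], fh)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# Truth concordance
# ---------------------------------------------------------------------------

def evaluate_concordance(result: PipelineResult, truth: CohortTruth) -> dict:
    """Score pipeline calls against simulated ground truth.

    Accuracy for the genotype and species callers is computed over samples
    the pipeline called (samples under the read-depth floor are counted
    separately as uncallable, not as errors); blood-meal and infection
    recovery compare host/organism sets for every mosquito.
    """
    kdr_match = kdr_called = kdr_uncalled = 0
    for s in truth.mosquitoes():
        g = result.genotypes.get(s.sample_id)
        if g is None or g.call == calling.NO_CALL:
            kdr_uncalled += 1
            continue
        kdr_called += 1
        kdr_match += g.call == s.kdr_genotype

    sp_match = sp_called = sp_uncalled = 0
    for s in truth.mosquitoes():
        c = result.species.get(s.sample_id)
        if c is None or c.species == calling.NO_CALL:
            sp_uncalled += 1
            continue
        sp_called += 1
        sp_match += c.species == s.species

    bm_match = 0
    n_mosq = len(truth.mosquitoes())
    for s in truth.mosquitoes():
        b = result.blood_meals.get(s.sample_id)
        observed = set(b.hosts) if (b and b.fed) else set()
        fed_obs = bool(b.fed) if b else False
        bm_match += (observed == set(s.blood_meal)) and (fed_obs == bool(s.blood_meal))

    detected: dict[str, set] = {}
    for r in result.detections:
        if not r.is_control:
            detected.setdefault(r.sample_id, set()).update(r.species)
    inf_match = sum(detected.get(s.sample_id, set()) == set(s.infections) for s in truth.mosquitoes())

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return {
        "kdr_accuracy_pct": pct(kdr_match, kdr_called),
        "kdr_called": kdr_called,
        "kdr_uncalled": kdr_uncalled,
        "species_accuracy_pct": pct(sp_match, sp_called),
        "species_called": sp_called,
        "species_uncalled": sp_uncalled,
        "blood_meal_accuracy_pct": pct(bm_match, n_mosq),
        "infection_accuracy_pct": pct(inf_match, n_mosq),
        "n_mosquitoes": n_mosq,
    }
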
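# ampliscreen

Multi-locus amplicon screening of individual wild-caught mosquitoes, from
pooled multiplexed paired-end reads to per-mosquito biology, plus the
community statistics that ask *what shapes the mosquito microbiota*.

A single sequencing run multiplexes hundreds of individually barcoded
mosquitoes, each amplified at six loci:

| locus            | question answered                                      |
|------------------|--------------------------------------------------------|
| bacterial 16S    | microbiota composition (ASV table, beta diversity)     |
| *kdr* (L1014F)   | pyrethroid-resistance genotype RR / SS / RS            |
| S200X6.1         | *Anopheles* species (and F1 hybrid detection)          |
| cox1             | species rescue for *An. nili* (no S200X6.1 amplicon)   |
| mammalian 16S    | blood-meal host composition                            |
| 18S / NS5 panel  | eukaryotic parasite and arbovirus detections           |

The package provides the full analysis path — demultiplexing by exact barcode
and primer match, FLASH-style pair merging, primer trimming, dereplication
into unique-sequence tables with abundance/depth filters, the four locus
callers, Bray-Curtis and weighted UniFrac beta diversity, PCoA, and a
sequential (Type I) distance-based PERMANOVA — together with a synthetic-run
generator that emits complete multiplexed runs with known ground truth, so
every stage is testable without touching real data.

## The statistics at the core

**kdr genotyping.** For each mosquito the two most abundant unique sequences
at the *kdr* locus, Seq1 and Seq2, give the ratio r = Seq2/(Seq1+Seq2):
r ≈ 0 for homozygotes (Seq2 is sequencing error) and r ≈ 0.5 for
heterozygotes. Calls: r < 0.15 → homozygous (RR if Seq1 matches the L1014F
resistant allele, else SS); r > 0.35 → RS; the band between is left
uncalled. Samples under 1000 reads are not called.

**Sequential PERMANOVA.** Given an n×n dissimilarity matrix D and ordered
factors (collection site, species, *kdr* genotype, blood-meal status,
infection status), let G be the Gower-centred matrix of −½D². With H_k the
hat matrix of the design through the k-th factor,

    SS_k = tr((H_k − H_{k−1}) G),   R²_k = SS_k / tr(G),
    F_k  = (SS_k/df_k) / (SS_res/df_res),

and the p-value counts permutations of D's rows/columns whose F* ≥ F_obs,
with the +1 convention (999 permutations → smallest attainable p = 0.001).
The partition is verified in the tests against both explicit hat-matrix
algebra and R's `vegan::adonis2(..., by = "terms")`.

## Worked example

```python
import ampliscreen as am
from ampliscreen import simulate as sim
from ampliscreen.panel import default_panel

truth = sim.simulate_cohort(120, n_sites=6, site_effect_size=0.2,
                            n_controls=10, seed=20)
panel = default_panel(truth.sample_ids, seed=20)
config = sim.RunConfig(depth_means={"bacteria_16s": 6000, "s200x6": 1500,
                                    "cox1": 1200, "kdr": 1500,
                                    "mammal_16s": 2500, "parasite_virus": 1500},
                       depth_shape=200.0, seed=20)
paths = sim.emit_run(truth, panel, config, "run/")
pc = am.PipelineConfig(fastq1=paths["r1"], fastq2=paths["r2"],
                       output_dir="out/", metadata_path=paths["samples"])
result = am.run_pipeline(pc, panel,
                         control_ids=[c.sample_id for c in truth.controls()])
print(am.evaluate_concordance(result, truth))
```

prints

```
{'kdr_accuracy_pct': 100.0, 'kdr_called': 120, 'kdr_uncalled': 0,
 'species_accuracy_pct': 100.0, 'species_called': 120, 'species_uncalled': 0,
 'blood_meal_accuracy_pct': 100.0, 'infection_accuracy_pct': 100.0,
 'n_mosquitoes': 120}
```

i.e. with no sequencing error every genotype, species call (including F1
hybrids and the cox1-rescued *An. nili*), blood-meal host set and infection
set is recovered exactly. `out/summary.json` additionally reports the
routing tallies, per-locus table sizes and the PERMANOVA partition; for this
cohort the location term gives R² = 0.254 with p = 0.001 (single cohorts
scatter around the planted 0.2 because only six site centroids are drawn —
the replicate mean is what the calibration targets).

The same stages are scriptable from the shell:

```bash
ampliscreen simulate -o run/ --n-samples 96 --n-controls 8 --seed 1
ampliscreen run-all --fastq1 run/run_R1.fastq --fastq2 run/run_R2.fastq \
    --barcodes run/barcodes.tsv --metadata run/run_truth_samples.tsv \
    --controls CTL001,CTL002 -o out/
```

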
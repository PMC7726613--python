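# Methods

This note documents the models, rules and numerical choices behind
`ampliscreen`, and what the synthetic-data studies do and do not demonstrate.

## Read routing

Reads are assigned to samples by an **exact** match of the read-1 prefix
against the barcode table (8-nt barcodes by default) and to loci by an exact
forward-primer match anchored immediately after the barcode; when one primer
is a prefix of another the longest match wins. No mismatch tolerance is
applied at either step — a read that does not carry the exact barcode and
primer is tallied UNASSIGNED/UNKNOWN rather than rescued. This trades a few
percent of reads (at a 0.3% per-base error rate, an 8-nt barcode loses ~2.4%
of pairs) for zero risk of mis-assignment, which matters because several
downstream rules interpret low read counts in the *wrong* sample as
contamination evidence.

**Pair merging** searches every ungapped overlap of at least 12 nt between
read 1 and the reverse-complemented read 2 and keeps the overlap with the
lowest mismatch fraction (default ceiling 0.25), ties going to the longer
overlap. Two orientations are scored: the usual "innie" layout, and the
dovetailed "outie" layout that occurs when the amplicon is shorter than the
read length and both reads run through it — there the overhang of read 2
past the amplicon start is barcode/adapter read-through and is discarded, so
the merged sequence stays in the read-1 frame. At mismatched overlap
positions the higher-quality base wins (read 1 on ties). All overlaps are
scored at once from the diagonal sums of the outer equality matrix of the
two reads, and results are cached per unique (read 1, read 2, qualities)
tuple, which makes error-free runs effectively free to merge. Pairs that
fail to merge are not discarded: they continue as read-1-only sequences
through the same trimming rules.

**Trimming and length filter.** The forward primer must begin the merged
sequence (else the read is unroutable). If the reverse primer's reverse
complement is found, the insert between the primers is kept. If not, loci
with an expected amplicon under 300 bp additionally lose 50 bp from the 5'
end as a quality guard; longer loci are kept untrimmed past the forward
primer. Sequences are then kept only if **strictly longer than 90 bp** —
the boundary is exclusive by design and configurable.

One merge/trim path serves all six loci, including 16S. Denoising-style
error modelling is deliberately out of scope: exact unique sequences play
the role of ASVs, with the rare-sequence filter absorbing error reads.

## Tables and filters

Dereplication groups exact strings per locus, recording per-sample counts;
sequences containing N are dropped first. Filters, all exclusive/inclusive
exactly as stated:

* unique sequences seen **fewer than 10 times across all samples** are
  removed (error suppression);
* 16S samples with **fewer than 5000 reads** are excluded from community
  analysis (likely cross-contamination);
* *kdr*, S200X6.1, cox1 and mammalian-16S calls require **at least 1000
  reads** in the sample.

The parasite/virus stream has no per-sample floor beyond the global
rare-sequence filter; weak detections are instead *annotated* post hoc
(below) rather than silently dropped.

## Reference matching

Queries are aligned to the packaged reference set with a global
Needleman-Wunsch alignment in which end gaps on the **reference** are free
and the full query must align (match +1, mismatch −1, gap −2). Identity is
matches divided by the query-spanned alignment columns; hits below **70%**
are suppressed, and exact ties at the top are all reported. Queries under
20 nt are not matched. Note that identity is a property of one optimal
alignment: when a gapped alignment ties the ungapped optimum in score the
reported identity can differ in the third decimal — the tests therefore pin
the alignment *score* to an independent dynamic-programming oracle and use
tie-free constructions for the 70% boundary.

## Locus callers

* **kdr**: ratio r = Seq2/(Seq1+Seq2) of the two most abundant unique
  sequences; r < 0.15 homozygous (RR iff Seq1 matches the packaged L1014F
  allele), r > 0.35 heterozygous, the closed band [0.15, 0.35] uncalled.
  A sample with a single unique sequence has r = 0 (the formula's natural
  limit). Count ties between Seq1/Seq2 break lexicographically by sequence
  for determinism. The caller is scale-invariant above the depth floor.
* **Species**: the most abundant S200X6.1 sequence is matched to the
  reference set; if the top two sequences pass the heterozygosity ratio
  cutoff (> 0.35, the same 0.35 reused — no separate hybrid cutoff is
  defined) *and* map to different species, the sample is flagged an F1
  hybrid. cox1 is consulted only when S200X6.1 yields no call, which by
  construction rescues *An. nili*.
* **Blood meal**: a mosquito is considered fed iff its mammalian-16S total
  reaches 1000 reads ("at least 1000" is the operative wording; the
  threshold is configurable); host read counts come from per-sequence
  reference matching, and multi-host meals are reported as such.
* **Infections**: one detection record per (sample, best-hit set) with read
  count and percent identity; extraction controls are flagged, not removed.
  `flag_contamination` then annotates any non-control detection whose read
  count falls below a multiple (default 2×) of the mean read count of
  control detections of the same organism as "possible contamination".

## Community statistics

Bray-Curtis is computed on **raw counts** (the convention of the ecology
software family this pipeline follows; proportions are a caller-side
transform if wanted). Weighted UniFrac uses scikit-bio's tree traversal,
unnormalized by default, and requires every ASV to be a tip of the supplied
tree. PCoA Gower-centres −½D² and eigendecomposes; coordinates use positive
eigenvalues only, and negative eigenvalues (non-Euclidean metrics) are
excluded from the variance-proportion denominator — no Cailliez/Lingoes
correction is applied by default.

The **sequential PERMANOVA** adds categorical factors in a stated order as
treatment contrasts; SS_k = tr((H_k − H_{k−1})G) with hat matrices from an
SVD projector (rank tolerance 1e-8 relative). Constant or collinear factors
receive df 0, SS 0 and an undefined p. The permutation test permutes rows
and columns of D jointly, includes the identity via the +1 convention
(n_perm = 999 by default, so the smallest attainable p is 0.001), and counts
ties as "at least as extreme" with a 1e-10 relative tolerance so that
algebraically equal statistics are not split by floating-point jitter. A
zero residual (exact-fit designs) is clamped at 0 and yields an infinite
observed F, matched only by partition-preserving permutations. The partition
is cross-checked in the tests against explicit pseudo-inverse algebra, full
permutation enumeration at small n, and `vegan::adonis2(by = "terms")`.

## The synthetic cohort generator

The generator emulates the structure of a West African field study of
individual *Anopheles*: five species with *An. gambiae* dominant (plus
occasional F1 gambiae×coluzzii hybrids at ~1.4%), kdr genotype frequencies
strongly linked to species (near-fixed resistance in *An. gambiae*,
wild-type *An. melas*/*arabiensis*, mixed *An. coluzzii*), ~20% blood-fed
mosquitoes (mostly human, some cow/sheep and mixed meals), ~19% infected
with one or two organisms from an eight-member parasite/virus panel, and a
40-ASV bacterial community. Extraction controls carry no template and
receive reads only through a configurable index-leak rate.

**Reference sequences are synthetic**: deterministic random sequences that
reproduce the *relationships* the callers rely on (one well-separated
S200X6.1 allele per species except *An. nili*; shallowly diverged cox1
haplotypes; two kdr alleles differing at one site; distinct mammal and
parasite markers; 40 16S ASVs with taxonomy and a random phylogeny). No
real-organism sequence data is included or required.

**Planted site effect.** Each cohort draws a base composition (log-normal
abundances, σ = 1.5), perturbs it per site by iid log-normal noise of scale
σ_b, and draws per-sample compositions Dirichlet(30 · centroid). σ_b is
looked up from the requested between-site variance share via a Monte-Carlo
calibration (mean location R² of the sequential Bray-Curtis PERMANOVA at
n = 120, 6 sites, depth 5000; table frozen from
`scripts/calibrate_effect.py`). Individual cohorts scatter around the
target (sd ≈ 0.06 at a planted 0.2) because only six centroids are drawn;
the calibration targets the replicate mean, which the tests verify to
±0.05 over 20 cohorts. An effect of 0 makes samples exchangeable across
sites, and the location p-value is then uniform — verified as a rejection
rate inside the exact binomial interval over 200 cohorts.

**Sequencing layer.** Per-locus depths are negative-binomial (configurable
mean and shape); reads are `barcode + forward primer + insert +
revcomp(reverse primer)` read from both ends at 200 nt with constant Q40
qualities and an optional substitution-only error model (no indels, so
merge and dereplication behaviour stays analyzable; error rate capped at
0.1). Identical (truth, panel, config) produce byte-identical FASTQ.

**Problem sizes.** The package's reference studies use a 120-mosquito,
6-locus run at desk-scale depths (16S mean 6000, other loci 1200–2500,
shape 200 so depths essentially never cross a call floor by chance), 20
replicate cohorts for effect recovery, and 200 reduced cohorts (n = 40) for
null calibration. Full study-scale depth defaults (16S ≈ 11.7k reads per
mosquito, genotyping loci 1.2–2.9k) are the `RunConfig` defaults for users
who want them.

**What the synthetic studies do not show.** Real data add chimeras,
indels, quality-score structure, index hopping beyond a flat leak, primer
bias and DNA degradation, none of which are modelled; passing the noise-free
closure test demonstrates the correctness of the plumbing and rules, not
robustness to instrument pathology. The community model is compositional
Dirichlet-multinomial and does not emulate overdispersed taxon-specific
blooms.

## Known limitations

* Exact-match demultiplexing discards barcode-error reads instead of
  correcting them.
* Identity on tied optimal alignments is alignment-choice dependent (see
  above); boundary behaviour at exactly 70% is guaranteed only for
  substitution-only divergence.
* The PERMANOVA permutes raw rows/columns (no restricted permutations or
  strata); factor order is the user's scientific choice, and R² of later
  terms depends on it.
* Controls participate in the community tables only via leaked reads; no
  decontamination model beyond the annotation rule is implemented.
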
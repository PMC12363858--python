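# Methods

`intronspace` analyses how the six classes of the human intron continuum —
major, major-like, hybrid, minor-like, minor and non-canonical — distribute
across 3D-genome features and how efficiently they are spliced. This note
records the models, the defaults and the reasoning behind the choices that
were genuinely open.

## Linear-genome statistics

**Inter-intron distance.** For each class, introns are sorted by start within
each chromosome and the gap `next.start − current.end` is taken for every
consecutive same-class pair; cross-chromosome pairs are excluded. Overlapping
introns (alternative isoforms) would give negative gaps; these are clamped to
zero and kept, since a distance cannot be negative and dropping the pairs
would bias medians upward. Gap distance (not start-to-start) is used because
it reproduces the well-known result that the major-intron median spacing is
about one exon length. Strand is ignored: the question is genomic, not
transcriptional, spacing.

**Abundance–distance fit.** Pearson correlation of log10(class count) against
log10(median gap); R² is reported at full precision and rounded to two
decimals as conventionally printed. On the published six-class table
(counts 345,317 / 29,337 / 6,070 / 850 / 458 / 373 against medians
141 bp / 27 kb / 105 kb / 1.8 Mb / 4.0 Mb / 6.1 Mb) this gives R² = 0.98.

**Density-cluster scan.** The genome is tiled in 250 kb bins (terminal bins
truncated), each intron assigned once by midpoint. The source analyses call
bins "significant" without naming a test, so a test had to be chosen here:
each bin's class count is compared with the upper tail of
Poisson(λ = N_class · bin width / genome length), with Benjamini–Hochberg
control at FDR 0.05 within class. Poisson is the natural null for uniform
scatter of a rare class; the FDR choice keeps single-gene-family clusters
(the interesting signal) detectable without flooding flags.

## 3D-feature membership

An intron belongs to a feature when at least 50% of its length is covered by
a **single merged interval** of the track (`min_overlap_frac = 0.5`,
inclusive — "at least half"). Tracks are merged on load so that fragmentation
of the source file cannot change results; the fraction is never summed across
disjoint fragments. Within each mutually exclusive partition (compartments
{A, B, neither}; subcompartments; nuclear bodies {SPAD, LAD, neither};
TAD/boundary/loop-anchor), an intron passing the threshold for two categories
is resolved to the larger overlap; an exact tie (only possible at 50/50) goes
to "neither" with a warning. "Neither" covers both absence from the file and
sub-threshold overlap — the two are indistinguishable downstream.
Subcompartment fractions are reported conditional on parent-compartment
membership (A1 vs A2 among A-introns, and so on).

**Enrichment.** Each rare class is tested against the abundant major class as
background with a two-sided Fisher exact test on the 2×2
in-feature/out-of-feature table. The odds ratio reported is the sample
cross-product; the p-value comes from the exact conditional distribution.
Multiplicity is handled by Bonferroni with an **explicit** `family_size`
(default 15: five rare classes × three categories of a partition panel),
always logged, because the appropriate family depends on the analysis panel.
A zero margin yields an "untestable" flag rather than an error.

## Resampling nulls

**Bootstrap null.** `n_boot` (default 1000) random sets of `sample_size`
baseline (major) introns, drawn *without replacement within a replicate* and
with replacement across replicates; the statistic is the in-feature
proportion per replicate. The without-replacement reading is the only one
under which full substitution (below) reproduces the focal class exactly.
The observed focal proportion is located in the null with a two-sided
empirical tail using the (b+1)/(n_boot+1) correction. Per-replicate RNG
substreams are spawned from the master seed, so enlarging `n_boot` never
reshuffles earlier replicates.

**Pollution analysis.** At each fraction f (default 0.1 … 1.0) a replicate
holds round(f·n) focal plus round((1−f)·n) baseline introns (banker's
rounding, n defaulting to the focal class size). Enrichment tethered to class
identity shows up as a monotone rise of the in-feature proportion with f,
summarised by Pearson r over all replicate points. At f = 1 each replicate is
the full focal set, so the proportion is exactly the focal rate — a built-in
self-check. Replicates at a single fraction skip the correlation with a flag,
as do zero-variance curves.

## Gene context

A gene is *expressed* when its replicate-mean TPM meets the threshold
(inclusive ≥, default 1; a stricter 20 is also wired through). Genes present
in the catalog but missing from the TPM table count as not expressed, with a
logged count. Essentiality tests deduplicate to gene level (a gene with k
class introns counts once); expression-stratified feature tests count
introns, matching how the two questions are framed. The essentialome is two
nested sets — total (essential in ≥ 1 screened line) and core (essential in
all); a core gene missing from total is repaired into it with a warning.

## Splicing indices

From spliced alignments, five counts are taken per intron from primary,
non-duplicate, uniquely mapped reads (mapping quality ≥ 1 and NH ≤ 1 when
present): `n5`/`n3` boundary-spanning reads with ≥ `min_anchor` (default 2)
contiguously aligned bases on each side of the exon–intron / intron–exon
junction; `n_spliced` reads whose alignment gap equals the intron exactly;
`n_skip` reads whose gap contains the intron plus at least one whole
annotated adjacent exon; and `n_cryptic` reads using a non-annotated splice
site at or inside the intron. The single-nucleotide-overhang exclusion is
applied to boundary reads as well as spliced reads, for symmetry
(configurable). Extraction is a single linear pass over the SAM/BAM with an
interval index over introns, so plain-text SAM needs no index; a brute-force
re-scan oracle in the test suite checks it read-for-read.

Indices, as percentages:

    SI_RET = 100 · B / (B + n_spliced),  B = (n5 + n3) / 2
    SI_ES  = 100 · n_skip / (n_skip + n_spliced)

Any cryptic evidence vetoes boundary reads as retention support: the intron
becomes spliced-only if `n_spliced > 0`, otherwise it is dropped with a
reason. Introns are categorised retained-only / spliced-only / both; analyses
of splicing efficiency restrict to "both". One exon-skipping junction removes
two introns and the exon between them, so a skip read legitimately counts
toward both flanking introns; the simulator's truth tables record this same
semantics.

Filters before comparison: parent gene expressed at ≥ 1 TPM, at least one
supporting read, optional category = both, and seeded down-sampling of the
abundant classes (default 5000 each for major and major-like). Two-group
comparisons use Mann–Whitney (exact for small untied samples); multi-group
use Kruskal–Wallis followed by all-pairs Dunn z tests with tie correction and
Benjamini–Hochberg adjustment. Dunn's test is implemented in
`intronspace._stats` (rank-sum z with the standard `N(N+1)/12 − T` tie term)
and is cross-checked in tests against the two-group normal approximation.
Replicates of one cell line are pooled (counts summed) before index
computation by default; a per-replicate-then-average mode coincides with
pooling when there is one replicate.

Cross-cell-line analyses intersect introns sharing a nuclear-body category in
all (or pairs of) cell lines, compare their SI_RET between lines with
Mann–Whitney, and extract introns with *strictly lower* retention outside the
reference line (no minimum effect size), exporting deduplicated parent-gene
lists for external GO tools.

## Synthetic study generator

The generator is first-class, tested code: it is the study condition under
which the pipeline is validated.

* **Annotation.** Genes alternate 150 bp exons with 300 bp introns (defaults),
  three introns per gene, laid out non-overlapping with 500 bp spacers on
  four chromosomes sized to fit. A gene carrying a rare intron carries
  exactly one, at the middle position, with major introns flanking —
  mirroring the empirical one-rare-intron-per-gene structure and isolating
  the middle junctions from skip-read cross-talk. Class counts match the
  configuration exactly.
* **Calibrated preset.** Placement probabilities are the published K562
  rates: compartment A 0.62 (major) / 0.71 (minor) / 0.64 (major-like) /
  0.51 (hybrid) / 0.50 (non-canonical); SPAD 0.21 / 0.25; LAD 0.19 / 0.14;
  subcompartment conditionals likewise. Class counts are 30,000 major /
  5,000 major-like / 2,550 minor / 3,000 non-canonical / 1,350 minor-like /
  1,100 hybrid — rare classes at roughly three times their genomic counts'
  unit ratios, a size chosen so the smallest printed effect (SPAD 25% vs 21%)
  is detectable at Bonferroni-corrected α = 0.05 with ~95% power while the
  whole study stays desk-sized. SPAD membership is drawn conditionally on
  compartment A (concordance 1.4, marginal rate preserved; impossible
  combinations raise an error), emulating the observed speckle/A-compartment
  nesting.
* **Tracks.** Feature intervals coincide with member introns, so the
  50%-overlap rule recovers intended membership exactly — membership noise in
  validation comes only from the Bernoulli placement draws, never from
  interval arithmetic.
* **Expression.** A configured fraction of genes (default 0.75) is expressed
  with mean TPM 1.5 + LogNormal(0, 1), the rest Uniform(0, 0.9); replicate
  values jitter the mean multiplicatively (σ = 0.05). The gap around the
  1-TPM rule makes the expressed flag deterministic given the draw.
* **Alignments.** Per intron with depth d and true retention ψ and skipping
  σ: n5, n3 ~ Poisson(dψ) independently, n_spliced ~ Poisson(d(1−ψ)(1−σ)),
  n_skip ~ Poisson(d(1−ψ)σ), optional cryptic reads. Every count is
  materialised as a single-end, uniquely mapped SAM record with exact gapped
  CIGARs and 30 bp anchors; extraction recovers the written counts exactly
  (the randomness is upstream of emission). Per-class ψ/σ are Beta-distributed
  around class means (major 0.06/0.02 … non-canonical 0.25/0.12) chosen to
  mirror the qualitative ordering of retention across classes.

**What the generator does not emulate:** nucleotide sequence and splice-site
motifs, multi-mapping reads, fragmented or nested real feature intervals,
Hi-C contact structure, and correlated expression between neighbouring
genes. Passing tests therefore validate the statistical machinery and the
interval/junction arithmetic under known truth — they do not certify the
biological conclusions on real hg38/4DN/GEO inputs, whose published
percentages (62%/71% in compartment A, 21%/25% in SPADs, r = 0.89, shared-set
sizes 173/24/36/27, improved-splicing sets 32/33/38) are instead encoded as
the preset's generative parameters and documented as the expected outputs
for users supplying the real data.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; 1-based inclusive TSV is
  converted on load, and the two dialects round-trip identically.
* Fisher p-values come from `scipy.stats.fisher_exact`; tests pin them to
  exhaustive hypergeometric enumeration (≤ 1e-9) for all tables with N ≤ 40.
* Zero denominators (no junction evidence, empty classes, empty scopes)
  produce explicit `None`/untestable results, never exceptions mid-pipeline.
* Identical groups short-circuit to p = 1 in rank tests, avoiding tie-only
  division errors.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; every orchestrated run records its seed and a parameter hash in
  the manifest, and identical configurations reproduce byte-identical
  tables.

## Problem sizes used in validation

Validation runs use the calibrated preset (43,000 introns), 1000 bootstrap
replicates of 850 introns, 200 pollution replicates per fraction, 300 introns
per ψ- or σ-stratum at junction depth 200, and the exhaustive Fisher sweep to
N = 40 — sizes at which Monte-Carlo error is far below the tolerances being
checked while a full run completes in minutes.

## Known limitations

* The cluster-scan test is this package's choice; other reasonable nulls
  (e.g. gene-density-conditioned) would flag different marginal bins.
* The Bonferroni family is explicit but conventional; panels with different
  numbers of tested classes/categories need an adjusted `family_size`.
* Exon-skipping counts do not require the skipped exon to be constitutive.
* The SI formulas are the package's defaults for junction-evidence indices;
  `compute_si_ret`/`compute_si_es` are small pure functions that can be
  swapped if a different weighting of boundary evidence is preferred.
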
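# intronspace

Where do rare introns live in the 3D genome, and does it matter for their
splicing?

Human introns fall along a continuum of six classes defined by splice-site
and branch-point motif similarity to the major (U2-type) versus minor
(U12-type) spliceosomal consensus: **major, major-like, hybrid, minor-like,
minor and non-canonical**. `intronspace` is a Python toolkit for analysing
how these classes distribute across features of nuclear organisation — Hi-C
A/B compartments and subcompartments, speckle-associated domains (SPADs,
SON TSA-seq) and lamina-associated domains (LADs, DamID) — and how
efficiently they are spliced, from junction-level read evidence. It is aimed
at genomics researchers with a class-labelled intron catalog, interval
annotations of 3D features, gene-level TPM tables and spliced alignments.

## What it computes

* **Linear-genome statistics** — inter-intron gap distances per class, the
  log–log abundance–distance fit (Pearson R²), 250 kb density bins and a
  Poisson/Benjamini-Hochberg scan for class-specific clusters.
* **3D-feature membership** — the ≥ 50%-of-intron single-interval overlap
  rule, mutually exclusive partitions with "neither", per-class proportions,
  and class-vs-major Fisher exact enrichment with explicit Bonferroni
  families.
* **Resampling nulls** — the matched-size bootstrap (random major-intron
  sets the size of the focal class) and the pollution analysis (substituting
  a growing fraction of minor introns into major sets), the controls that
  separate class identity from gene identity.
* **Gene context** — expression-stratified (TPM ≥ 1 / ≥ 20) and
  essentialome-conditioned enrichment.
* **Splicing indices** — per-intron intron-retention and exon-skipping
  indices from junction reads,

      SI_RET = 100 · B / (B + n_spliced),  B = (n5 + n3)/2
      SI_ES  = 100 · n_skip / (n_skip + n_spliced)

  with anchor and cryptic-splice-site rules, the expression/supporting-read/
  category filters, Mann–Whitney and Kruskal–Wallis + Dunn (BH) comparisons,
  and cross-cell-line matched-location sets with improved-splicing
  intersections.
* **A synthetic study generator** — a toy genome with class-labelled introns,
  feature tracks with class-specific placement probabilities, replicate TPM
  tables and simulated spliced SAM alignments with known per-intron retention
  and skipping truth, so the whole pipeline is testable without downloads.

## Worked example

Generate a small synthetic study and test whether minor introns are enriched
in compartment A relative to major introns:

```python
import intronspace as isp
from intronspace.simulate import SyntheticConfig, generate_annotation, \
    generate_feature_tracks

cfg = SyntheticConfig(seed=7)                 # calibrated preset
catalog, models, truth = generate_annotation(cfg)
tracks = generate_feature_tracks(cfg, catalog, truth)
matrix = isp.assign_membership(catalog, tracks)

r = isp.enrichment_fisher(matrix, catalog, "minor", "compartment_A",
                          family_size=15)
print(f"minor in A: {r.proportion_focal:.1%}  "
      f"major in A: {r.proportion_baseline:.1%}  "
      f"adjusted p = {r.p_adjusted:.2e}")

boot = isp.bootstrap_null(matrix, catalog, "major", "compartment_A",
                          sample_size=850, n_boot=1000, seed=1,
                          focal_class="minor")
print(f"bootstrap median of 1000 random major sets: {boot.median:.1%}")
```

Output:

```
minor in A: 69.3%  major in A: 62.0%  adjusted p = 1.41e-12
bootstrap median of 1000 random major sets: 61.9%
```

Minor introns sit in compartment A at ~70% versus ~62% for major introns,
and the bootstrap shows that random major-intron sets of the same size stay
at the major rate — the enrichment is tied to class identity, not set size.

The same analyses run from the shell:

```bash
intronspace simulate all --seed 7 --out-dir study/
intronspace run --config run.yaml
```

`intronspace run` executes every stage (catalog statistics, overlap,
resampling, expression/essentiality context, splicing indices, cross-line
sets) from one YAML configuration and writes TSV tables plus a manifest with
seeds and a parameter hash.

Note on real data: the published full-scale percentages (e.g. 62%/71% in
compartment A) require the hg38 intron catalog, 4DN feature tracks and GEO
alignments as inputs; this package encodes them as the calibrated synthetic
preset's generative parameters and reproduces them there by construction.

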
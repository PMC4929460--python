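# Methods

`cnvindex` implements an integrated strategy for deciding which genes inside
clinically reported copy-number variants (CNVs) are plausible contributors to
neurodevelopmental phenotypes.  Three independent evidence streams are
computed and intersected:

1. **Critical-exon indexing** — exons that combine a low population burden of
   rare deleterious point mutations with high expression in brain tissue,
   aggregated to a per-gene fraction and ranked genome-wide;
2. **Signed protein co-expression modules** — weighted correlation-network
   modules detected on protein abundance across prenatal and adult tissues,
   with the phenotype-relevant module picked by functional (gene-set)
   enrichment;
3. **Case-exclusive CNV gene sets** — genes exonically covered by pathogenic
   or uncertain-significance (VOUS) CNVs in affected cases and by no CNV in
   unaffected controls.

A gene is a candidate when it lies in all three: the selected module, the
genome's top quartile of critical-exon fraction (by default in *both*
developmental periods), and at least one case-exclusive pathogenic/VOUS set.
Enrichment statistics (Fisher's exact tests, Bonferroni correction,
permutation empirical p-values) are reported as evidence alongside the
candidate list but never gate candidacy, so the candidate set is invariant to
the permutation budget.

## Critical-exon model

For exon *e* with rare-variant burden *b(e)* (count of missense and
loss-of-function variants at allele frequency < 5% inside the exon), the
genome-wide burden percentile rank is

    rank(e) = 100 · #{e′ : b(e′) < b(e)} / (N − 1),

over the N retained exons (genes without any variant call are excluded
first).  Exon *e* is **critical in sample s** iff

    rank(e) < 75   and   RPKM(e, s) > Q75(s),

where Q75(s) is the nearest-rank 75th percentile of expression over all exons
within sample *s*.  Both gates are strict, so values tied with the threshold
fail; the nearest-rank (inverse empirical CDF) convention avoids
interpolation ambiguity and makes the calls exactly reproducible.  An
all-zero sample has Q75 = 0 and therefore no critical exons (logged).

Per gene *g* and sample *s* the critical-exon fraction is the number of
critical exons divided by the gene's **full** annotated exon count; annotated
exons missing from the expression matrix count as non-critical.  A gene is a
**top critical gene** for a period (prenatal or adult) when its fraction
reaches the within-sample nearest-rank 75th percentile over genes
(inclusive ≥) in at least ⌈0.5 · n⌉ of the period's samples — "at least
half" is inclusive at exactly half.  Burden is the raw per-exon count, not
length-normalised (a length-normalised mode exists behind
`CriticalExonConfig.length_normalized`, off by default).  Region summaries
average per-sample results (per-gene mean across a region's samples, then
mean over genes); pooling samples before ranking is deliberately not done, so
regional heterogeneity survives.

Open conventions resolved here (both configurable): the expression reference
is per-sample, not per-region; the top-quartile gene rule is evaluated
within samples and then subjected to the period majority.

## CNV gene sets

CNV calls are BED-convention intervals with type (del/dup), clinical class
(pathogenic / VOUS / control), inheritance and carrier sex.  Analysis is
restricted to lengths in the closed interval [30 kb, 5 Mb] — both bounds
inclusive.  A gene is exonically hit when a call overlaps ≥ 1 bp of ≥ 1 of
its exons (half-open overlap).  For each (class, type) stratum the
case-exclusive set removes every gene hit by *any* control call, pooling
control deletions and duplications (a per-type exclusion mode exists behind
a flag).  Cohort summaries report carrier percentages over distinct samples,
mean genes per call, de novo class shares, and a one-sided Fisher test for a
female excess of pathogenic-deletion carriers.  Genes-per-variant is counted
per call, not per sample.

## Co-expression network

Protein abundance (spectral counts per gene across 24 tissues, 7 prenatal)
is filtered of rarely expressed genes (zero in ≥ 90% of tissues), then
correlated (Pearson, across all tissues; inputs must be complete — the
loaders reject missing values).  The signed soft-threshold adjacency is

    a_ij = |0.5 + 0.5 · cor(x_i, x_j)|^β,   β = 18 by default,

with zero diagonal; connectivity is the row sum ("connections to other
nodes").  Neighbourhood sharing is the topological overlap matrix

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and genes are clustered by average-linkage hierarchical clustering on
1 − TOM.  Spectral counts enter untransformed by default, mirroring the
stated input of the analysis this package operationalises (a `log1p` switch
exists for stress tests).

**Module extraction** is a simplified dynamic hybrid tree cut, re-implemented
rather than ported: a static cut at a deepsplit-scheduled fraction of the top
merge height (0.995, 0.9925, 0.99, 0.9875, 0.985 for deepsplit 0–4; the
middle level matches the reference default of 0.99 × max), a minimum module
size of 30, and a rescue stage that attaches a leftover gene to its nearest
module when its mean-dissimilarity gap to the rest of the network exceeds a
deepsplit-scheduled margin.  The schedule is anchored near the top of the
dendrogram because at β = 18 all between-branch dissimilarities collapse to
≈ 1, so every valid cut lies just below the final merges.  Fidelity to the
published algorithm is asserted by planted-module recovery (adjusted Rand
index), not label-for-label agreement with the reference implementation.

Each module's **eigengene** is the first singular direction of its
gene-standardised submatrix (unit norm, sign-anchored to correlate
positively with members on average); KME is a gene's correlation with a
module eigengene.  Members with KME < 0.30 (the reference implementation's
`minKMEtoStay` default; the analysis names the function but not a value) are
trimmed.  A KME settlement pass then (i) moves an assigned gene to the
module it correlates with best and (ii) adopts an unassigned gene whose best
KME clears 0.30 — together these reproduce the net effect of the reference
workflow's partition-around-medoids stage followed by KME filtering, and
they are what recovers legitimately weak module members that a single static
cut strands.  Modules whose eigengene dissimilarity 1 − cor(ME_a, ME_b) is
strictly below 0.35 are merged greedily (closest pair first, eigengenes
recomputed after every merge).  Final modules are renamed M1, M2, … by
decreasing size; per-gene kTotal/kWithin come from the full adjacency.

Above 20,000 genes the pipeline runs blockwise: a deterministic k-means
pre-clustering (fixed seed, oversized clusters split by distance-to-centre
order) partitions genes into blocks, the per-block pipeline runs, and
modules are merged across blocks by eigengene dissimilarity.  At or below
the block cap the blockwise path is literally the single-block pipeline.
Every stage is deterministic; the module has no randomness.

**Scale-free fit.**  `pick_soft_threshold` reports, per candidate β, the R²
of log10 p(k) on log10 k (equal-width bins in log10 k, sign flipped for a
rising slope) and mean connectivity, suggesting the smallest β with
R² ≥ 0.8.  On the synthetic latent-factor proteome no candidate typically
reaches 0.8: the factor model's connectivity distribution is a noise bump
plus a module bump, not a power law, so the suggestion is often absent
there.  Mean connectivity decreasing in β is analytic (the adjacency base
lies in [0, 1]).  Downstream stages therefore run at the β = 18 default
rather than a data-driven suggestion.

## Enrichment statistics

Overrepresentation is a one-sided (greater) Fisher exact test on the 2×2
membership table over an explicit background; genes outside the background
are dropped and counted.  The odds ratio is ad/bc, with the Haldane +0.5
applied to every cell only when some cell is zero (flagged).  Bonferroni is
min(1, m·p).  Two named background presets mirror the analysis design:
`proteome_transcriptome` (genes with both protein and mRNA expression; used
for critical-gene-in-module tests) and `proteome` (all genes with protein
expression; used for CNV-gene-in-module tests).

The permutation test draws |query| genes from the background without
replacement and scores the overlap with the target.  That null statistic is
exactly hypergeometric, so draws are sampled from the hypergeometric law
directly — sampling-equivalent to materialising gene lists, an order of
magnitude cheaper at n_perm = 100,000, and trivially invariant to background
ordering.  The empirical p uses the add-one estimator
p = (1 + #{perm ≥ obs}) / (n_perm + 1), which cannot return zero.  The
permutation statistic is the overlap count (for fixed margins its ranking is
equivalent to re-computing per-permutation Fisher p-values).

## Synthetic data: what it emulates, and what it does not

The generator plants recoverable ground truth with the statistical structure
the analysis assumes.  All randomness flows from one seed through named
per-stage `SeedSequence` spawns, so identical configs give byte-identical
outputs and stages can be regenerated independently.

* **Gene model** — genes tiled end-to-end on one synthetic chromosome;
  exon counts 1 + Poisson(mean − 1) (mean 8), exons 150 bp with 2 kb
  introns.  The intergenic gap is deliberately large (20 Mb) so that
  uniformly placed control CNVs of the configured size range rarely hit
  genes (≈ 0.02 expected exonic gene hits per control call): after
  frequency filtering, real rare control CNVs cluster outside the
  case-implicated gene space, and this geometry reproduces that sparsity so
  the case-exclusive construction is exercised rather than saturated.
* **Burden** — per-exon Poisson counts, mean 0.5 for the 50 planted risk
  genes vs 5.0 for background: planted genes sit far below the 75th burden
  percentile.
* **Brain expression** — i.i.d. log-normal RPKM per exon and sample over a
  16-region × {prenatal, adult} × 3 grid (96 samples); planted exons use
  mean-log 3.0 vs 0.0 background (sd-log 1.0), placing them in the top
  expression quartile of essentially every sample.
* **Proteome** — 24 tissues (7 prenatal); five 50-gene modules on
  consecutive blocks (block 1 = the planted genes) from a latent one-factor
  model with latent correlation 0.8; counts are round(exp(3 + 0.5·latent))
  with 5% dropout for zero inflation.  The exponential transform, rounding
  and dropout attenuate the realised count-scale correlation to ≈ 0.55–0.7
  (occasionally lower when a factor draw has little spread) — a deliberate
  feature: module detection is tested under attenuation, not at the nominal
  latent value.
* **CNV cohorts** — 500 cases (31.5% female), each carrying a pathogenic
  CNV with probability 0.10 and a VOUS with probability 0.50; each such
  call covers a random exon of a random planted gene with probability 0.9,
  otherwise it is placed uniformly.  500 controls carry one uniform call
  each.  Sizes are log-uniform on [5 kb, 5.5 Mb], straddling both ends of
  the 30 kb–5 Mb analysis window so the size filter removes calls on both
  sides.  Inheritance is independent of class (de novo 0.25, inherited
  0.55, unknown 0.20).
* **Gene sets** — one `planted_synaptic` term (planted genes plus a 10%
  noise fraction of random genes) among 50 random same-size terms.

Not emulated: donor/age structure beyond the region × period grid, linkage
between expression and proteome noise, realistic exon-length variation,
recurrent CNV hotspots, genome-wide burden covariates (GC, mappability), or
gene-density variation.  Passing recovery tests therefore demonstrates that
the pipeline's logic is correct and well-calibrated under its own model
assumptions — not that the thresholds are optimal for any real cohort.

## Problem sizes and numerical choices

Default study conditions (800 genes ≈ 6,300 exons, 96 brain samples, 24
tissues, 500 + 500 cohorts) run the full pipeline in a few seconds on one
CPU; the acceptance battery, including 100,000-draw permutations and a
46,375-table exact-test enumeration, completes in well under a minute.
Tolerances: oracle equivalences are asserted at 1e−12 (exact tests, TOM) or
exact equality (critical calls); eigengene decompositions at 1e−8.
Tie-breaks are always deterministic (module naming by size then label;
module selection by corrected p, then size, then label).  Degenerate inputs
are defined behaviours, not errors: all-zero expression samples call
nothing, single-gene modules use the standardised profile as eigengene,
all-equal burdens rank 0, degenerate connectivity yields a missing
scale-free R².

## Known limitations

* The tree cut is a simplified re-implementation; on data whose dendrogram
  has no near-top plateau of between-branch merges (e.g. unthresholded
  correlation dissimilarities) the static schedule may cut poorly — the
  planted-recovery contract, not reference parity, is the supported claim.
* Sensitivity of end-to-end planted-gene recovery varies with the random
  realisation (≈ 0.84–0.98 across seeds at default conditions): weak factor
  draws cost module members, and cohort sampling occasionally leaves a
  planted gene without a surviving case call or covered by a control call.
* The permutation and exact tests agree by construction for overlap
  statistics; no support is provided for permutation statistics other than
  the overlap count.
* Pearson correlation with pairwise-complete observations is unsupported;
  inputs must be complete.
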
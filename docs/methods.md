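# Methods

## Setting and coordinate conventions

The package analyses a two-group (case vs. control) design with biological
replicates, starting from per-cytosine methylated/unmethylated read counts
(CX-report-like TSVs: chrom, 1-based position, strand, methylated count,
unmethylated count, context) and a gene × sample read-count matrix.
Internally all intervals are 0-based half-open; GFF3 input/output uses the
format's 1-based inclusive convention and BED stays 0-based half-open.
TSS/TES are strand-normalized so the TSS is always the 5′ end; a
minus-strand gene occupying `[start, end)` has TSS = `end` and its promoter
at `[end, end + 2000)`.

Direction is everywhere **case minus control**: "hyper" means the case
group is more methylated. Every report produced by the DMR caller carries
this convention; it is a modelling choice, stated here once, because the
reference group of a two-group comparison is otherwise ambiguous.

## Methylation levels

The elementary statistic is the pooled methylation level
`ML = Σ methylated / Σ (methylated + unmethylated)`. Window, feature,
metagene and genome-wide summaries are all ratios of summed counts — never
means of per-site ratios — so low-coverage sites are automatically
down-weighted. Zero-coverage entities are reported as missing (NaN), never
as 0, to avoid deflating pooled levels.

- **Windows**: non-overlapping 10-kb tiles by default; the step is
  configurable for a true sliding window. The last tile of a chromosome may
  be short, so tile widths sum exactly to the chromosome length.
- **Feature levels**: a cytosine inside intervals of several feature
  classes (promoter, TSS ±50 bp, 5′UTR, exon, intron, 3′UTR, TES ±50 bp,
  downstream, repeat) counts once in every class; no precedence hierarchy
  is imposed, matching per-region reporting. UTRs derive from the CDS and
  are skipped (logged) for genes without one. TSS/TES point-windows default
  to ±50 bp to keep them distinct from promoter and body.
- **Metagene profiles**: 20 upstream bins of 100 bp, 60 body bins with each
  gene's body linearly scaled, 20 downstream bins of 100 bp. Minus-strand
  genes are mirrored so bin 0 is always 5′-most; genes shorter than 60 bp
  are excluded with a log entry. Per-bin values pool counts across genes.
- The **promoter** defaults to the 2-kb region upstream of the TSS and is
  the same interval as the "upstream 2 kb" flank; the two labels are kept
  because feature-level and metagene reports use them in different roles.
  The promoter length is configurable.

Per-site statistics can apply a minimum-coverage filter (default ≥ 5 reads
per sample when requested); pooled summaries always use all reads.
Symmetric-CpG strand merging is available but off by default — CX reports
are per-strand and the tests treat strands as separate observations.

## DMR calling

For one context, per chromosome:

1. **Smoothing.** Each group's proportion at a site is the ratio of pooled
   counts over all sites within ±250 bp (span 500 bp); this equals the
   coverage-weighted moving average of site MLs and is clamped to
   `[1e-6, 1 − 1e-6]`.
2. **Dispersion.** A beta-binomial dispersion φ is estimated per site by
   method of moments from replicate proportion variation within each group
   (`E s² = p(1−p)[φ + (1−φ)/n̄]`), averaged over groups, then shrunk
   toward the genome-wide median with weight `w = cov/(cov + cov₀)`
   (cov₀ = 50) on the site estimate. Sites with fewer than two covered
   replicates in both groups fall back to the median, with a warning.
3. **Wald test.** With window-aggregated per-replicate coverages
   `A = Σ n` and `B = Σ n(n−1)`, each group's variance is
   `v = μ(1−μ)(A + φB)/A²`, the exact variance of the pooled proportion
   when every observation is beta-binomial with a common φ. For an
   isolated site this reduces to `Σᵢ μ(1−μ)(1+(nᵢ−1)φ)/nᵢ / R²` over
   replicates. Aggregating at the smoothing scale is what makes a 0.3
   methylation difference detectable at 30× coverage under a site
   threshold of p < 1e-5; per-site coverages alone would cap the z-score
   near 3. A finite-sample correction divides by `(1 − c)`, where
   `c = (A + φB)/A²`, because the plug-in `μ̂(1−μ̂)` underestimates
   `μ(1−μ)` by exactly that factor in expectation. The statistic
   `(μ₁−μ₂)/√(v₁+v₂)` is referred to the standard normal, two-sided;
   zero-information sites get p = 1.
4. **Region merging.** Maximal runs of significant (p < 1e-5) same-sign
   sites with ≤ 100 bp between consecutive significant sites become
   candidate regions; a region is kept when it spans ≥ 50 bp, contains
   ≥ 3 same-context sites, and ≥ 50% of those are significant. Runs of
   opposite sign never merge. Defaults mirror the published defaults of
   the standard smoothing-based caller for this design and are all
   configurable.

No site-level multiple-testing correction is applied; region-level
filtering plays that role by design. Observed absolute differences are not
capped. Swapping the group labels flips every direction and negates every
statistic while leaving p-values unchanged (tested).

DMR summaries use fixed length bins [50,100), [100,150), [150,200),
[200,250), [250,300), [300,400), [400,∞); per-chromosome and
per-direction counts partition the DMR set, while per-feature counts are
multi-assigned and may exceed the total.

## Differential expression

Median-of-ratios size factors (geometric-mean reference over genes
positive in all samples; total-count fallback with a warning otherwise).
Per gene, a method-of-moments NB dispersion is computed from pooled
within-group variances, `α̂ = (s² − m̄ξ)/m̄²` with `ξ = mean(1/sf)`; the
untruncated estimates are averaged in 20 log-spaced mean bins and a
parametric trend `α(μ) = a₀ + a₁/μ` is fitted by non-negative least
squares. The working dispersion blends trend and (truncated) gene estimate
with fixed weight 0.6 on the trend — enough pooling to keep the null
rejection rate at nominal 0.05 within [0.03, 0.07] at 4 vs 4 (verified by
simulation in the test suite), while letting genuinely noisy genes keep
extra variance. log2 fold change uses normalized group means with a 0.5
pseudo-count; its delta-method standard error uses
`Var(mean) = (Σᵢ μ/sfᵢ + αμ²)/R²`. The Wald statistic is referred to the
standard normal.

DEG calls follow the strict rule `FC > 1.5 or FC < 0.67` with raw Wald
`p < 0.05`; a gene exactly at a threshold is not called. No FDR enters the
calls; a Benjamini–Hochberg column is emitted for users. Expression bins:
"none" = zero raw counts in all samples; the remaining genes are ranked by
mean normalized count and split into near-equal tertiles (low / medium /
high), ties broken by gene id. Whether binning should use normalized
counts or FPKM is genuinely open; normalized counts were chosen because
the pipeline never sees transcript lengths.

## Integration

A DMG record is one (gene, region) pair — region ∈ {promoter, gene body}
— overlapping ≥ 1 DMR; its direction is hyper, hypo, or "both" when both
directions overlap the region. The Venn partition
(hyper-only, hypo-only, both) always sums to the region total.
DMG × DEG intersection is an inner join on gene id over called DEGs, with
concordance: hypo + up → `hypo_up`, hyper + down → `hyper_down`,
direction "both" → `mixed`, anything else → `discordant`. "Mixed" genes
belong to neither concordant set. When a gene carries promoter and body
records that disagree, the per-gene roll-up used for enrichment takes the
promoter record (the stronger regulatory prior); this is configurable in
code and reported per-region in full in the tables. Overlap totals count
unique gene ids; region detail is kept separately.

Stratified metagene profiles compute one 100-bin profile per expression
bin per group; genes contribute only to their own bin.

## Pathway enrichment

Exact upper-tail hypergeometric over-representation: for a query of n
background genes and a pathway covering K of N background genes with
intersection k, `p = P(X ≥ k)`, X ~ Hypergeometric(N, K, n). The
background defaults to genes present in both the annotation and the
pathway collection. Raw p < 0.05 is the significance rule; BH-adjusted
values are reported alongside. Three suites run against the same
background: all overlapping genes, `hyper_down`, and `hypo_up`.

## Synthetic data generator

The generator emulates the statistical structure of the study, not its
sequences: no reads, no bisulfite-conversion failure, no SNPs, no
alignment artifacts.

- **Genome**: 2 chromosomes × 1.5 Mb holding 200 non-overlapping genes
  (3–8 kb, 1–4 exons, random strand, CDS-derived UTRs) with 2-kb flanks
  kept disjoint between neighbours; repeats occupy intergenic gaps.
  Infeasible requests raise a capacity error naming the violated
  constraint.
- **Cytosines**: background CpG pairs (both strands) at ~1 per 100 bp,
  CHG/CHH at ~1 per 150 bp each; in addition a dense cluster of 8 CpG
  pairs spaced 20 bp is placed at the middle of every promoter and gene
  body so planted DMRs always satisfy the caller's minimum-site rules.
- **Methylation counts**: totals are Poisson(30) per site and sample;
  methylated counts are beta-binomial with dispersion 0.05 around a
  context baseline (CpG 0.7, CHG/CHH 0.02). The case group is shifted
  −0.1 outside gene bodies (the genome-wide flank hypo-methylation
  feature); planted DMRs add ±0.3 inside their interval for the case
  group. Means pushed outside [0.001, 0.999] are clamped and counted in a
  logged warning — with the default shift the CHG/CHH flank baselines
  saturate at the floor, which is intentional: those contexts are nearly
  unmethylated to begin with.
- **Expression**: negative-binomial counts (dispersion 0.05) around
  log-uniform baselines (10^0.5–10^3); 10% of genes are silent ("none"
  bin). Planted DEGs (default 20, |log2FC| = 1) draw baselines in
  10²–10³ so detection power is a property of the effect, not of counting
  noise. Keeping the DE fraction near 10% matters: median-of-ratios
  normalization assumes most genes unchanged, and a strongly asymmetric
  DE fraction visibly biases every fold change (at 35%-up the bias
  reaches ~0.2 log2 units — measured, not hypothetical).
- **Linkage**: a configurable fraction of planted DMRs are placed
  hypo-methylated in the promoter cluster of genes simultaneously planted
  as up-regulated DEGs — the negative methylation–expression coupling.
  An optional monotone mode instead pins promoter CpG levels per
  expression bin (none 0.80 / low 0.65 / medium 0.50 / high 0.35, both
  groups) for testing the stratified profiles.
- **Seeding**: one master seed; each stage (genome, truth, methylome,
  expression, pathways) derives a child generator at a fixed offset, so a
  fixed config reproduces byte-identical fixture directories; the
  ground-truth manifest is written last so its presence marks a complete
  fixture.

Because replicate effects are exchangeable beta-binomial/NB draws, passing
tests demonstrate calibration and recovery under the assumed models; they
do not probe batch structure, coverage biases along the genome, spatially
correlated dispersion, or annotation errors found in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full chain at deliberate
desk scale — 2–3 Mb genomes, 100–200 genes, 2 000–6 600 null units per
calibration, 3–5 seeds per rate — sizes at which every planted effect is
comfortably identifiable yet a complete run takes seconds. Calibration
bands ([0.03, 0.07] at nominal 0.05) and recovery floors (≥ 80% DMR and
linkage recovery, ≥ 90% DEG detection, ≤ 20% false DMR calls) are
evaluated at exactly these sizes. Proportions are clamped away from
{0, 1} before variance formation; ties in expression ranking break by
gene id; degenerate inputs (empty windows, empty feature classes, empty
queries, zero-coverage sites) produce explicit missing values or logged
skips rather than zeros.

## Known limitations

- The site-level Wald test is mildly anti-conservative at n = 4 per group
  (empirical null rejection ≈ 0.06 at nominal 0.05) because μ and φ are
  plugged in as known; the region-level filters absorb most of this, and
  the behaviour is measured by the calibration tests rather than assumed.
- Dispersion shrinkage is a coverage-weighted pull to a global median /
  parametric trend, not an empirical-Bayes posterior; per-site dispersion
  heterogeneity beyond the trend is only partially captured.
- The expression model has no covariates, batch terms, or paired designs;
  the DMR caller has no covariate adjustment either.
- Hypergeometric enrichment ignores gene length, expression-detection
  bias, and pathway topology.
- With n = 4 per group, per-gene methylation–expression correlation
  coefficients are not meaningful and are deliberately not computed; the
  expression-stratified profile comparison is the supported alternative.
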
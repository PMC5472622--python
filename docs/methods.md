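# Methods

This note documents the models and procedures implemented in
`methintegrate`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic data generator does and does not
emulate.

## Overview

The pipeline integrates three data modalities across cell types, with one
cell type acting as reference:

1. **Differential methylation.** Per-CpG methylated/unmethylated read
   counts (RRBS-style) are compared between cell types; differentially
   methylated CpGs (DMCs) are aggregated into regions (DMRs); set
   deduction against all other cell types' DMR sets yields the
   *cell-type-specific* DMR set.
2. **Genomic context.** The genome is partitioned into six
   CGI/shore/promoter classes, CpGs and DMRs are assigned to features, and
   DMRs are overlapped with tumor-suppressor gene (TSG) segments.
3. **Expression integration.** A Bayesian Gaussian regression links each
   annotated gene's differential expression (log2 fold change) to the mean
   methylation difference of its hosting DMR, its TSG status and its
   genomic segment; Bayes factors from Chib marginal likelihoods select
   between model variants.
4. **TF interplay.** Promoter-window CpG methylation under ChIP peaks is
   aggregated over all (cell type, TF) combinations into a Beta background;
   each combination is Kolmogorov–Smirnov-tested against it and classified.

## Differential methylation

**Per-site test.** At every CpG covered by ≥ `min_coverage` (default 10)
reads in both samples, a two-sided Fisher exact test is run on the 2×2
table of methylated/unmethylated counts. Fisher's exact test is the
standard no-replicate choice for count-based bisulfite comparisons. P-values
are Benjamini–Hochberg adjusted across all tested sites; a DMC requires
|methylation difference| ≥ 25 percentage points and q ≤ 0.01. The sign
convention is reference minus comparator: *hyper* = more methylated in the
reference.

**DMR construction.** Tested sites are tiled into fixed windows (default
1,000 bp, step = window). Per window, counts are pooled per sample
(Σ meth, Σ coverage), the window methylation difference is the difference
of pooled proportions, and a Fisher test on the pooled table is BH-adjusted
across windows. Windows qualifying at |diff| ≥ 20 points and q ≤ 0.01 are
merged with adjacent qualifying same-direction windows (the merged mean
difference is recomputed from the merged pooled counts; the merged q is the
most significant member's). Tiers:

- *candidate*: |mean diff| ≥ 20, q ≤ 0.01;
- *significant*: additionally q ≤ 0.001 and ≥ 5 qualifying DMCs inside.

The tiling parameters are not dictated by the data model; 1 kb non-overlapping
windows are a common default and are configurable.

**Cell-type specificity.** For reference cell *i* with per-cell DMR sets
{DMR_j}, the specific set is DMR_i minus the union of all other cells'
sets, where "minus" removes any reference DMR sharing ≥ 1 base with any
other cell's DMR, regardless of direction. Half-open interval semantics
mean exactly abutting DMRs do not block each other. The deduction defaults
to the significant tier (configurable), and is idempotent by construction.

## Six-region partition

With P = merged promoter bases (TSS ± 1,000 bp per gene), CGI = merged
island bases, and S = shore bases (1,000 bp flanks on each side of every
merged island, minus island bases):

| region | formula | meaning |
|---|---|---|
| I CGI.NP | CGI \ P | islands outside promoters |
| II CGIS.NP | S \ P | shores outside promoters |
| III P.CGI | CGI ∩ P | islands inside promoters |
| IV P.CGIS | S ∩ P | shores inside promoters |
| V P.NCGI | P \ CGI | promoter bases outside islands |
| VI P.NCGIS | P \ (S ∪ CGI) | open-sea promoter bases |

Islands are merged before shores are computed so adjacent islands never
double-count shore bases, and shore bases overlapping any island are
removed; islands and shores are therefore disjoint. Region VI removes
island bases as well as shore bases: an island is not its own shore, but a
promoter base inside an island is not outside the island neighbourhood
either, and VI is meant to capture promoter sequence away from islands
altogether. Exact base-set identities follow by construction:
V ∪ III = P, I ∪ III = CGI, II ∩ CGI = ∅.

"1,000 bp centered around an island" could alternatively be read as a 500
in / 500 out band straddling each island edge; the flank width is a
parameter (`shore_flank`) rather than a hard-coded choice.

**Feature assignment.** Each site receives exactly one gene-context label
with precedence promoter > exon > intron > intergenic and one CpG-context
label with precedence CGI > shore > open sea. The precedence rules exist
because percentage breakdowns require mutually exclusive bins.

## Bayesian expression regression

Per annotated gene *i*:

    DGE_i = Methy_i·β_methy + TSG_i·β_tsg + β_seg[GS_i] + ε_i,   ε_i ~ N(0, σ²)

- `DGE`: log2 fold change from a DESeq-style table;
- `Methy`: signed mean methylation difference (percentage points) of the
  gene's hosting DMR (the DMR with the largest overlap of the gene's
  promoter/transcript; segment label = the finest segment class with the
  largest overlap, ties alphabetical, falling back to "gene body");
- `TSG`: binary membership in the TSG list;
- `GS`: one indicator per retained segment (cell-means coding, no global
  intercept), so each segment coefficient is directly that segment's
  baseline differential expression. `Methy` and `TSG` enter once with
  shared coefficients.

Segments with fewer than `min_segment_n` rows (default 50) are dropped and
recorded — with few observations a segment's cell mean is not estimable
and would destabilize the comparison. The variant model appends `HPRO`,
the binary hyper/hypo indicator derived from sign(Methy); rows with
Methy = 0 are excluded there because their status is undefined. Since the
signed Methy covariate already carries this information, the Bayes factor
is expected to prefer the base model — the model-recovery check confirms
it does on data generated without any HPRO effect.

**Priors** (semi-conjugate, proper): β ~ N(b0, B0⁻¹) with b0 = 0,
B0 = 10⁻⁴·I, and σ⁻² ~ Gamma(c0/2, d0/2) with c0 = d0 = 0.002. Weak but
proper — propriety is required for the marginal likelihood to exist. All
configurable.

**Gibbs sampler.** Two blocks, alternating exact conditional draws:
β | h ~ N(m, Pᵇ⁻¹) with P = B0 + h·XᵀX and P·m = B0·b0 + h·Xᵀy;
h = σ⁻² | β ~ Gamma((c0+n)/2, (d0+‖y−Xβ‖²)/2) (rate form). Default
schedule 10,000 iterations with 1,000 burn-in, which the parameter-recovery
checks show is ample for this conjugate-structure model; a `paper` preset
runs 500,000/1,000 for users who want a long chain. Reproducible under a
seed; draws are refused if the design is rank deficient.

**Chib marginal likelihood.** The single-point identity at the posterior
mean (β*, h*):

    log m(y) = log p(y|β*,h*) + log p(β*) + log p(h*) − log p̂(h*|y) − log p(β*|h*,y)

with p̂(h*|y) the Rao-Blackwellised average of the Gamma full conditional
over retained β draws and p(β*|h*,y) the exact Gaussian full conditional.
Because β's conditional given h* is available in closed form in this
two-block sampler, no reduced run is needed. The estimate is refused with
fewer than 1,000 retained draws. Verified against 2-D quadrature of the
joint on a 4-observation problem (agreement well under 0.05 nats).

**Model comparison.** Posterior model probabilities under equal prior odds
are exp(LML_k − logsumexp(LML)), stable at |LML| ~ 10³. Candidate models
must be fitted on identical row sets or the comparison is refused.

**Summaries.** Per-coefficient medians and central (equal-tailed) 95%
intervals from linear-interpolation percentiles.

## TF–methylation interplay

Promoter windows are TSS ± 1,000 bp. A window is "bound" for a (cell, TF)
combination as soon as any peak overlaps it by ≥ 1 base; all the window's
CpGs with coverage ≥ 10 contribute their methylation proportions.

The **background** aggregates proportions over *all* combinations, clamps
to [ε, 1−ε] (ε = 10⁻⁶) and fits a Beta distribution by the method of
moments (k = m(1−m)/v − 1, α = mk, β = (1−m)k), with an optional MLE
refinement. A tested combination's own values stay inside the aggregate
(no leave-one-out), a deliberate conservatism: if many combinations are
strongly shifted, the single-Beta background fits the aggregate poorly and
the test over-rejects. The fit is refused when v ≥ m(1−m) (outside Beta
support) or with < 100 values.

Each combination with ≥ `min_sites` (default 50) measured CpGs is tested
with a one-sample K-S statistic D = sup |ECDF − BetaCDF| (both one-sided
gaps at every jump), p from the asymptotic Kolmogorov distribution at
√n·D. BH correction runs across tested combinations only. Classes:
*highly-differentiated* (adjusted p ≤ 0.05), *lowly-differentiated*
(tested, adjusted p > 0.05), *null* (too few sites or no peaks). The
`min_sites` cutoff defines the null/gray class; 50 CpGs is roughly the
point below which the asymptotic K-S p and the Beta fit both degrade.

## Synthetic data generator

The generator produces the statistical structure the pipeline assumes,
with full ground truth, and nothing more.

- **Site catalogue.** One set of CpG positions shared by all cell types
  (RRBS enriches the same MspI-fragment loci across samples); per-cell
  missingness by independent dropout (default 10%). Every planted DMR is
  guaranteed its requested number of shared sites.
- **Methylation landscape.** Each cell has a beta-mixture spec (uni-, bi-
  or tri-modal). One latent uniform quantile is drawn per ~1 kb region
  block (with small per-site jitter, σ = 0.02 on the quantile scale) and
  pushed through each cell's mixture quantile function. This comonotone
  coupling keeps each cell's marginal modality while making cells with
  identical specs identical in their latent methylation — so with no
  planted DMRs the between-cell null is calibrated. The block structure
  emulates the regional autocorrelation of real methylomes; without it,
  pooled window counts suffer Simpson's-paradox artifacts (independent
  per-cell coverage re-weights heterogeneous sites) and no window test
  could be calibrated.
- **Counts.** Coverage ~ negative binomial (mean 30, dispersion 5 by
  default, floored at 1) — deep and shallow sites both occur, so the
  ≥ 10-read filter is exercised; methylated counts ~ Binomial(coverage, p)
  with p clamped to [0.01, 0.99] so the downstream Beta fit never sees
  exact 0/1.
- **Planted DMRs.** An interval, target cell, direction, effect size and a
  regional baseline (default 0.2 for hyper, 0.8 for hypo). All cells share
  the baseline inside the interval; the target cell is shifted by the
  effect. Effect ≥ 0.4 at coverage 30 with ≥ 8 CpGs is recoverable by the
  DMR caller with ≥ 90% success.
- **Expression.** Genes receive a signed methylation difference (uniform
  magnitude 20–80 points), a TSG flag and a segment; log2FC is exactly the
  linear predictor plus recorded Gaussian noise. DESeq-style p-values are
  emulated from the standardized effect — they make the table well-formed,
  not a model of count noise.
- **TF peaks.** Each (cell, TF) combination either samples its window CpG
  methylation from the background Beta or from a shifted Beta; a
  configurable fraction emits no peaks ("no-data"). Windows are assigned
  without replacement within a cell so re-extraction from the emitted
  CpG records reproduces each combination's values exactly.

**What the generator does not emulate:** read-level data (no FASTQ, no
bisulfite-conversion errors), sequence composition (no real CpG spacing or
island sequence), biological covariation between methylation and
expression beyond the linear model, replicate structure, and count noise
in expression. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated models, not performance on real
ENCODE-scale data — genome-scale counts from the original compendium
(e.g. total DMC/DMR tallies) depend on data this repository does not
ship.

## Numerical choices

- BH adjustment delegates to `statsmodels` (`fdr_bh`); Fisher tests to
  `scipy.stats.fisher_exact` with memoisation over repeated tables.
- Interval algebra is exact integer arithmetic on merged, sorted,
  half-open interval arrays; all coordinates are 0-based half-open
  internally, 1-based only at the methylKit TSV boundary.
- methylKit `freqC` is a percentage of limited precision: methylated
  counts are reconstructed by rounding half away from zero, and rows with
  freqC+freqT off 100 by more than 0.5 are rejected with their line
  number.
- KDE modality uses a Gaussian KDE (Silverman bandwidth by default) on a
  grid spanning [−0.05, 1.05] truncated to [0, 1], which suppresses
  boundary-artifact modes; modes are maxima with prominence ≥ 5% of the
  global peak. Degenerate (zero-variance) input is refused.
- Gibbs draws use Cholesky factorisations of the conditional precision; a
  non-PD precision raises with the iteration index.
- Percentiles are linear-interpolation; ties in K-S input are handled by
  ECDF right-continuity.
- Problem sizes in the test-suite simulations (e.g. 2,000-site catalogues,
  10,000-iteration chains, 20–50 replicates) were chosen as the smallest
  sizes at which the monitored quantities are stable; all are parameters.

## Known limitations

- Strands are never merged before analysis (a merge toggle exists,
  default off); whether CpG dinucleotide strands should be pooled is
  data-dependent.
- The window/tiling DMR construction cannot resolve sub-window boundaries;
  merged DMRs inherit window granularity.
- The no-leave-one-out background makes the K-S classification
  conservative when shifted combinations dominate the aggregate.
- Selection probabilities compare exactly the models supplied; they do not
  average over model space.
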
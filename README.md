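# methintegrate

Integration of DNA methylation, gene expression and transcription-factor
binding across cell types, for regulatory epigenomics analyses in which
one cell type serves as the reference: which genomic regions are
differentially methylated *specifically* in that cell type, how does that
methylation sit relative to CpG islands, shores and promoters, how does it
relate quantitatively to differential expression and tumor-suppressor-gene
(TSG) status, and which TF–cell-type combinations bind promoters whose
methylation departs from the genome-wide background?

The package is a library (`src/methintegrate/`) plus numbered analysis
drivers (`analysis/01…06`) that run the whole story on a synthetic
multi-cell-type compendium with known ground truth, so every stage is
exercisable without any download.

## What it computes

1. **Cell-type-specific differential methylation.** Per-CpG Fisher exact
   tests (coverage ≥ 10, |Δ| ≥ 25 points, BH q ≤ 0.01) define DMCs;
   1-kb tiling windows with pooled-count tests define DMRs (candidate:
   |Δ| ≥ 20, q ≤ 0.01; significant: q ≤ 0.001 and ≥ 5 DMCs). The specific
   set of reference cell *i* is the set deduction

       DMR̂_i = DMR_i \ ⋃_{j≠i} DMR_j

   removing any reference DMR that overlaps (≥ 1 bp) another cell's DMR.
2. **Six-region partition.** With promoters P (TSS ± 1 kb), islands CGI
   and shores S (1-kb island flanks): I = CGI∖P, II = S∖P, III = CGI∩P,
   IV = S∩P, V = P∖CGI, VI = P∖(S∪CGI), plus per-feature CpG assignment
   and DMR–TSG segment overlap (promoter, 5′UTR, 3′UTR, CDS, intron).
3. **Bayesian Gaussian regression** of differential expression on
   methylation, TSG status and genomic segment,

       DGE_i = Methy_i·β₁ + TSG_i·β₂ + β₃(GS_i) + ε_i,  ε_i ~ N(0, σ²),

   with semi-conjugate priors β ~ N(b₀, B₀⁻¹), σ⁻² ~ Gamma(c₀/2, d₀/2),
   fitted by Gibbs sampling; Chib single-point log marginal likelihoods
   give Bayes-factor selection probabilities between the base model and a
   variant adding the binary hyper/hypo indicator HPRO.
4. **TF–methylation interplay.** Promoter-window (TSS ± 1 kb) CpG
   methylation under ChIP peaks, aggregated over all (cell, TF)
   combinations, is fitted with a Beta background (method of moments);
   each combination is K-S-tested against the background CDF and
   classified highly-differentiated (BH-adjusted p ≤ 0.05),
   lowly-differentiated, or null (too few sites).

Formats: methylKit-style CpG TSV, Bismark-coverage bedGraph, BED6,
refFlat, DESeq-style TSV, plain gene lists. See `docs/methods.md` for the
models, priors, defaults and limitations.

## Worked example

```bash
cd analysis
python 01_simulate_compendium.py   # 4 cell types, planted DMRs, expression, TSGs
python 03_differential_methylation.py
python 05_expression_model.py
```

The simulation plants six DMRs for reference cell `cellB` and generates
expression from the regression model with known coefficients
(β_Methy = −0.01 per point, β_TSG = 0.4, σ = 0.5). The drivers print, among
other lines:

```
== cell-type-specific DMRs by set deduction ==
4 DMRs specific to cellB (0 removed for overlapping another cell's DMRs); ...

== posterior summaries (median [95% CI]) ==
  coefficient  median   ci_lo   ci_hi
        Methy -0.0095 -0.0102 -0.0088
          TSG  0.3682  0.2773  0.4591
...
== Bayes-factor model selection ==
    model  log_marginal_likelihood  selection_probability
     base                -575.2669                 0.9987
base+HPRO                -581.9100                 0.0013
```

i.e. the planted reference-specific DMRs survive the deduction, the
posterior recovers the generating coefficients (the Methy and TSG medians
sit on the truth within their intervals), and the Bayes factor rejects the
redundant HPRO term — the signed methylation covariate already encodes
hyper/hypo status. The same stages are scriptable via the `methintegrate`
CLI (`methintegrate all --seed 1 --out-dir out/`), whose thresholds all
live in a flat key-value config (`methintegrate write-config cfg.txt`).

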
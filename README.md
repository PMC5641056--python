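# oncopass

Large structural variants in tumor genomes amplify or delete whole
chromosomal segments, dragging along hundreds of *onco-passenger* genes
that happen to neighbor a driver oncogene (ERBB2, MYC, CCND1, ...).
`oncopass` is a Python toolkit for asking what happens to those
passengers: whether their mRNA expression follows their copy number,
whether DNA methylation compensates when it does not, and what either
regime implies for patient survival and pathway activity.

The package implements the full analysis chain over four omic layers
(SNP-array segmentation, RNA-seq normalized counts, methylation-array
beta values, clinical follow-up), plus a synthetic-cohort generator with
planted ground truth so every stage can be validated offline.

## The analysis

1. **Segment → gene copy number.** SEG-format segmentation is mapped to a
   gene × sample log-ratio matrix by length-weighted averaging of segment
   means over each gene body. Genes are called *gain* when their
   90th-percentile log-ratio across patients exceeds 0.50 and *loss* when
   the 10th percentile is below −0.50; constitutively silent genes
   (≤ 30 normalized counts in more than 90% of samples) are dropped.
2. **Dosage coupling (CR classification).** For each gene, Pearson's *r*
   between its own CNV and its own log2(count+1) expression. Across
   frequently altered genes this distribution is bimodal; the cutoff is
   the valley of a Gaussian KDE between the two modes (empirically near
   *r* = 0.4, which also serves as the fallback). Genes above the cutoff
   are **CR-high** (expression tracks dosage), the rest **CR-low**
   (expression uncoupled from dosage).
3. **Profiles and enrichment.** For an index oncogene, genome-wide
   co-amplification (CNV–CNV) and co-expression (CNV–mRNA) profiles, their
   concordance, and a hypergeometric test of whether genes overexpressed
   in index-amplified samples are simply the co-amplified ones.
4. **Methylation compensation.** Per-gene CNV–beta correlations and their
   coherence (Spearman ρ, OLS slope) with CNV–mRNA correlations. A
   negative relationship is the signature of compensation: amplified
   CR-low genes hypermethylate (suppressing the extra copies) while
   amplified CR-high genes hypomethylate.
5. **Survival screening.** A univariate Cox proportional-hazards model per
   gene (partial likelihood maximized by Newton–Raphson with Efron tie
   handling, covariate = standardized log2 expression), then a
   stratification of the dosage correlation by Cox z bands (poor: z > 2;
   better: z < −2) and Kaplan–Meier splits for single genes.
6. **Pathway Flux.** Dosage correlations are transformed by
   f(x) = 2^(x − 0.4) into positive walk-bias values centered at 1, a
   random walk with restart biased by those values is run on a gene
   interaction network, and each pathway (GMT gene set) is scored by the
   stationary flux through its members and internal edges against a
   degree-binned membership-permutation null.

## Worked example

```python
from oncopass import (SimulationConfig, simulate_cohort,
                      per_gene_dosage_correlation, classify,
                      coamplification_enrichment,
                      cnv_methylation_correlation, coherence,
                      cox_per_gene, stratify_by_cr)

cfg = SimulationConfig(n_samples=300, cr_low_fraction=0.3, seed=1)
cohort, truth = simulate_cohort(cfg)
amp = truth.amplicon_genes()

r = per_gene_dosage_correlation(cohort, gene_set=amp)
cr = classify(r)
print(f"valley cutoff: r = {cr.cutoff:.3f} ({cr.cutoff_source})")
print(f"CR-high: {len(cr.genes('CR-high'))}  CR-low: {len(cr.genes('CR-low'))}")

enr = coamplification_enrichment(cohort, "G00100")
print(f"co-amplification enrichment: {enr.n_overlap}/{enr.n_overexpressed} "
      f"overexpressed genes co-amplified (P = {enr.p_value:.2e})")

meth = cnv_methylation_correlation(cohort, gene_set=amp)
rho, slope = coherence(meth.table["cnv_meth_r"], r)
print(f"CNV-meth vs CNV-mRNA coherence: Spearman rho = {rho:.2f}, slope = {slope:.2f}")

cox = cox_per_gene(cohort, gene_set=amp)
summary = stratify_by_cr(cox, cr.table)
poor, better = summary.groups["poor"], summary.groups["better"]
print(f"Cox screen: median r = {poor['median']:.2f} in poor-survival genes "
      f"(z > 2, n={poor['n']}) vs {better['median']:.2f} in better-survival "
      f"genes (z < -2, n={better['n']})")
```

prints

```
valley cutoff: r = 0.342 (valley)
CR-high: 170  CR-low: 73
co-amplification enrichment: 57/57 overexpressed genes co-amplified (P = 3.57e-76)
CNV-meth vs CNV-mRNA coherence: Spearman rho = -0.82, slope = -2.50
Cox screen: median r = 0.75 in poor-survival genes (z > 2, n=108) vs 0.01 in better-survival genes (z < -2, n=7)
```

Reading this: the density valley lands near the canonical 0.4; all genes
overexpressed alongside the simulated driver amplification are themselves
co-amplified passengers; methylation coupling runs opposite to expression
coupling (compensation); and the genes whose expression predicts poor
survival are overwhelmingly the dosage-coupled (high-*r*) ones, as
planted.

## Command line

Every stage is also exposed as a subcommand of `oncopass`:

```
oncopass simulate --seed 3 --out cohort/
oncopass classify --cohort cohort/ --scope gain-only --out cr.tsv
oncopass enrich --cohort cohort/ --index G00100
oncopass methylation --cohort cohort/ --policy best_abs --out meth.tsv
oncopass survival --cohort cohort/ --out cox.tsv
oncopass netflux --network net.tsv --values cr.tsv --gmt sets.gmt --out flux.tsv
oncopass run --config pipeline.yaml     # full pipeline with a manifest
```

`oncopass run` writes one TSV per stage plus a JSON manifest (config,
config hash, seed, version) and is byte-reproducible for a fixed seed.

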
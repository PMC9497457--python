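# m6apat

Molecular-pattern discovery and diagnostic modelling for epitranscriptomic
regulator studies in case/control transcriptomes.

Bulk expression studies of RNA-methylation regulators — the writers
(methyltransferases), erasers (demethylases) and readers (binding proteins)
of N6-methyladenosine (m6A) and 5-methylcytosine (m5C) — typically chain the
same analyses: merge multi-batch microarray cohorts, remove batch effects,
test regulators for differential expression, build a penalized diagnostic
model, cluster cases into molecular patterns, profile the immune
microenvironment per pattern, pull in correlated lncRNAs, detect
co-expression modules and summarize each patient with a signature score.
`m6apat` packages that chain as a tested, reusable Python library with a
synthetic-cohort generator so every stage can be validated against known
ground truth without any external download.  The shipped catalogs cover the
26 m6A regulators (9 writers / 3 erasers / 14 readers) and 14 m5C
regulators (10 / 3 / 1) used throughout this literature, plus the published
14-regulator and 8-lncRNA diagnostic signatures.

## Methods at the core

- **Batch harmonization** — parametric empirical-Bayes location/scale
  adjustment per gene (ComBat-style): standardize, estimate per-batch
  (γ̂, δ̂²), shrink toward moment-matched priors, remove and restore the
  grand mean.
- **Diagnostic model** — univariate logistic screen (Wald p < 0.05), then
  L1-penalized logistic regression solved by cyclic coordinate descent on a
  100-point λ path with stratified 10-fold cross-validation on binomial
  deviance (selection at λ_min), then an unpenalized multivariate fit
  reporting OR = e^β with Wald 95% CIs, ROC/AUC with DeLong CI (C-index =
  AUC for a binary outcome) and Hosmer–Lemeshow calibration.
- **Consensus clustering** — 1 − Pearson average-linkage hierarchical
  clustering of subsampled case sets; consensus(i,j) = co-clustered /
  co-sampled; K chosen by the lowest proportion of ambiguously clustered
  pairs, PAC = F(0.9) − F(0.1) of the consensus CDF.
- **Set-level scoring** — ssGSEA (rank-weighted running-sum integral,
  α = 0.25, global max−min normalization) and GSVA (Gaussian-kernel CDF
  statistic, bandwidth s/4, KS-like walk, signed max-deviation score) for 23
  immune-cell and 17 immune-reaction signatures; Wilcoxon / Kruskal–Wallis
  group reports with Benjamini–Hochberg control.
- **lncRNA linkage** — a lncRNA is modification-related when |r| > 0.4 and
  p < 0.001 against ≥ 1 regulator; the m6A and m5C sets are intersected.
- **Co-expression modules** — unsigned adjacency |cor|^β, topological
  overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
  average-linkage tree with a static largest-gap cut, module eigengenes
  (first PC, positive mean loading) and eigengene–trait correlation.
- **m6Ascore** — per-sample score = PC1 + PC2 of the standardized
  pattern-related gene profile, with median/mean high–low splits.

## Worked example

```bash
m6apat init-config --out demo.yaml
m6apat all --config demo.yaml --outdir demo --seed 7
```

simulates a 120-case / 60-control cohort in 3 batches and runs every stage,
printing per-stage summaries:

```
"diagnose": { "n_screened": 24, "n_selected": 14, "auc": 1.0,
              "hosmer_lemeshow_p": 1.0 },
"cluster":  { "chosen_k": 3, "low_confidence": false },
"lncrna":   { "n_m6a": 24, "n_m5c": 24, "n_dual": 12 },
"modules":  { "n_pattern_genes": 91, "n_modules": 1, "power": 6 },
"score":    { "omnibus_p": 2.3e-18, "n_signature_genes": 91 }
```

Reading: 24 of 26 m6A regulators pass the univariate screen and the LASSO
keeps 14 of them; the fitted model separates cases from controls perfectly
on this synthetic cohort (AUC 1.0) and is well calibrated (H–L p = 1.0).
Consensus clustering picks K = 3 — the number of planted patterns — and the
PAC table written to `demo/consensus_pac.tsv` shows why (PAC = 0.16, 0.02,
0.05, 0.08 for K = 2..5).  24 of 60 lncRNAs correlate with m6A regulators,
24 with m5C, 12 with both.  91 genes separate the patterns and feed the
m6Ascore, which differs strongly across patterns (Kruskal–Wallis
p ≈ 2×10⁻¹⁸); per-sample scores and high/low groups are in
`demo/m6ascore.tsv`, and `demo/alluvial_crosstab.tsv` cross-tabulates
subtype × pattern × score group for an alluvial plot.

Every stage is also callable as a library function
(`m6apat.diagnostics.lasso_logistic_cv`, `m6apat.consensus.select_k_and_label`,
`m6apat.enrichment.ssgsea_scores`, ...) or as an individual subcommand
(`simulate`, `preprocess`, `diagnose`, `cluster`, `enrich`, `lncrna`,
`modules`, `score`).

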
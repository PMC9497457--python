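# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, the design decisions that were genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Synthetic cohort model

Expression is Gaussian on the log2 scale, matching post-RMA microarray data
well enough for the rank-based and linear methods used downstream.  For gene
g and sample s:

    x_gs = μ_g + planted effects + δ_{g,b(s)} · ε_gs + γ_{g,b(s)}

with baselines μ_g ~ U(4, 10), noise ε ~ N(0, noise_sd²), per-gene per-batch
location shifts γ ~ N(0, batch_shift_sd²) and multiplicative dispersions
δ = exp(N(0, batch_scale_sd²)) applied to the biological residual — exactly
the location/scale model the batch correction assumes.

Planted structure:

- **Diagnostic signal**: `n_diagnostic` randomly chosen m6A regulators gain
  `case_effect` log2 units in every case.
- **Patterns**: cases are assigned to `n_patterns` latent subgroups in a
  balanced, shuffled way (near-equal sizes keep the subgroups exchangeable;
  shuffling decouples pattern from the cyclic batch assignment).  The
  regulator panel is split into equal-size disjoint blocks, one per pattern,
  elevated by `pattern_effect` in that pattern's samples; leftover
  regulators carry no pattern signal.  Controls carry no pattern.
- **Immune signatures**: 23 immune-cell and 17 immune-reaction gene sets are
  allocated disjoint gene blocks; two cell sets and one reaction set per
  pattern are elevated by `immune_effect` in that pattern, the rest stay at
  background.
- **lncRNAs**: a linked lncRNA is built as r·z + √(1−r²)·ε from the
  standardized target regulator row, so its Pearson correlation with the
  target is `lncrna_link_r` in expectation.  Linked lncRNAs cycle through
  m6A-only, m5C-only and dual targets; a dual lncRNA is built from the sum
  of one standardized regulator of each modification with the noise weight
  solved so the correlation with *each* target is again r.

Defaults mirror the merged study design: 196 cases, 89 controls, 5 batches,
26 regulators, 3 patterns.  Effect sizes: `case_effect = 1.5` and
`lncrna_link_r = 0.6` (the values the recovery experiments stipulate),
`pattern_effect = 2.0`, `noise_sd = 0.5` on the crisp end of plausible
post-RMA per-gene dispersions, `batch_shift_sd = 0.5`,
`batch_scale_sd = 0.2` — mid-sized batch effects for arrays processed in
separate series.  Pattern sizes are near-equal by design; observed cohorts
can be far more lopsided, which makes every recovery task harder (see
Limitations).

What the generator does **not** emulate: probe-level noise, intensity-
dependent variance, correlated background genes, annotation errors, or
clinically realistic subtype–pattern dependence (subtypes are assigned at
random).  Passing recovery tests therefore demonstrates that the machinery
is correct and well-calibrated, not that effect sizes of this magnitude
occur in real cohorts.

## Batch correction

Parametric empirical-Bayes location/scale adjustment with batch as the only
factor (no covariate protection — the default use of the cited approach, and
the conservative choice when group/batch composition is unknown).  Per gene:
standardize by the grand mean and the pooled within-batch variance; estimate
per-batch location γ̂ and scale δ̂²; shrink γ̂ toward a normal prior and δ̂²
toward an inverse-gamma prior, both moment-matched across genes, iterating
the two posterior equations to relative tolerance 1e-6; remove, rescale, and
restore the per-gene grand mean exactly.  Zero-variance genes are left
unadjusted with a warning rather than aborting the pipeline.  The
implementation agrees with an independent ComBat implementation to
max |Δ| < 0.01 on planted-offset data.

Two properties worth knowing:

- EB shrinkage leaves a residual batch-mean gap when *every* gene shares one
  offset (the across-gene prior variance collapses); with per-gene offsets —
  the realistic case and what the generator produces — the post-correction
  gap is ~0.02 log2 units against a planted 2.0.
- Because estimated batch means are removed almost exactly, the
  post-correction batch ANOVA F is *below* its null expectation (≈0.07, not
  ≈1).  The correction can only be tested as "not inflated", never as
  "exactly nominal"; any standard ComBat behaves the same way.

## Differential testing

Two-group comparisons are two-sided Mann–Whitney tests with midranks, exact
enumeration when both n ≤ 8 without ties and a tie/continuity-corrected
normal approximation otherwise; ≥3 groups use Kruskal–Wallis.  "Adjusted p"
always means Benjamini–Hochberg within the named family.

The moderated-t differential-expression test pools the two-group residual
variance and shrinks it toward a scaled inverse-chi-square prior (d₀, s₀²)
fitted by moment-matching on log variances (trigamma inversion by Newton's
method); the statistic is t on d₀ + n − 2 degrees of freedom, z when d₀ is
infinite, and exactly the ordinary equal-variance t when d₀ = 0.  DEGs
require |log2FC| > 1 and BH-adjusted p < 0.05, with log2FC the difference of
group means on the log2 matrix.  Pattern-related genes are the union of the
pairwise DEG sets across patterns.

## Diagnostic model

Stage 1 screens each regulator with a single-predictor logistic fit
(IRLS, tolerance 1e-8, ≤100 iterations) at Wald p < 0.05; perfectly
separating features are flagged (diverging coefficient or exploding SE) and
kept with a warning, since separation is evidence of signal, not absence.

Stage 2 is L1-penalized logistic regression, solved by an outer IRLS
quadratic approximation with inner cyclic coordinate descent using
covariance updates, on features standardized inside the solver, over a
100-point λ grid log-spaced from λ_max = max|X'(y−ȳ)|/n down four decades,
warm-started along the path.  Model size is chosen at the λ minimizing the
stratified 10-fold cross-validated binomial deviance (λ_min rather than
1-SE: with ~26 candidate features, 1-SE routinely collapses to very few
features; λ_min matches the regime in which roughly half the panel is
retained).  The Gaussian-loss coordinate-descent primitive is exposed
separately and verified against the soft-threshold closed form on
orthonormal designs; the logistic path is verified against an independent
L1 solver to 5e-3.

Stage 3 refits the selected features without penalty (IRLS via GLM, which
survives quasi-separation with finite but large SEs; a warning marks the
Wald intervals unreliable in that case) and reports OR = e^β with Wald 95%
CIs, AUC by the midrank Mann–Whitney formula with a DeLong 95% CI, C-index
(= AUC for binary outcomes) and the Hosmer–Lemeshow χ² over deciles of risk
(χ² = Σ (O−E)²/(E(1−E/n_g)), df = g−2; zero-expected groups merge into a
neighbor; g < 3 is rejected as zero-df).  External validation applies frozen
coefficients only.

On the synthetic defaults the training task is nearly separable (1.5 log2
units against noise 0.5 on ten genes), so training AUC ≈ 1 and coefficient
magnitudes are boundary-limited; held-out AUC on independently generated
cohorts is the meaningful number (~0.96 averaged over seeds).

## Consensus clustering and PAC

For each K: subsample ⌈p_item·n⌉ case samples without replacement (1000
repetitions by default), cluster by average linkage on 1 − Pearson
correlation between samples, cut to K; consensus(i,j) = co-clustered /
co-sampled (never co-sampled pairs score 0 with a warning).  Gene rows are
median-centered before the distance — the usual preparation so that
inter-sample correlation reflects relative profiles, not the shared
baseline.  PAC is the empirical-CDF mass of strictly-upper-triangle
consensus values in (0.1, 0.9]; the chosen K minimizes PAC with ties going
to the smaller K (parsimony); final labels come from average-linkage
clustering of 1 − consensus.  A run whose best PAC exceeds 0.5 is flagged
low-confidence.

An important regime effect: when cluster separation vastly exceeds
within-cluster spread, the K = 2 merge is the *same* in every subsample, so
PAC(2) = PAC(3) = 0 and the parsimony tie-break picks K = 2.  PAC
discriminates the true K only when resampling actually perturbs the merge
order — moderate separation, exchangeable (equal-size, equal-effect)
clusters, and enough subsample variation.  The recovery experiment is
therefore run at noise_sd = 1.0, pattern_effect = 2.0 and p_item = 0.5
(half-sampling roughly doubles resampling variation); in that regime the
planted K = 3 is chosen with ARI = 1.0 across seeds, with PAC(2) ≈ 0.2–0.7
and PAC(3) ≈ 0.  The module default stays at the conventional p_item = 0.8.

## Sample-wise gene-set scoring

ssGSEA: per sample, genes get midranks (top gene = N); walking down the
ranking, in-set genes add rank^α / Σ_set rank^α (α = 0.25) and out-set genes
subtract 1/(N−|S|); the score is the sum of the running walk (its integral).
With normalization the entire score matrix is divided by its global
max − min, so the output range is exactly 1.  Scores are rank-based and
hence invariant to any strictly monotone per-sample transform.  Ordering
agreement with an independent ssGSEA implementation exceeds Spearman ρ 0.8
on planted-signal fixtures.

GSVA: per gene, a Gaussian-kernel CDF across samples (bandwidth = sample
SD/4) converts expression to a relative statistic; per sample, genes are
ranked by it and weighted by |N/2 − rank|^τ (τ = 1); a KS-like walk gives
score = max positive + max negative deviation (the signed-difference
variant, more interpretable for two-sided contrasts).  Genes constant
across samples carry zero walk weight — they are uninformative, and this
makes all-constant inputs score exactly 0.

## lncRNA linkage

Pearson r for every lncRNA × regulator pair of a modification, p from
t = r√((n−2)/(1−r²)); retain a lncRNA iff ≥1 pair has |r| > 0.4 and
p < 0.001, strict inequalities; all passing pairs are stored, and the m6A
and m5C sets intersect to the dual list.  Under the null the per-pair pass
probability is min(0.001, P(|r| > 0.4)) — at n = 50 the p-threshold binds
and per-lncRNA retention is 1 − 0.999^26 ≈ 0.026, which the null
calibration experiment reproduces within Monte-Carlo error.

## Co-expression modules

Top-25%-variance genes; unsigned adjacency |cor|^β.  β is the smallest
power whose connectivity distribution fits a scale-free line at signed
R² ≥ 0.85; when no power qualifies (planted-block fixtures are not
scale-free) the fallback is the sample-size convention for unsigned
networks (β = 6 for n ≥ 40) rather than the R²-argmax, which lands at
extreme powers and degrades recovery.  TOM similarity, average linkage on
1 − TOM, and a static cut at the midpoint of the largest gap in the upper
half of sorted merge heights — a fixed quantile cannot be right for every
block count, while the widest gap separates within-module from
between-module merges whenever coherent modules exist (a fixed-quantile cut
remains available as a parameter).  Clusters must have ≥ `min_module_size`
genes *and* mean within-cluster TOM ≥ 1.5× the global off-diagonal mean;
everything else is module 0, so structureless data is left unassigned
rather than wrapped into one giant pseudo-module.  Eigengenes are the first
PC of the standardized module, sign-fixed to positive mean loading, and are
correlated against trait indicator vectors.

## m6Ascore

Signature-gene rows are centered and (by default) scaled to unit variance —
so no single high-variance gene dominates — and a PCA over samples yields
score_s = PC1_s + PC2_s.  Each component's sign is fixed by positive
correlation with the per-sample mean signature expression, making the score
deterministic; both components sum to zero by centering.  High/low groups
split at the median by default (the mean rule is exposed as well, matching
the convention used for single-gene splits).  Group comparisons use the
rank tests above, with BH-adjusted pairwise tests when the omnibus test
rejects.

## Numerical choices

- Logistic IRLS weights floored at 1e-5; linear predictors clipped at ±30
  in the penalized solver.
- Coordinate descent tolerance 1e-6 on coefficient changes, ≤25 outer IRLS
  steps, ≤100 inner sweeps; path warm starts.
- Trigamma inversion by Newton, 50 iterations, relative tolerance 1e-10.
- Pearson-distance matrices are symmetrized and clipped to [0, ∞) before
  linkage; consensus and TOM diagonals pinned to 1.
- Seeds: every stochastic routine takes an explicit seed; nested experiments
  derive child seeds through `numpy.random.SeedSequence`.

## Limitations

- The acceptance experiments run in regimes where each method is
  informative (moderate cluster separation, balanced patterns, planted
  effects ≥ 1.5 log2 units).  Highly unbalanced patterns — e.g. one
  subgroup of a handful of samples — can be missed at K selection even when
  label recovery at the true K would succeed.
- Wald inference after quasi-separation is reported but flagged; penalized
  or exact inference is out of scope.
- The static tree cut with coherence filtering recovers well-separated
  blocks; overlapping or nested modules need a dynamic cut, which this
  package deliberately does not implement.
- Immune-cell and reaction signatures are synthetic stand-ins over
  simulated gene ids; real analyses must supply their own GMT collections.
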
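# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic validation does and does not show.

## Scope and data model

The pipeline operates on a genes × samples matrix of
log2(normalized count + 1) expression values with a two-level group
label (tumor / normal), optionally split into subcohorts (one
platform-matched normal arm and one external normal arm), plus ordinal
tumor stage (I–IV, coded 1–4 everywhere), demographics, and overall
survival (event indicator + time in days) for the tumor arm. Values are
finite and non-negative; a stored 0 means a raw zero count. Genes whose
entries are zero in strictly more than two thirds of samples are
removed before any analysis (the boundary is exact: a gene that is zero
in exactly 2/3 of samples is kept).

## Synthetic cohort generator

The generator draws from a linear-Gaussian structural equation model
over genes plus one binary class node. The Markov blanket of the class
node is planted as 40% parents, 40% children and 20% co-parents
(spouses) of the class node; a single signal gene is a child. Per
sample, genes are simulated ancestrally: baseline (uniform 2–9 log2
units) + class shift (for parents/children) + weighted gene-parent
contributions + Gaussian noise (sd 1), clipped at 0.

Key defaults and why:

- **Cohort shape** 120 tumor / 20 normal-a / 120 normal-b samples,
  40 signal + 960 noise genes: a 1/50-dimensionality analogue of a
  289-tumor / 41 + 307-normal colon cohort, preserving class imbalance
  and the two-source normal structure.
- **Effect sizes** |Δ| ~ U(1.5, 3.5) log2 units with 20% of signal
  genes down-regulated. With unit noise this yields single-gene AUCs of
  roughly 0.93–0.99, matching the discrimination reported for strong
  tumor markers.
- **Batch offset** +0.5 log2 units on a random 30% of genes for
  normal-b samples: the two normal subcohorts overlap but remain
  distinguishable, as a cross-platform normal arm is. Note an inherent
  consequence: because normal-b is class-pure, batch genes are *weakly
  class-dependent* (marginal SNR ≈ 0.2) and are **not** d-separated
  from the class node. The d-separation guarantee — partial correlation
  with the class given the planted blanket → 0 — holds exactly for
  non-batch noise genes and only approximately (|r| ≲ 0.07 at n ≈ 2000)
  for batch genes. A perfectly class-orthogonal batch would require the
  offset to hit tumor and normal arms alike, which would not emulate a
  normal-only external cohort.
- **Zero inflation**: 2% of noise genes are zero-inflated with
  per-entry zero probability 0.8, so the default cohort genuinely
  exercises the zero filter (Binomial(260, 0.8) essentially never stays
  at or below the 2/3 boundary).
- **Stage** is drawn by an ordered-logit model: latent score =
  Σ slopes·z(stage genes) + logistic noise, cut at the latent quantiles
  of the target marginal distribution (0.16/0.40/0.30/0.14 across
  stages I–IV, the stage mix of a typical resected-adenocarcinoma
  cohort). 14 up-regulated signal genes carry stage slopes U(0.4, 0.9).
- **Survival** is exponential proportional hazards: rate =
  h₀·exp(Σ log-HR·z(hazard genes) + log(2.2)·(stage − mean)), h₀ =
  1/1500 events/day, independent exponential censoring at 3·h₀ giving
  a ~25–30% event rate. Three hazard genes carry log HRs (0.7, 0.7,
  −0.7). Because hazard ratios are non-collapsible, the *marginal*
  (univariate) HR of a hazard gene is attenuated when stage
  heterogeneity is present; parameter-recovery checks therefore
  generate with the stage hazard off or adjust for stage.

What the generator does **not** emulate: count-level sampling noise
(RSEM/DESeq2 pipelines), gene–gene co-expression outside the planted
DAG, heavy-tailed or bimodal expression, stage-dependent effect sizes,
and informative censoring. Passing recovery tests therefore show the
pipeline is correct *under its own assumptions* — linear-Gaussian
signals, independent noise genes — not that it is robust to everything
real cohorts do.

## SNR screening

SNR(g) = |u₊ − u₋| / (δ₊ + δ₋) with sample standard deviations
(ddof = 1). Degenerate guard: both sds zero gives 0 for equal means and
+∞ (sorts first) otherwise. Screening keeps the top k = 430 by score,
ties broken lexicographically by gene id so results are independent of
input order; a score-threshold mode exists because a fixed count is
only one way to set the cutoff.

## PPFS selection

A candidate is tested against a context by stratified 5-fold CV of a
40-tree random forest on context ∪ {candidate}; within each validation
fold the candidate's column is permuted 50 times and the score drop
(original − permuted) recorded. The validation score is the negative
log-loss by default: accuracy saturates on well-separated cohorts and
stops registering drops long before the class-conditional information
is exhausted.

**Significance.** Under the null the unpermuted score is exchangeable
with the permuted scores, so its rank within each fold is an exact
one-sided p-value on the grid 1/(K+1)…1; fold p-values are combined by
Fisher's method (χ² with 2·n_folds df). This replaces a t-test over
score drops, which assumes both normality and within-fold independence
of drops; the drops share the fold's unpermuted score and are skewed,
and the t-test was measurably anticonservative in null simulations.
The t-test variants remain available (`test_level="fold"` /
`"permutation"`).

**Trees use every feature.** The forest splits on a single random
feature per node (`max_split_features=1`). With greedy split selection
(`"sqrt"`), trees ignore candidates that are individually weaker than
the context — late-ranked blanket genes and co-parents then show zero
permutation importance no matter how much signal they carry, because
importance can only be attributed to features the model uses. Randomized
splits spread reliance across all features; the exact test keeps its
level for any learner, so this trades no validity for the power gain.

**Permutation scheme.** Marginal column shuffling (the default)
measures the model's reliance on the candidate's actual values. It has
a known blind spot: shuffling also destroys the candidate's correlation
with context features, so a redundant-but-correlated candidate (a noisy
proxy of an admitted gene) registers an off-manifold score drop and can
survive. The `"residual"` scheme addresses exactly this: an OLS fit of
the candidate on the context (estimated on the training fold) splits
the validation column into fitted + residual, and only the residual is
shuffled. This preserves the joint candidate/context distribution and
isolates the candidate-specific signal — the right semantics for
redundancy pruning. It is not the default because conditional signal
decays to nothing once the admitted set saturates the class (the same
reason a faithful conditional-independence test would stop admitting
early); the marginal scheme is what makes full-blanket recovery
possible on strongly separated cohorts.

**Grow/prune.** Grow iterates candidates in SNR rank order, admitting
those significant at α = 0.05 against the current set; prune re-tests
each admitted gene against all other survivors and removes
non-significant ones, sweeping until a pass removes nothing. All
randomness (folds, permutations, forests) derives from the config seed
plus stable per-candidate/per-context digests, so runs are exactly
reproducible and the prune re-test of a gene never reuses the
permutations that admitted it.

Known limitations: co-parents have no marginal signal, so they reach
the test only if the top-k screen happens to include them, and their
conditional signal (explaining-away through a child) is weak — they are
the typical misses in recovery runs. Weakly class-associated batch
genes are the typical false admissions, and they are *correctly*
admitted by the test's own criterion (they do carry class information);
the planted-blanket F1 counts them against the method.

## PC-stable network

Fisher-z partial-correlation CI tests (precision-matrix inversion of
the correlation submatrix; z = ½·ln((1+r)/(1−r))·√(n−|S|−3), two-sided
normal p). PC-stable freezes neighbor sets at the start of each
conditioning level, so the skeleton is independent of node order;
conditioning sets are enumerated lexicographically and the first
separating set is recorded. Defaults α = 0.05, max conditioning size 3
— conventional at n in the hundreds; raising max_cond mainly costs time
once neighborhoods are already thin. Orientation: unshielded triples
i–k–j with k outside sepset(i, j) become colliders; conflicting
collider demands leave the edge undirected and are logged; Meek rules
1–4 close the orientation. The class label can enter as a binary node
through the same machinery (a point-biserial approximation — adequate
for edge detection, not for effect sizes); both with- and without-class
modes are first-class because either is a defensible reading of
"network over the signature".

## Downstream statistics

- **Differential expression**: per-gene two-group linear model with
  pooled variance; empirical-Bayes moderation shrinks gene variances
  toward a prior fitted by matching moments of log s² to a scaled F
  distribution (trigamma inversion by Newton's method); moderated t has
  df + d₀ degrees of freedom. logFC is exactly the difference of group
  means on the log2 scale — the identity logFC = AveExpr(T) −
  AveExpr(N) is what the published reference table reproduces. A Welch
  mode serves as a cross-check; only sign/significance agreement is
  expected, not equal p-values.
- **BH adjustment** delegates to statsmodels' step-up implementation
  (hand-verified against the direct definition in tests).
- **ROC**: AUC equals the Mann–Whitney probability with ties counted ½;
  orientation is flipped when AUC < 0.5 (markers down in tumors score
  by negated expression) and recorded; the operating point maximizes
  Youden's J, reported as sensitivity/specificity percentages with the
  cutoff on the original scale.
- **Embeddings**: centered-SVD PCA with a fixed sign convention
  (largest-|loading| positive); PLS-DA via NIPALS against a one-hot
  class response, scores from the fitted X-rotation.
- **Bi-clustering**: per-gene z-scoring then average-linkage Euclidean
  clustering of rows and columns independently; leaf orders are
  returned for heatmap display.

## Stage and survival

Stage analyses drop missing-stage samples and use Pearson correlation
with the t-transform p-value; "stage-positive" means r > 0 at p < 0.05.
Cox models maximize the Efron-tie partial likelihood (lifelines) with
Newton precision tightened to 1e-11 so coefficients are reproducible
against direct likelihood maximization to ~1e-7. The survival screen is
two-tier: univariate per gene, flagging p < 0.05 (significant) and
0.05 ≤ p < 0.1 (trend); trend-or-better genes enter one joint
multivariate fit. Kaplan–Meier high/low groups split at the cutpoint
maximizing the two-group log-rank statistic over observed values within
the 10–90% quantile band (median fallback); the reported log-rank p is
the plain two-group p at the chosen cutpoint and is therefore optimistic
under cutpoint selection — it mirrors the common display convention, and
readers should treat it as descriptive.

## Numerical conventions

Ties in the SNR ranking break lexicographically; |r| is clipped to 1
with p = 0 at the boundary; probability clipping at 1e-15 bounds
log-loss; constant genes yield SNR 0, undefined correlations are
reported missing with a warning, and constant covariates or event-free
survival data raise typed errors rather than fitting. All stochastic
stages accept one integer seed and are bit-reproducible given it.

## Problem sizes used in validation

Module tests run on an 8-blanket/100-noise cohort (n = 130); the
end-to-end recovery check runs the full default cohort (1000 genes,
n = 260, top-430 screen), which takes a few minutes on one CPU; null
calibration uses 200 pure-noise replicates (n = 200, 20 candidates)
with a compact 3-fold/8-tree configuration, valid because the rank test
is exact at any configuration size. Structure-learning recovery uses
n = 2000 samples on 3- and 10-node graphs with edge weights 0.9.
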
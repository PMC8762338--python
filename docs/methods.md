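# Methods

## The model

`immsub` treats a tumor's immune state as a latent, approximately
one-dimensional quantity — infiltration level — observed through the
coordinated expression of immune-cell marker-gene sets. The analysis has
three stages:

1. **Scoring.** Each sample is summarized by its ssGSEA enrichment score
   for each of a collection of immune signatures (28 immune-cell-type
   marker sets in the bulk workflow; four tumor-cell-intrinsic immune
   pathways in the single-cell workflow). The score is the integrated
   difference between the weighted empirical CDF of in-set genes and the
   uniform CDF of out-of-set genes, walked down the sample's
   decreasing-expression ordering. Only within-sample ranks enter, so the
   statistic is invariant to monotone transforms of a sample's expression
   and needs no cross-sample normalization.
2. **Subtyping.** Samples are points in signature-score space. An
   agglomerative tree (Ward linkage on Euclidean distances over
   per-signature z-scores) is cut at k = 3, and the clusters receive
   *ordered* labels ImH/ImM/ImL by the mean (over member samples) of the
   per-sample mean enrichment score. Ordered labels, not cluster identity,
   are the cross-dataset currency: independently clustered cohorts are
   matched by score level.
3. **Characterization.** The subtypes are contrasted on survival,
   categorical composition (receptor status, grade, stage), mutation and
   copy-number burden, per-gene mutation frequency, differential
   expression and pathway enrichment, with an explicit statistical
   convention for every contrast (below).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.25 | exponent on rank-normalized expression weighting in-set genes; the common ssGSEA convention. 0 gives the unweighted KS-type statistic. |
| `normalize` | off | divide all scores by the global (max − min) so a score matrix spans exactly 1; cosmetic, for heatmap-style comparison. |
| `min_fraction` | 0.5 | a gene set must retain at least this fraction of its genes (and ≥ 2 genes) after intersection with the measured genes; a score over fewer than two genes is meaningless. |
| `distance`/`linkage` | euclidean / ward | most common choice for score matrices; both recorded in every assignment's `linkage_record`. |
| `k` | 3 | number of subtypes; no automatic selection is attempted. |
| `pseudocount` | 0.01 | added before geometric means in the CD8/Treg log-ratio; RNA-seq zeros. |
| DEG gate | FDR < 0.05, FC > 1.5 | both strict inequalities; fold change is a ratio of linear-scale group means (log2 data exponentiated first). |
| mutation screen | `min_mutated` = 10, FDR < 0.15 | genes with fewer mutated samples produce degenerate exact tests. |
| TMB | all variant classes | "total count of somatic mutations"; a nonsynonymous-only switch is provided. |
| SCNA score | `abs_sum` | Σ\|call\| over regions flagged recurrent; `event_count` (number of altered recurrent regions) is the alternative reading. Recurrence is an input flag — it is a cohort-level definition made upstream. |

Statistical conventions: one-tailed contrasts are always oriented "the
higher-labeled subtype has the greater scores" (for SCNA burden, the
orientation is reversed and stated in the output). The rank-vs-t choice is
the caller's; a Shapiro–Wilk helper exists but is never applied silently.
Welch's correction is the t-test default. Standardized logistic βs
multiply each coefficient by its predictor's sample SD only (the
latent-outcome SD is not included). Median splits use strict inequalities
and drop (and report) observations at the median. Exactly tied cluster
means during labeling are broken by cluster size (larger cluster takes the
lower label) with a warning.

## Numerical choices

* ssGSEA ranks use average-rank tie handling; the expression walk breaks
  ties by gene input order (stable sort), so scores are deterministic.
* Fisher's exact test: 2×2 via the closed-form hypergeometric two-sided p;
  2×k by exact enumeration of candidate tables when their number is within
  the enumeration budget (2×10⁵), otherwise a seeded Monte-Carlo estimate
  over multivariate-hypergeometric draws; r×c (r > 2) by seeded label
  permutation. A table is counted as "as extreme" when its probability is
  ≤ the observed table's up to a 10⁻⁹ relative tolerance; with heavily
  tied table probabilities, different tie conventions (e.g. R's 10⁻⁷) can
  shift the p-value in the third decimal. The method string always records
  which path produced the p.
* Mann–Whitney: exact when the pooled sample is ≤ 12 with no ties,
  otherwise the normal approximation with continuity and tie corrections.
  A fully tied pooled sample returns p = 1.
* Spearman: exact permutation p by full enumeration for n ≤ 10 (chunked),
  t approximation above.
* One-way ANOVA with zero within-group variance but nonzero between-group
  variance reports an infinite F, p = 0, and a method flag rather than an
  error.
* Logistic fits use Newton MLE; perfect or quasi-perfect separation is
  reported via `converged = False` (diverged coefficients are never
  returned silently).
* Degenerate inputs error loudly: constant score matrices ("no structure
  to cluster"), gene sets covering every measured gene (undefined
  out-of-set CDF), survival data without events, single-class outcomes.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes — it
is the package's test bed, not a model of any real cohort. Three latent
infiltration levels (low/mid/high, equal proportions by default) drive:

* marker-set genes shifted by `level × marker_shift` (default 2.0)
  within-level SDs on the log2 scale over a log-normal background; the
  regulatory-T-cell set is attenuated (×0.5) so the CD8/Treg log-ratio
  rises with level while both signatures do;
* exponential survival with hazard multipliers 1.0 / 0.7 / 0.45
  (low/mid/high) racing an exponential censor calibrated to a 30%
  censoring fraction;
* Poisson mutation counts with means 20 / 35 / 60 plus three planted
  driver-like genes whose per-level rates echo commonly reported
  breast-cancer values (an increasing TP53-like gene at 24.2/25.7/45.7%, a
  middle-peaked PIK3CA-like gene at 28.1/41.3/28.2%, a decreasing
  GATA3-like gene at 13.1/10.8/5.4%) over a bed of flat 10% genes;
* signed copy-number calls over 60 flagged recurrent regions with event
  probabilities 0.5 / 0.35 / 0.2 (decreasing with level);
* receptor composition skewing TNBC and HER2+ toward the high level and
  HR+ toward the low level, grade/stage/TIL/methylation covariates rising
  with level.

Default problem sizes: 2000 genes with 28 marker sets of 10 genes
(markers ≈ 14% of the transcriptome — keeping the marker fraction small
matters, because ssGSEA scores saturate when most measured genes belong to
shifted sets). The single-cell variant plants the same levels on four
40-gene pathways plus a 19-gene HLA-like block ordered high > mid > low,
then applies **expression-dependent dropout**: the per-entry zeroing
probability starts at `dropout_rate` (default 0.3) at baseline expression
and halves for every log2 unit above it, the standard scRNA-seq
observation that abundant transcripts are rarely missed. Uniform
(expression-independent) zeroing was considered and rejected: at
comparable zero fractions it erases the mid-versus-high pathway-score
contrast that real dropout leaves intact.

What the generator does **not** model: negative-binomial count noise,
library-size and batch effects, doublets, correlated marker sets beyond
the shared latent level, non-exponential hazards, subclonal mutation
structure. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes, at realistic effect sizes — not that it is
robust to every artifact of real data.

## Problem sizes used in validation

The test suite and the acceptance script run the full stack at n = 150–900
samples, 2000 genes and 300 cells, with 50–100 seeded replicates for the
recovery-rate, power and type-I-error checks; these sizes give
Monte-Carlo error comfortably below the margins being asserted while
keeping a complete run in the minutes range on one CPU.

## Known limitations

* The immune score is an ssGSEA statistic over a pooled immune gene list —
  a relative infiltration proxy on the ssGSEA scale, not an absolute
  purity/infiltration estimate, and it will not numerically match
  regression-based estimators trained on curated immune/stromal lists.
* Pathway "enrichment of a DEG list" is the over-representation reading
  (hypergeometric): an unranked gene list carries no ranking to run a
  weighted enrichment walk on.
* Cross-dataset label matching relies on the mean-score ordering; with
  k > 3 or weakly separated clusters the ordering statistic can be
  unstable even when the partition is good.
* No automatic k selection, consensus clustering, or single-sample
  classification of new tumors into an existing subtyping.
* The 2×k exact test's tie convention (above) makes third-decimal
  differences from other implementations possible on near-uniform tables.
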
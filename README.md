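# immsub — immune-signature subtyping of tumor transcriptomes

`immsub` classifies breast-cancer (or other tumor) samples into ordered
immune subtypes — **ImH** (hot), **ImM** (intermediate), **ImL** (cold) —
from bulk or single-cell expression data, and characterizes the subtypes
clinically, genomically and transcriptionally. It is written for
computational biologists who want the whole immune-subtyping workflow as a
tested, scriptable library rather than a collection of one-off analysis
scripts, and it ships a synthetic-cohort generator with full ground truth
so every stage can be validated without access to patient data.

## What it computes

**Single-sample enrichment (ssGSEA).** For each sample, genes are
rank-transformed (average ranks, ties deterministic) and walked in
decreasing-expression order. With in-set weights `w_i = (r_i / N)^alpha`
(rank-normalized expression to the power `alpha`, default 0.25), the score
of gene set *S* is the integrated difference of two empirical CDFs:

    ES(S) = sum over positions j of [ P_in(j) − P_out(j) ]
    P_in(j)  = sum of w_i for in-set genes at positions <= j / sum of all in-set w
    P_out(j) = count of out-of-set genes at positions <= j / (N − |S|)

The statistic depends only on within-sample ranks, so it is invariant to
any monotone transform of a sample's expression (platform- and
normalization-robust).

**Subtype discovery.** Samples are clustered agglomeratively
(Ward/Euclidean by default, on per-signature z-scores) in the space of
their 28 immune-cell-type ssGSEA scores; the tree is cut at *k* = 3 and
clusters are labeled by mean signature score, highest to lowest. Ordering
by score level is what makes labels comparable across independently
clustered datasets. Single cells are subtyped identically on four immune
pathway scores (antigen processing and presentation, PD-L1/PD-1
checkpoint, JAK-STAT signaling, apoptosis).

**Characterization battery.** Kaplan–Meier / log-rank survival comparison;
Mann–Whitney / Student–Welch location tests with explicit one-tailed
orientation (higher subtype > lower subtype); Fisher's exact test (2×2
closed form, 2×k exact enumeration with a seeded Monte-Carlo fallback);
Spearman correlation (exact permutation p for n ≤ 10); one-way ANOVA;
Benjamini–Hochberg FDR; TMB (total mutation count) and SCNA score
(sum of |call| over recurrent regions); standardized-β logistic regression
(β = coefficient × predictor SD); DEG calling (two-tailed t, FDR < 0.05,
fold change > 1.5) with hypergeometric pathway over-representation,
cross-dataset consistency, and one-vs-both-others feature screens.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
import immsub as im

dataset = im.generate_bulk_dataset(im.SyntheticConfig(seed=1, n_samples=150))
scores = im.ssgsea_matrix(dataset.expression, dataset.marker_sets)
assignment = im.subtype_samples(scores, k=3)
print(assignment.labels.value_counts().to_dict())
print({k: round(v, 1) for k, v in assignment.cluster_means.items()})
print(adjusted_rand_score(dataset.truth.levels.values, assignment.labels.values))
```

prints

```
{'ImM': 50, 'ImL': 50, 'ImH': 50}
{'ImH': 857.8, 'ImM': 732.5, 'ImL': 93.3}
1.0
```

Three equal clusters are recovered; the cluster means justify the ordered
labels (ImH highest), and the adjusted Rand index of 1.0 against the
generator's planted infiltration levels means every sample returned to its
true group. The scripts in `examples/` walk one capability each —
subtyping, survival and receptor composition, TMB/SCNA burden and the
logistic model, DEGs and pathways, single-cell mode — and print the
numbers they compute with a note on what they mean. The same workflow is
available from the shell:

```sh
immsub simulate --seed 1 --out-dir data/
immsub run --expression data/expression.tsv --genesets data/markers.gmt \
  --clinical data/clinical.tsv --mutations data/mutations.maf.tsv \
  --cnv data/cnv.tsv --out-dir results/
```

## File formats

Expression: TSV/CSV, genes in rows, first column gene symbols, header of
sample IDs (`#` comment lines ignored). Gene sets: Broad-dialect GMT.
Mutations: MAF-like TSV (`Tumor_Sample_Barcode`, `Hugo_Symbol`,
`Variant_Classification`). Copy number: region × sample TSV of discretized
calls in {−2..2} with a boolean `recurrent` column. Clinical: TSV with
`time`, `event` and free covariate columns.

See `docs/methods.md` for the model, parameter defaults, and known
limitations.
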
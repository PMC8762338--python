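"""Differential analyses across subtypes.

Differential expression between two subtypes (t test + fold change),
hypergeometric pathway over-representation of a DEG list, cross-dataset
pathway consistency, pathway-score vs immune-score correlation,
one-versus-both-others feature screens (proteins, HLA genes), and
categorical composition contrasts (receptor status, grade, stage).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .containers import EnrichmentMatrix, ExpressionMatrix
from .signatures import GeneSetCollection
from .stats import TestResult, bh_fdr, fisher_exact, spearman
from .subtyping import SubtypeAssignment, ordered_labels

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    """Per-gene differential expression between two groups.

    ``table`` columns: mean_a, mean_b (linear scale), fold_change
    (mean_a / mean_b), direction (up_in_a / up_in_b), p, fdr, significant.
    """

    table: pd.DataFrame
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    fc_threshold: float
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def upregulated_in(self, group: str) -> list[str]:
        direction = {"a": "up_in_a", "b": "up_in_b"}[group]
        mask = self.table["significant"] & (self.table["direction"] == direction)
        return list(self.table.index[mask])


def differential_genes(matrix: ExpressionMatrix, group_a, group_b,
                       fc_threshold: float = 1.5,
                       fdr_threshold: float = 0.05) -> DifferentialResult:
    """Call DEGs between two sample groups.

    Per gene: two-tailed Student's t test on the stored scale, BH-FDR over
    all tested genes; fold change is the ratio of linear-scale group means
    (log2 data are exponentiated first). A gene is significant when
    ``fdr < fdr_threshold`` and ``max(FC, 1/FC) > fc_threshold`` — both
    strict. Genes with zero variance in both groups are excluded with a
    warning.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    group_a = [str(s) for s in group_a]
    group_b = [str(s) for s in group_b]
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >=2 samples")
    A = matrix.data.loc[:, group_a].to_numpy(dtype=float)
    B = matrix.data.loc[:, group_b].to_numpy(dtype=float)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    testable = (var_a + var_b) > 0
    if not testable.all():
        logger.warning("excluding %d zero-variance genes", int((~testable).sum()))
    genes = np.asarray(matrix.genes)[testable]
    with np.errstate(all="ignore"):
        tstat, pvals = sps.ttest_ind(A[testable], B[testable], axis=1)
    linear = matrix.to_linear()
    mean_a = linear.data.loc[genes, group_a].mean(axis=1).to_numpy()
    mean_b = linear.data.loc[genes, group_b].mean(axis=1).to_numpy()
    eps = np.finfo(float).tiny
    fc = (mean_a + eps) / (mean_b + eps)
    fdr = bh_fdr(pvals)
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "fold_change": fc,
        "direction": np.where(fc >= 1, "up_in_a", "up_in_b"),
        "p": pvals, "fdr": fdr,
    }, index=pd.Index(genes, name="gene"))
    table["significant"] = (table["fdr"] < fdr_threshold) & \
        (np.maximum(fc, 1.0 / fc) > fc_threshold)
    return DifferentialResult(table=table, group_a=tuple(group_a),
                              group_b=tuple(group_b),
                              fc_threshold=fc_threshold,
                              fdr_threshold=fdr_threshold)


def ora_pathways(deg_list, background, pathways: GeneSetCollection,
                 fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in pathway sets.

    For each pathway (intersected with the background) the upper-tail
    hypergeometric p of the observed overlap with the DEG list is computed;
    BH-FDR is applied across pathways. Columns: overlap_count, set_size,
    deg_size, background_size, p, fdr, significant.
    """
    background = {str(g).strip().upper() for g in background}
    degs = {str(g).strip().upper() for g in deg_list}
    if not degs <= background:
        raise ValueError("DEG list must be a subset of the background")
    if not degs:
        logger.warning("empty DEG list; over-representation table is trivial")
    N = len(background)
    n = len(degs)
    rows = []
    names = []
    for gs in pathways:
        members = set(gs.genes) & background
        if not members:
            continue
        K = len(members)
        k = len(members & degs)
        # P(overlap >= k) under sampling n genes from N with K marked
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"overlap_count": k, "set_size": K, "deg_size": n,
                     "background_size": N, "p": min(p, 1.0)})
        names.append(gs.name)
    out = pd.DataFrame(rows, index=pd.Index(names, name="pathway"))
    if out.empty:
        out = pd.DataFrame(columns=["overlap_count", "set_size", "deg_size",
                                    "background_size", "p", "fdr", "significant"])
        out.index.name = "pathway"
        return out
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def consistent_pathways(per_dataset_results: list[pd.DataFrame]) -> list[str]:
    """Pathways flagged significant in every dataset's table (alphabetical)."""
    if len(per_dataset_results) < 2:
        raise ValueError("need at least two datasets to intersect")
    sets = []
    for table in per_dataset_results:
        if table.empty:
            sets.append(set())
        else:
            sets.append(set(table.index[table["significant"]]))
    return sorted(set.intersection(*sets))


def pathway_immune_correlation(pathway_scores: EnrichmentMatrix,
                               immune_scores: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each pathway's scores with the immune score."""
    shared = [s for s in pathway_scores.sample_ids if s in immune_scores.index]
    if len(shared) < 3:
        raise ValueError("need >=3 samples shared between pathway and immune scores")
    imm = immune_scores.loc[shared].to_numpy(dtype=float)
    rows = []
    for name in pathway_scores.set_ids:
        vec = pathway_scores.scores.loc[name, shared].to_numpy(dtype=float)
        rho, p = spearman(vec, imm)
        rows.append({"rho": rho, "p": p})
    out = pd.DataFrame(rows, index=pd.Index(pathway_scores.set_ids, name="pathway"))
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def one_vs_rest_features(features: pd.DataFrame, assignment: SubtypeAssignment,
                         fdr_threshold: float = 0.05) -> dict[str, list[str]]:
    """Features significantly higher in one subtype than in BOTH others.

    For every feature, all pairwise two-tailed t tests between subtypes are
    run and BH-FDR is applied over the full feature-by-pair family. A
    feature is assigned to a subtype only if both of that subtype's
    pairwise comparisons are significant AND both mean differences favor
    it; at most one subtype can satisfy this, so assignments are disjoint.
    """
    labels_seq = ordered_labels(assignment.k)
    groups = {lab: [s for s in assignment.samples_with(lab)
                    if s in features.columns] for lab in labels_seq}
    if any(len(m) < 2 for m in groups.values()):
        raise ValueError("every subtype needs >=2 samples with feature data")
    pairs = [(labels_seq[i], labels_seq[j])
             for i in range(len(labels_seq)) for j in range(i + 1, len(labels_seq))]
    records = []  # (feature, pair, mean_i - mean_j, p)
    for feat in features.index:
        vals = {lab: features.loc[feat, m].to_numpy(dtype=float)
                for lab, m in groups.items()}
        if all(np.var(v) == 0 for v in vals.values()) and \
                np.unique(np.concatenate(list(vals.values()))).size == 1:
            logger.warning("feature %r constant everywhere; excluded", feat)
            continue
        for a, b in pairs:
            va, vb = vals[a], vals[b]
            if np.var(va, ddof=1) + np.var(vb, ddof=1) == 0:
                p = 1.0 if va.mean() == vb.mean() else 0.0
            else:
                with np.errstate(all="ignore"):
                    p = float(sps.ttest_ind(va, vb).pvalue)
            records.append((feat, (a, b), float(va.mean() - vb.mean()), p))
    if not records:
        return {lab: [] for lab in labels_seq}
    fdr = bh_fdr([r[3] for r in records])
    sig = {}
    diff = {}
    for (feat, pair, delta, _), q in zip(records, fdr):
        sig[(feat, pair)] = q < fdr_threshold
        diff[(feat, pair)] = delta
    assigned: dict[str, list[str]] = {lab: [] for lab in labels_seq}
    for feat in features.index:
        for lab in labels_seq:
            ok = True
            for a, b in pairs:
                if lab not in (a, b):
                    continue
                key = (feat, (a, b))
                if key not in sig:
                    ok = False
                    break
                delta = diff[key] if lab == a else -diff[key]
                if not (sig[key] and delta > 0):
                    ok = False
                    break
            if ok:
                assigned[lab].append(feat)
                break  # mean-difference signs make a second subtype impossible
    return assigned


def composition_test(assignment: SubtypeAssignment, category: pd.Series,
                     seed: int = 0) -> tuple[pd.DataFrame, TestResult]:
    """Association between subtype and a categorical covariate.

    Samples lacking a category value are excluded (count logged). Returns
    the per-subtype within-subtype proportions of each category and the
    exact test on the subtype-by-category contingency table.
    """
    cat = category.dropna().astype(str)
    shared = [s for s in assignment.sample_ids if s in cat.index]
    excluded = len(assignment.sample_ids) - len(shared)
    if excluded:
        logger.warning("composition test: %d samples lack a category value", excluded)
    cat = cat.loc[shared]
    if cat.nunique() < 2:
        raise ValueError("need at least two categories")
    labels = assignment.labels.loc[shared]
    table = pd.crosstab(labels, cat)
    table = table.loc[[l for l in ordered_labels(assignment.k) if l in table.index]]
    counts = table.to_numpy()
    result = fisher_exact(counts, seed=seed)
    proportions = table.div(table.sum(axis=1), axis=0)
    return proportions, result
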
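"""Per-sample signature scoring.

The workhorse is single-sample gene-set enrichment analysis (ssGSEA): for
each sample independently, genes are rank-transformed, ordered by decreasing
expression, and the score is the integrated difference between the weighted
empirical CDF of in-set genes and the uniform empirical CDF of out-of-set
genes walked down that ordering. Because the statistic depends only on
within-sample ranks it is invariant to any strictly monotone transform of a
sample's expression, which makes it robust across platforms and scales.

Also provided: geometric-mean log-ratios of two marker sets (the
immunostimulatory-over-immunosuppressive balance, e.g. CD8+ T cells over
regulatory T cells) and an ssGSEA-based immune infiltration score.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import EnrichmentMatrix, ExpressionMatrix
from .signatures import GeneSet, GeneSetCollection, restrict_to_matrix

logger = logging.getLogger(__name__)

#: Weight exponent on the rank-normalized expression of in-set genes.
#: 0 gives the unweighted (Kolmogorov–Smirnov-type) running sum.
DEFAULT_ALPHA = 0.25


def _rank_state(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Precompute per-sample rank weights and the decreasing-expression order.

    Ranks are ascending (highest expression -> rank ``n_genes``) with
    average-rank tie handling; the walk order breaks expression ties by
    gene input order (stable sort), so results are deterministic.
    """
    X = matrix.values()
    ranks = rankdata(X, axis=0)  # average ranks, ascending
    order = np.argsort(-X, axis=0, kind="stable")
    return ranks, order


def _ssgsea_from_state(ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray,
                       alpha: float) -> np.ndarray:
    n_genes, n_samples = ranks.shape
    n_in = int(in_set.sum())
    n_out = n_genes - n_in
    weights = (ranks / n_genes) ** alpha  # rank-normalized, bounded in (0, 1]
    w_ord = np.take_along_axis(weights, order, axis=0)
    m_ord = in_set[order]  # bool, genes ordered by decreasing expression
    w_in = np.where(m_ord, w_ord, 0.0)
    cdf_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
    cdf_out = np.cumsum(~m_ord, axis=0) / n_out
    return (cdf_in - cdf_out).sum(axis=0)


def _in_set_mask(matrix: ExpressionMatrix, gene_set: GeneSet) -> np.ndarray:
    present = set(gene_set.intersect(matrix.genes))
    return np.fromiter((g in present for g in matrix.genes), dtype=bool,
                       count=matrix.n_genes)


def ssgsea_score(matrix: ExpressionMatrix, gene_set: GeneSet,
                 alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """ssGSEA enrichment score of one gene set, per sample.

    Parameters
    ----------
    matrix
        Expression matrix (any scale; only within-sample ranks are used).
    gene_set
        Must have >=2 genes measured in the matrix, and at least one
        measured gene must lie outside the set.
    alpha
        Non-negative exponent on rank-normalized expression weighting the
        in-set CDF; ``alpha=0`` weights all in-set genes equally.

    Returns
    -------
    pandas.Series indexed by sample id. Positive scores mean the set's
    genes concentrate at the top of the sample's expression ranking.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    mask = _in_set_mask(matrix, gene_set)
    n_in = int(mask.sum())
    if n_in < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 2 genes measured ({n_in})")
    if n_in == matrix.n_genes:
        raise ValueError(
            f"gene set {gene_set.name!r} covers every matrix gene; "
            "the out-of-set CDF is undefined")
    ranks, order = _rank_state(matrix)
    scores = _ssgsea_from_state(ranks, order, mask, alpha)
    return pd.Series(scores, index=matrix.samples, name=gene_set.name)


def ssgsea_matrix(matrix: ExpressionMatrix, collection: GeneSetCollection,
                  alpha: float = DEFAULT_ALPHA, normalize: bool = False,
                  min_fraction: float = 0.5) -> EnrichmentMatrix:
    """Score every gene set in a collection against every sample.

    The collection is first restricted to the matrix's genes (sets covering
    fewer than ``min_fraction`` of their genes, or fewer than two, are
    dropped). With ``normalize=True`` all scores are divided by the global
    score range so the matrix spans exactly 1 — convenient for heatmaps
    and cross-set comparison.
    """
    restricted = restrict_to_matrix(collection, matrix, min_fraction=min_fraction)
    ranks, order = _rank_state(matrix)
    rows = []
    names = []
    for gs in restricted:
        mask = _in_set_mask(matrix, gs)
        if int(mask.sum()) == matrix.n_genes:
            raise ValueError(f"gene set {gs.name!r} covers every matrix gene")
        rows.append(_ssgsea_from_state(ranks, order, mask, alpha))
        names.append(gs.name)
    scores = pd.DataFrame(np.vstack(rows), index=names, columns=matrix.samples)
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return EnrichmentMatrix(scores=scores, normalized=normalize,
                            meta={"alpha": alpha, "min_fraction": min_fraction,
                                  "restriction": dict(restricted.restriction)})


def log2_signature_ratio(matrix: ExpressionMatrix, numerator: GeneSet,
                         denominator: GeneSet, pseudocount: float = 0.01) -> pd.Series:
    """Per-sample log2 ratio of geometric-mean marker expression.

    Used for the CD8+ T cell / regulatory T cell balance: log2 of the
    geometric mean of the numerator set's marker expression divided by that
    of the denominator set. Expression is taken on the linear scale (log2
    input is exponentiated first); ``pseudocount`` guards against zeros.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    linear = matrix.to_linear()
    out = {}
    for role, gs in (("numerator", numerator), ("denominator", denominator)):
        genes = gs.intersect(linear.genes)
        if len(genes) < 1:
            raise ValueError(f"{role} set {gs.name!r} shares no genes with the matrix")
        values = linear.data.loc[list(genes)].to_numpy(dtype=float) + pseudocount
        out[role] = np.exp(np.log(values).mean(axis=0))  # geometric mean
    ratio = np.log2(out["numerator"] / out["denominator"])
    return pd.Series(ratio, index=linear.samples,
                     name=f"log2({numerator.name}/{denominator.name})")


def immune_score(matrix: ExpressionMatrix, immune_gene_set: GeneSet,
                 alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Immune infiltration proxy: ssGSEA over a pooled immune gene list.

    A rank-based within-sample statistic, reported on the ssGSEA scale; it
    tracks relative infiltration across samples rather than an absolute
    immune fraction.
    """
    score = ssgsea_score(matrix, immune_gene_set, alpha=alpha)
    score.name = "immune_score"
    return score
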
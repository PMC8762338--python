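"""Immune subtype discovery: hierarchical clustering of enrichment scores.

Samples (or single cells) are clustered agglomeratively on their gene-set
enrichment vectors and the resulting k groups are given *ordered* labels by
mean immune-signature score: ImH (high), ImM (medium), ImL (low) for k = 3,
or Im1..Imk (Im1 highest) otherwise. Ordering by score level — rather than
by arbitrary cluster identity — is what makes labels comparable across
datasets clustered independently.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .containers import EnrichmentMatrix, ExpressionMatrix
from .enrichment import DEFAULT_ALPHA, ssgsea_matrix
from .signatures import GeneSetCollection

logger = logging.getLogger(__name__)

LABELS_K3 = ("ImH", "ImM", "ImL")


@dataclass
class SubtypeAssignment:
    """Per-sample ordered subtype labels with the justifying cluster means.

    ``cluster_means`` maps each label to the mean (over the cluster's
    samples) of the per-sample mean enrichment score; by construction
    mean(ImH) > mean(ImM) > mean(ImL).
    """

    labels: pd.Series  # sample_id -> label
    cluster_means: dict[str, float]
    linkage_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = ordered_labels(len(self.cluster_means))
        means = [self.cluster_means[lab] for lab in order]
        if any(means[i] < means[i + 1] for i in range(len(means) - 1)):
            raise ValueError("cluster means must be ordered with the labels")
        counts = self.labels.value_counts()
        if set(counts.index) != set(order) or (counts == 0).any():
            raise ValueError("every label must be assigned to at least one sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def k(self) -> int:
        return len(self.cluster_means)

    def samples_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.labels.index, "label": self.labels.values})
        df["cluster_mean_score"] = [self.cluster_means[l] for l in df["label"]]
        return df


def ordered_labels(k: int) -> tuple[str, ...]:
    """Label sequence from highest to lowest immune score for k clusters."""
    if k == 3:
        return LABELS_K3
    return tuple(f"Im{i + 1}" for i in range(k))


def cluster_samples(enrichment: EnrichmentMatrix, k: int = 3,
                    distance: str = "euclidean", linkage: str = "ward",
                    standardize: bool = True) -> np.ndarray:
    """Cut an agglomerative tree over samples into exactly k clusters.

    Samples are points in gene-set-score space. With ``standardize`` each
    signature row is z-scored first so no single signature dominates the
    distance. Deterministic: scipy's linkage breaks ties by input order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    scores = enrichment.scores
    n = scores.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = scores.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=1, ddof=0, keepdims=True)
        keep = sd.ravel() > 0
        if not keep.any():
            raise ValueError("no structure to cluster: all signatures constant")
        X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep]
    if np.allclose(X, X[:, :1]):
        raise ValueError("no structure to cluster: all samples identical")
    Z = scipy_linkage(X.T, method=linkage, metric=distance)
    idx = fcluster(Z, t=k, criterion="maxclust")
    if np.unique(idx).size != k:
        raise ValueError(f"tree cut produced {np.unique(idx).size} clusters, not {k}")
    return idx


def assign_subtype_labels(enrichment: EnrichmentMatrix,
                          cluster_indices, linkage_record: dict | None = None
                          ) -> SubtypeAssignment:
    """Order clusters by mean immune-signature score and label them.

    For each cluster, the ordering statistic is the mean over its samples
    of the per-sample mean enrichment score. Exactly equal means (rare
    outside degenerate input) are broken by cluster size, the larger
    cluster taking the lower-score label, with a warning.
    """
    idx = np.asarray(cluster_indices)
    samples = enrichment.sample_ids
    if len(idx) != len(samples):
        raise ValueError("cluster indices must align with enrichment samples")
    sample_means = enrichment.sample_means()
    clusters = pd.unique(idx)
    stats = []
    for c in clusters:
        members = np.asarray(samples)[idx == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        stats.append((c, float(sample_means.loc[members].mean()), members.size))
    means = [m for _, m, _ in stats]
    if len(set(np.round(means, 15))) != len(means):
        logger.warning("tied cluster mean scores; breaking by cluster size")
    # highest mean first; ties -> smaller cluster keeps the higher label
    stats.sort(key=lambda t: (-t[1], t[2]))
    labels_seq = ordered_labels(len(stats))
    cluster_to_label = {c: lab for (c, _, _), lab in zip(stats, labels_seq)}
    labels = pd.Series([cluster_to_label[c] for c in idx], index=samples, name="label")
    cluster_means = {lab: m for (c, m, _), lab in zip(stats, labels_seq)}
    return SubtypeAssignment(labels=labels, cluster_means=cluster_means,
                             linkage_record=linkage_record or {})


def subtype_samples(enrichment: EnrichmentMatrix, k: int = 3,
                    distance: str = "euclidean", linkage: str = "ward",
                    standardize: bool = True) -> SubtypeAssignment:
    """Convenience: cluster then assign ordered labels."""
    idx = cluster_samples(enrichment, k=k, distance=distance, linkage=linkage,
                          standardize=standardize)
    record = {"distance": distance, "linkage": linkage, "k": k,
              "standardize": standardize}
    return assign_subtype_labels(enrichment, idx, linkage_record=record)


def subtype_single_cells(cell_matrix: ExpressionMatrix,
                         pathway_sets: GeneSetCollection, k: int = 3,
                         alpha: float = DEFAULT_ALPHA,
                         distance: str = "euclidean", linkage: str = "ward",
                         standardize: bool = True) -> SubtypeAssignment:
    """Subtype single cells on exactly four immune-pathway scores.

    Tumor cells are scored on four immune pathways expressed by the cells
    themselves (antigen processing and presentation, PD-L1/PD-1 checkpoint,
    JAK-STAT signaling, apoptosis in the reference analysis), then clustered
    and labeled exactly as bulk samples.
    """
    if len(pathway_sets) != 4:
        raise ValueError(f"single-cell subtyping requires exactly 4 pathway sets, "
                         f"got {len(pathway_sets)}")
    enr = ssgsea_matrix(cell_matrix, pathway_sets, alpha=alpha)
    if len(enr.set_ids) != 4:
        raise ValueError("all 4 pathway sets must have >=2 genes measured in the matrix")
    assignment = subtype_samples(enr, k=k, distance=distance, linkage=linkage,
                                 standardize=standardize)
    assignment.linkage_record["mode"] = "single-cell"
    assignment.linkage_record["alpha"] = alpha
    return assignment
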
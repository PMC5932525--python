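"""Hierarchical clustering QC of the normalized expression matrix.

After cross-batch normalization the samples should cluster by clinical
group, not by iTRAQ batch.  This module clusters samples on the
Euclidean distance of their normalized intensity profiles and scores
cluster/label agreement with the adjusted Rand index (ARI), giving a
quantitative version of the usual dendrogram eyeball check: batch-label
ARI near the permutation null means the batch effect is gone;
group-label ARI above it means biological separation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode
from sklearn.metrics import adjusted_rand_score

log = logging.getLogger(__name__)


class ClusteringError(ValueError):
    """Raised when the matrix cannot support a sample clustering."""


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over samples.

    ``merges`` is a SciPy linkage matrix whose heights are Euclidean
    cophenetic distances; ``labels`` are the sample ids in matrix column
    order; ``n_proteins_used`` counts the complete-case proteins the
    distances were computed from.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    n_proteins_used: int

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster membership (1..k) from cutting the tree."""
        if k > len(self.labels):
            raise ClusteringError(f"cannot cut {len(self.labels)} samples into {k} clusters")
        return fcluster(self.merges, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize as Newick with merge heights as branch lengths."""
        tree = TreeNode.from_linkage_matrix(self.merges, list(self.labels))
        buf = io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()


def cluster_samples(matrix: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Cluster samples by Euclidean distance of their protein profiles.

    Proteins with any missing value across the clustered samples are
    dropped before computing distances (complete-case; no imputation),
    and the count retained is logged.  Default linkage is average
    (UPGMA), the common choice for expression dendrograms.
    """
    if matrix.shape[1] < 2:
        raise ClusteringError("need at least 2 samples to cluster")
    complete = matrix.dropna(axis=0)
    log.info("clustering on %d complete-case proteins of %d", len(complete), len(matrix))
    if len(complete) < 2:
        raise ClusteringError(
            f"only {len(complete)} proteins observed in every sample; cannot cluster"
        )
    dist = pdist(complete.to_numpy(dtype=float).T, metric="euclidean")
    merges = linkage(dist, method=method)
    return Dendrogram(merges, tuple(map(str, matrix.columns)), len(complete))


def label_agreement(dendrogram: Dendrogram, labels, k: int) -> float:
    """Adjusted Rand index between a k-cluster cut and external labels.

    1 for perfect agreement, about 0 for random labels, negative for
    worse-than-chance.  ``labels`` may be a sequence aligned with the
    dendrogram's samples or a mapping/Series indexed by sample id.
    """
    lab = _align_labels(dendrogram, labels)
    return float(adjusted_rand_score(lab, dendrogram.cut(k)))


def permutation_null(
    dendrogram: Dendrogram, labels, k: int, n_perm: int = 200, seed: int = 0
) -> np.ndarray:
    """Null ARI distribution from randomly permuted label vectors.

    The clustering is held fixed and the labels are shuffled, which is
    the exchangeability that 'no batch-oriented grouping' asserts.
    """
    lab = np.asarray(_align_labels(dendrogram, labels))
    clusters = dendrogram.cut(k)
    rng = np.random.default_rng(seed)
    return np.array(
        [adjusted_rand_score(lab[rng.permutation(len(lab))], clusters) for _ in range(n_perm)]
    )


def _align_labels(dendrogram: Dendrogram, labels) -> list:
    if isinstance(labels, (pd.Series, dict)):
        series = pd.Series(labels)
        return [series[s] for s in dendrogram.labels]
    labels = list(labels)
    if len(labels) != len(dendrogram.labels):
        raise ValueError(
            f"{len(labels)} labels for {len(dendrogram.labels)} clustered samples"
        )
    return labels


def qc_report(
    dendrogram: Dendrogram,
    batch_labels,
    group_labels,
    n_batches: int,
    n_groups: int,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """One-row QC summary: ARI vs batch, ARI vs group, and null bands.

    The 2.5/97.5 percentiles of the permutation null accompany each ARI
    so a reader can see whether batch structure is absent (batch ARI
    inside the band) and group structure present (group ARI above it).
    """
    ari_batch = label_agreement(dendrogram, batch_labels, n_batches)
    ari_group = label_agreement(dendrogram, group_labels, n_groups)
    null_b = permutation_null(dendrogram, batch_labels, n_batches, n_perm, seed)
    null_g = permutation_null(dendrogram, group_labels, n_groups, n_perm, seed + 1)
    return pd.DataFrame(
        {
            "ari_batch": [ari_batch],
            "ari_batch_null_lo": [float(np.quantile(null_b, 0.025))],
            "ari_batch_null_hi": [float(np.quantile(null_b, 0.975))],
            "ari_group": [ari_group],
            "ari_group_null_lo": [float(np.quantile(null_g, 0.025))],
            "ari_group_null_hi": [float(np.quantile(null_g, 0.975))],
            "n_proteins_used": [dendrogram.n_proteins_used],
        }
    )
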
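"""CTCF/RAD21 co-occurrence clustering of promoters.

Active genes are clustered (k-means, k=2) on their binned CTCF and RAD21
signal in the ±1 kb TSS window; cluster membership is then tested for
association with transcriptional directionality by Fisher's exact test.
Cluster 1 is canonically the cluster with the higher mean CTCF signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .footprints import SignalMatrix

BIN_BP = 25


def feature_matrix(
    matrices: Sequence[SignalMatrix], bin_bp: int = BIN_BP
) -> tuple[pd.DataFrame, list[slice]]:
    """Bin each track's window into ``bin_bp`` averages and concatenate.

    Returns the gene × feature frame and, per input track, the slice of
    feature columns it occupies (used for canonical cluster labeling). A
    trailing partial bin is averaged over its own width.
    """
    if not matrices:
        raise ValueError("need at least one signal matrix")
    ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != ids:
            raise ValueError("signal matrices cover different gene sets")
    blocks, slices, at = [], [], 0
    for m in matrices:
        width = m.values.shape[1]
        edges = np.arange(0, width, bin_bp)
        sums = np.add.reduceat(m.values, edges, axis=1)
        sizes = np.diff(np.append(edges, width))
        blocks.append(sums / sizes)
        slices.append(slice(at, at + len(edges)))
        at += len(edges)
    features = pd.DataFrame(np.hstack(blocks), index=pd.Index(ids, name="gene_id"))
    return features, slices


@dataclass
class ClusterResult:
    labels: pd.Series  # gene_id -> 1 or 2
    sizes: dict[int, int]
    centers: np.ndarray  # (2, n_features), row 0 = cluster 1
    inertia: float

    def mean_profile(self, cluster: int) -> np.ndarray:
        return self.centers[cluster - 1]


def kmeans2(
    features: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 10,
    ctcf_columns: slice | None = None,
) -> ClusterResult:
    """Two-cluster k-means (k-means++ seeding, best of ``n_restarts``).

    Cluster 1 is the cluster with higher mean signal over
    ``ctcf_columns`` (all columns when None).
    """
    X = features.to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < 2:
        raise ValueError("all rows identical: no two clusters exist")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(X)
    cols = ctcf_columns if ctcf_columns is not None else slice(None)
    order = np.argsort(-km.cluster_centers_[:, cols].mean(axis=1))
    relabel = {int(order[0]): 1, int(order[1]): 2}
    labels = pd.Series([relabel[int(l)] for l in km.labels_],
                       index=features.index)
    centers = km.cluster_centers_[order]
    sizes = {1: int((labels == 1).sum()), 2: int((labels == 2).sum())}
    return ClusterResult(labels, sizes, centers, float(km.inertia_))


def association_test(
    clusters: pd.Series, annotation: pd.DataFrame
) -> dict:
    """Fisher's exact test of cluster membership vs directionality class.

    Genes without a combined class (excluded / n-a) are dropped. Returns
    the 2×2 table, the two-sided p-value, and the percentage of each class
    falling in cluster 1.
    """
    cls = annotation.loc[clusters.index, "class_combined"]
    keep = cls.isin(["uni", "bi"])
    cls, lab = cls[keep], clusters[keep]
    table = np.zeros((2, 2), dtype=int)
    for i, c in enumerate((1, 2)):
        for j, k in enumerate(("uni", "bi")):
            table[i, j] = int(((lab == c) & (cls == k)).sum())
    if table.sum(axis=0).min() == 0:
        raise ValueError("a directionality class is absent")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    col = table.sum(axis=0)
    return {
        "table": table,
        "p": float(p),
        "cluster1_uni_pct": 100.0 * table[0, 0] / col[0],
        "cluster1_bi_pct": 100.0 * table[0, 1] / col[1],
    }
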
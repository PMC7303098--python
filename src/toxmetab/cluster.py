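"""Hierarchical clustering of the significant-feature matrix for heatmaps.

Rows (features) are z-scored first, then features and samples are each
clustered agglomeratively on Euclidean distances. The linkage method is
configurable (complete by default); merge trees are exportable as linkage
tables or Newick strings for external heatmap/dendrogram rendering — no
plotting happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusteringResult", "row_zscore", "hierarchical_cluster",
           "cluster_table", "linkage_to_newick"]

LINKAGE_METHODS = ("complete", "average", "ward")


class ClusterError(ValueError):
    pass


@dataclass
class ClusteringResult:
    zscored: pd.DataFrame            # features x samples, row-scaled
    feature_linkage: np.ndarray      # scipy linkage matrix over rows
    sample_linkage: np.ndarray       # scipy linkage matrix over columns
    feature_order: list[str]         # dendrogram leaf order
    sample_order: list[str]
    linkage_method: str


def row_zscore(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Scale each row to mean 0, sd 1 (sample sd, n-1 denominator)."""
    values = np.asarray(matrix, float)
    sd = values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (list(np.asarray(matrix.index)[bad]) if isinstance(matrix, pd.DataFrame)
                 else bad.tolist())
        raise ClusterError(f"zero-variance rows cannot be z-scored: {names}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def hierarchical_cluster(matrix: np.ndarray, linkage_method: str = "complete") -> np.ndarray:
    """Agglomerative clustering on Euclidean distances between rows.

    Returns the scipy linkage matrix (merge pairs and heights). SciPy's
    implementation breaks distance ties by lowest cluster index, which
    makes the result deterministic.
    """
    values = np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ClusterError("need a 2-D matrix with at least 2 rows")
    if np.isnan(values).any():
        raise ClusterError("matrix contains NaN")
    if linkage_method not in LINKAGE_METHODS:
        raise ClusterError(f"linkage_method must be one of {LINKAGE_METHODS}")
    return hierarchy.linkage(pdist(values), method=linkage_method)


def cluster_table(
    matrix: pd.DataFrame,
    linkage_method: str = "complete",
) -> ClusteringResult:
    """Row-scale a features x samples matrix and cluster both dimensions."""
    z = row_zscore(matrix)
    feat_link = hierarchical_cluster(z.to_numpy(), linkage_method)
    samp_link = hierarchical_cluster(z.to_numpy().T, linkage_method)
    feat_order = hierarchy.leaves_list(feat_link)
    samp_order = hierarchy.leaves_list(samp_link)
    return ClusteringResult(
        zscored=z,
        feature_linkage=feat_link,
        sample_linkage=samp_link,
        feature_order=[z.index[i] for i in feat_order],
        sample_order=[z.columns[i] for i in samp_order],
        linkage_method=linkage_method,
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
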
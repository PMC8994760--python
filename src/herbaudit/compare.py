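"""Sample-similarity analysis on PHS presence/abundance profiles.

Euclidean distances between sample rows (for binary presence rows the
squared distance equals the Hamming distance), hierarchical clustering with
a serializable dendrogram, distance-cutoff networks, and a deterministic PCA.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "NETWORK_CUTOFFS",
    "euclidean_distances",
    "hierarchical_cluster",
    "linkage_to_newick",
    "network_edges",
    "pca",
]

#: Per-barcode edge cutoffs for the sample network.
NETWORK_CUTOFFS = {"ITS2": 5.0, "trnL": 4.2}

_LINKAGES = {"complete", "average", "single", "ward"}


def euclidean_distances(pm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample rows."""
    if len(pm.index) < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(pm.to_numpy(dtype=float), metric="euclidean")
    return pd.DataFrame(squareform(condensed), index=pm.index, columns=pm.index)


def hierarchical_cluster(
    dm: pd.DataFrame, linkage: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate a distance matrix; returns (linkage matrix, leaf order).

    Deterministic for identical input.  Default linkage is complete;
    ``average``, ``single`` and ``ward`` are also accepted.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    _check_square(dm)
    condensed = squareform(dm.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaf_order = [dm.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaf_order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def network_edges(
    dm: pd.DataFrame, cutoff: float
) -> list[tuple[str, str, float]]:
    """Unordered sample pairs with distance <= cutoff (no self-edges)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    _check_square(dm)
    samples = list(dm.index)
    values = dm.to_numpy(dtype=float)
    edges = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if values[i, j] <= cutoff:
                edges.append((samples[i], samples[j], float(values[i, j])))
    return edges


def pca(
    table: pd.DataFrame, n_components: Optional[int] = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on column-centered (unscaled) data via SVD.

    Returns (scores, explained-variance fractions).  The sign convention is
    fixed so the largest-magnitude loading of each component is positive,
    making reruns identical.  A constant matrix yields all-zero scores.
    """
    X = table.to_numpy(dtype=float)
    n_samples, n_features = X.shape
    if n_samples < 2 or n_features < 2:
        raise ValueError("need at least 2 samples and 2 features")
    max_rank = min(n_samples - 1, n_features)
    k = max_rank if n_components is None else min(n_components, max_rank)
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        warnings.warn("constant input matrix: all PCA scores are zero")
        scores = np.zeros((n_samples, k))
        return (
            pd.DataFrame(scores, index=table.index,
                         columns=[f"PC{i+1}" for i in range(k)]),
            np.zeros(k),
        )
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[i]))
        if Vt[i, pivot] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = (U * S)[:, :k]
    explained = (S**2 / total_var)[:k]
    frame = pd.DataFrame(
        scores, index=table.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, explained


def _check_square(dm: pd.DataFrame) -> None:
    if dm.shape[0] != dm.shape[1] or list(dm.index) != list(dm.columns):
        raise ValueError("distance matrix must be square with matching labels")
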
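"""Two-component embeddings (UMAP / PCA) and hierarchical clustering of
trait vectors, with group labels coded 1-5
(Pathogenic=1, Pathogeniclikely=2, Benign=3, Benignlikely=4,
Uncertain=5)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .composition import minmax_normalize

GROUP_CODES = {"Pathogenic": 1, "Pathogeniclikely": 2, "Benign": 3,
               "Benignlikely": 4, "Uncertain": 5}


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    labels: np.ndarray
    coordinates: np.ndarray  # (n, 2), min-max normalised per component
    method: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "label": self.labels,
            "component1": self.coordinates[:, 0],
            "component2": self.coordinates[:, 1],
        })


@dataclass
class ClusteringResult:
    linkage: np.ndarray        # scipy linkage matrix
    leaf_order: np.ndarray     # leaf indices for heatmap rendering
    sample_ids: list[str]
    method: str
    metric: str = "euclidean"

    def to_newick(self) -> str:
        """Newick serialisation of the linkage tree (leaf names =
        sample ids, branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def reduce_two_components(features: np.ndarray, method: str = "umap",
                          seed: int = 0,
                          sample_ids: list[str] | None = None,
                          labels=None) -> EmbeddingResult:
    """Reduce a feature matrix to two components (UMAP or PCA), then
    min-max normalise each component to [0, 1].

    Deterministic for a fixed seed; labels may be the five significance
    strings (coded 1-5) or any numeric codes.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if method == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method == "umap":
        import umap  # deferred: heavy import

        reducer = umap.UMAP(n_components=2, random_state=seed)
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}; use 'umap' or 'pca'")
    # a component with no real spread (all samples coincide) is kept at
    # zero rather than letting min-max amplify float jitter
    scale = max(1.0, float(np.abs(coords).max()))
    coords = np.column_stack([
        minmax_normalize(coords[:, j])
        if np.ptp(coords[:, j]) > 1e-9 * scale else np.zeros(n)
        for j in range(2)])
    if labels is None:
        coded = np.zeros(n, dtype=int)
    else:
        coded = np.array([GROUP_CODES.get(l, l) for l in labels])
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return EmbeddingResult(sample_ids=list(ids), labels=coded,
                           coordinates=coords, method=method, seed=seed)


def hierarchical_cluster(features: np.ndarray,
                         sample_ids: list[str] | None = None,
                         method: str = "average") -> ClusteringResult:
    """Agglomerative clustering on Euclidean distances; the linkage
    method (default: average) is recorded in the result."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    ids = sample_ids or [f"s{i}" for i in range(X.shape[0])]
    return ClusteringResult(linkage=Z, leaf_order=order,
                            sample_ids=list(ids), method=method)
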
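"""Average-linkage hierarchical clustering of regions on Pearson dissimilarity.

The dissimilarity between two regions is the uncentered-correlation distance

    d(x, y) = 1 - (sum_i x_i y_i) / sqrt(sum_i x_i^2 * sum_i y_i^2),

i.e. one minus the cosine similarity of the two observation vectors (the
"pearson" distance of R's amap package).  A centered variant, one minus the
product-moment correlation, is available via ``centered=True``.  Regions are
then merged agglomeratively: at each step the minimum-distance pair of
clusters is joined, and the distance from the merged cluster to every other
cluster is the size-weighted mean of the two constituent distances — the
classic UPGMA contract, under which inter-cluster distance equals the mean
over all cross-pairs of leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ObservationMatrix


def amap_pearson_distance(x, y, centered: bool = False) -> float:
    """Uncentered (default) or centered Pearson dissimilarity of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-d vectors of equal length >= 2")
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    nx_ = np.dot(x, x)
    ny_ = np.dot(y, y)
    if nx_ == 0 or ny_ == 0:
        raise ValueError("zero-norm vector: dissimilarity undefined")
    d = 1.0 - np.dot(x, y) / np.sqrt(nx_ * ny_)
    return float(min(max(d, 0.0), 2.0))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix over labelled regions, values in [0, 2]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def distance_matrix(obs: ObservationMatrix, centered: bool = False) -> DistanceMatrix:
    """Pairwise region dissimilarities from an observation matrix."""
    x = obs.to_numpy()
    labels = list(obs.values.columns)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = amap_pearson_distance(x[:, i], x[:, j],
                                                      centered=centered)
    return DistanceMatrix(pd.DataFrame(d, index=labels, columns=labels))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (id_a, id_b, height, size) in merge order; leaves carry
    ids 0..n-1 in ``leaf_labels`` order and the k-th merge creates cluster
    id n+k, as in scipy's linkage encoding.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1) x 4 linkage array."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to children."""
        n = len(self.leaf_labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_labels[i] for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["cluster_a", "cluster_b", "height", "size"])


def average_linkage(D: DistanceMatrix) -> Dendrogram:
    """UPGMA clustering with a deterministic tie-break.

    When several pairs share the minimum distance, the pair whose clusters
    contain the earliest leaves in canonical label order is joined first,
    making the output invariant to input permutations.
    """
    labels = D.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    d = {(i, j): D.values.iat[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    # tie-break key: smallest original leaf index contained in the cluster
    first_leaf = {i: i for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        best_key = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = d[(i, j)] if (i, j) in d else d[(j, i)]
                key = (dij, *sorted((first_leaf[i], first_leaf[j])))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j, dij)
        a, b, h = best
        new = next_id
        next_id += 1
        for k in active - {a, b}:
            dak = d[tuple(sorted((a, k)))]
            dbk = d[tuple(sorted((b, k)))]
            d[(k, new)] = (size[a] * dak + size[b] * dbk) / (size[a] + size[b])
        active -= {a, b}
        active.add(new)
        size[new] = size[a] + size[b]
        first_leaf[new] = min(first_leaf[a], first_leaf[b])
        merges.append((a, b, float(h), size[new]))
    return Dendrogram(merges=merges, leaf_labels=labels)
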
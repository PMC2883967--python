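"""Probe filtering and hierarchical clustering of expression profiles.

The filter keeps probes that vary (coefficient of variation >= 0.05 by
default) and are expressed (at least 2 samples with log2 intensity >= 8).
Clustering is agglomerative complete linkage over samples, by default on
1 - Pearson correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix

__all__ = ["FilterSpec", "Dendrogram", "filter_probes", "hierarchical_cluster", "cut_tree"]


@dataclass(frozen=True)
class FilterSpec:
    """Variation + expression filter.

    cv_min: minimum coefficient of variation (sd/mean); cv_scale selects
    whether the CV is computed on log2 values (default) or on linear
    intensities (2**x).
    expr_min: log2 expression floor; at least ``min_samples_at_expr``
    samples must reach it.
    """

    cv_min: float = 0.05
    expr_min: float = 8.0
    min_samples_at_expr: int = 2
    cv_scale: str = "log2"

    def __post_init__(self) -> None:
        if self.cv_min < 0:
            raise ValueError("cv_min must be >= 0")
        if self.min_samples_at_expr < 1:
            raise ValueError("min_samples_at_expr must be >= 1")
        if self.cv_scale not in ("log2", "linear"):
            raise ValueError("cv_scale must be 'log2' or 'linear'")


@dataclass
class Dendrogram:
    """A complete-linkage merge tree over samples.

    ``merges`` follows the scipy linkage convention: row t merges clusters
    ``merges[t, 0]`` and ``merges[t, 1]`` (indices < n are leaves, n + t is
    the cluster created at step t) at height ``heights[t]``.
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    leaf_order: np.ndarray  # permutation of range(n)
    sample_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def to_linkage(self) -> np.ndarray:
        """Back to a scipy linkage matrix (with subtree sizes recomputed)."""
        n = self.n_leaves
        sizes = {}
        z = np.zeros((n - 1, 4))
        for t, ((i, j), h) in enumerate(zip(self.merges, self.heights)):
            si = 1 if i < n else sizes[i]
            sj = 1 if j < n else sizes[j]
            sizes[n + t] = si + sj
            z[t] = [i, j, h, si + sj]
        return z

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes = {i: f"{self.sample_ids[i]}" for i in range(n)}
        depth = {i: 0.0 for i in range(n)}
        for t, ((i, j), h) in enumerate(zip(self.merges, self.heights)):
            bi = max(h - depth[i], 0.0)
            bj = max(h - depth[j], 0.0)
            nodes[n + t] = f"({nodes[i]}:{bi:g},{nodes[j]}:{bj:g})"
            depth[n + t] = h
        return nodes[n + self.n_leaves - 2] + ";"


def filter_probes(matrix: ExpressionMatrix, spec: FilterSpec = FilterSpec()) -> ExpressionMatrix:
    """Keep probes with CV >= cv_min AND enough samples at the expression floor.

    Probe order is preserved. An empty result is a warning, not an error.
    """
    values = matrix.values.to_numpy()
    if spec.cv_scale == "linear":
        scale_values = np.power(2.0, values)
    else:
        scale_values = values
    mean = scale_values.mean(axis=1)
    sd = scale_values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.inf)
    expressed = (values >= spec.expr_min).sum(axis=1) >= spec.min_samples_at_expr
    keep = (cv >= spec.cv_min) & expressed
    if not keep.any():
        warnings.warn("probe filter removed every probe", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.labels)


def hierarchical_cluster(
    matrix: ExpressionMatrix, metric: str = "correlation", linkage: str = "complete"
) -> Dendrogram:
    """Complete-linkage agglomerative clustering of samples.

    ``metric`` is 'correlation' (1 - Pearson r across probes, the
    conventional expression-profile distance) or 'euclidean'.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is exposed")
    if metric not in ("correlation", "euclidean"):
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    if matrix.n_samples < 2:
        raise ValueError("clustering requires at least 2 samples")
    X = matrix.values.to_numpy().T  # samples x probes
    dist = pdist(X, metric=metric)
    z = sch.linkage(dist, method="complete")
    return Dendrogram(
        merges=z[:, :2].astype(int),
        heights=z[:, 2].copy(),
        leaf_order=np.asarray(sch.leaves_list(z)),
        sample_ids=list(matrix.sample_ids),
    )


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Partition samples into k groups by removing the k - 1 highest merges.

    Returns cluster labels (0..k-1, numbered by first appearance in sample
    order) indexed by sample id.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):  # apply all but the k-1 last merges
        i, j = dendrogram.merges[t]
        parent[find(int(i))] = n + t
        parent[find(int(j))] = n + t
    roots: dict[int, int] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels.append(roots[r])
    return pd.Series(labels, index=dendrogram.sample_ids)
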
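"""Average-linkage clustering of mean-normalized log fold changes.

Proteins quantified (majority rule) in every cohort are assembled into a
matrix of log2 fold changes, centered so that heatmap colors encode the
deviation of each protein from its own mean behaviour (per-protein
centering, the default) or from the cohort mean. Rows are then clustered
agglomeratively with the unweighted average (UPGMA) linkage on Euclidean
distances — the inter-cluster distance is the arithmetic mean over all
cross-cluster pairs of row distances.

The merge loop is implemented here rather than delegated, because
determinism under distance ties is part of the contract: when two candidate
merges are equally close, the pair whose clusters contain the smallest
original row indices merges first. Average linkage is inversion-free, so
merge heights are non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from bonlac.ratio_io import RatioTable
from bonlac.screen import ScreenConfig

__all__ = [
    "FoldChangeMatrix",
    "ClusterTree",
    "ClusterError",
    "build_fc_matrix",
    "average_linkage_tree",
    "cut_tree",
]


class ClusterError(ValueError):
    """Invalid clustering input."""


@dataclass
class FoldChangeMatrix:
    """Centered log fold changes: rows = proteins, columns = cohorts.

    ``values`` has no missing cells; ``log_base`` and ``center_axis`` record
    the transform. ``outside_broad_window`` flags proteins whose cohort
    ratios fall outside a broad fold-change window (annotation only)."""

    values: pd.DataFrame
    log_base: float = 2.0
    center_axis: str = "protein"
    outside_broad_window: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ClusterError("fold-change matrix must have no missing cells")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _cohort_means(
    table: RatioTable, config: ScreenConfig
) -> tuple[pd.Series, pd.Series]:
    """Per-protein mean ratio over detected replicates + majority-detection mask."""
    data = table.data
    n_detected = data.notna().sum(axis=1)
    detected = n_detected >= config.detection_floor(table.n_replicates)
    if config.mean_type == "geometric":
        means = np.exp(np.log(data).mean(axis=1))
    else:
        means = data.mean(axis=1)
    return means, detected


def build_fc_matrix(
    cohorts: Mapping[str, RatioTable],
    config: ScreenConfig = ScreenConfig(),
    log_base: float = 2.0,
    center_axis: Literal["protein", "cohort", "none"] = "protein",
    broad_window: tuple[float, float] | None = None,
) -> FoldChangeMatrix:
    """Assemble the cross-cohort matrix of centered log fold changes.

    Restricted to proteins that pass the majority-detection rule in every
    cohort; each cohort value is the mean ratio over that cohort's detected
    replicates (same averaging convention as the screen). ``broad_window``,
    e.g. ``(0.85, 1.15)``, annotates which proteins have at least one cohort
    mean outside the window — it does not filter.
    """
    if len(cohorts) < 2:
        raise ClusterError("need at least two cohorts")
    means: dict[str, pd.Series] = {}
    shared: pd.Index | None = None
    for name, table in cohorts.items():
        if not table.oriented:
            raise ClusterError(f"cohort {name!r} table is not oriented")
        m, detected = _cohort_means(table, config)
        means[name] = m[detected]
        shared = means[name].index if shared is None else shared.intersection(means[name].index)
    assert shared is not None
    if len(shared) == 0:
        raise ClusterError("cohort overlap is empty: no protein detected in every cohort")
    shared = shared.sort_values()

    ratio = pd.DataFrame({name: m.reindex(shared) for name, m in means.items()})
    logs = np.log(ratio) / np.log(log_base)
    if center_axis == "protein":
        logs = logs.sub(logs.mean(axis=1), axis=0)
    elif center_axis == "cohort":
        logs = logs.sub(logs.mean(axis=0), axis=1)
    elif center_axis != "none":
        raise ClusterError(f"unknown center_axis {center_axis!r}")

    outside = None
    if broad_window is not None:
        lo, hi = broad_window
        outside = ((ratio < lo) | (ratio > hi)).any(axis=1)
        outside.name = "outside_broad_window"
    return FoldChangeMatrix(
        values=logs, log_base=log_base, center_axis=center_axis, outside_broad_window=outside
    )


@dataclass
class ClusterTree:
    """Binary merge tree from agglomerative clustering.

    ``merges`` follows the linkage-matrix convention: row m merges nodes
    ``(a, b)`` at ``height`` into new node ``n_leaves + m``; node ids below
    ``n_leaves`` are leaves. ``labels`` names the leaves.
    """

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {
            n + m: (int(a), int(b))
            for m, (a, b) in enumerate(self.merges[:, :2].astype(int))
        }

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices of the dendrogram."""
        if self.n_leaves == 1:
            return [0]
        children = self._children()
        order: list[int] = []
        stack = [self.n_leaves + len(children) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                stack.append(b)
                stack.append(a)
        return order

    def to_newick(self) -> str:
        """Newick export with ultrametric branch lengths (node depth = height/2)."""
        n = self.n_leaves
        if n == 1:
            return f"{self.labels[0]}:0;"
        children = self._children()
        heights = {i: 0.0 for i in range(n)}
        for m in range(self.merges.shape[0]):
            heights[n + m] = float(self.merges[m, 2])

        def render(node: int, parent_height: float) -> str:
            branch = (parent_height - heights[node]) / 2.0
            if node < n:
                return f"{self.labels[node]}:{branch:.12g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{branch:.12g}"

        root = n + self.merges.shape[0] - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def _tie_key(members: Sequence[int], other: Sequence[int]) -> tuple:
    return tuple(sorted(set(members) | set(other)))


def average_linkage_tree(
    matrix: FoldChangeMatrix | np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> ClusterTree:
    """Agglomerative UPGMA clustering of rows under Euclidean distance.

    Inter-cluster distances follow the unweighted-average (Lance–Williams)
    update ``d(k, i∪j) = (|i| d(k,i) + |j| d(k,j)) / (|i|+|j|)``, exactly the
    mean over all cross-cluster row pairs. Ties merge the pair whose
    combined member-index tuple is lexicographically smallest, making the
    merge sequence deterministic.
    """
    if isinstance(matrix, FoldChangeMatrix):
        X = matrix.as_array()
        labels = tuple(matrix.protein_ids)
    elif isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        labels = tuple(str(i) for i in matrix.index) if labels is None else tuple(labels)
    else:
        X = np.asarray(matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = tuple(str(i) for i in range(X.shape[0])) if labels is None else tuple(labels)
    n = X.shape[0]
    if n < 2:
        raise ClusterError("need at least two rows to cluster")
    if not np.all(np.isfinite(X)):
        raise ClusterError("matrix contains non-finite values")
    if len(labels) != n:
        raise ClusterError("label count does not match row count")

    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))

    active: dict[int, dict] = {
        i: {"node": i, "size": 1, "members": (i,)} for i in range(n)
    }
    merges = np.zeros((n - 1, 4))
    next_node = n
    for m in range(n - 1):
        ids = sorted(active)
        best: tuple | None = None
        for ii, i in enumerate(ids):
            for j in ids[ii + 1 :]:
                d = dist[i, j]
                key = (d, _tie_key(active[i]["members"], active[j]["members"]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        assert best is not None
        _, i, j = best
        d = dist[i, j]
        ci, cj = active[i], active[j]
        merges[m] = (ci["node"], cj["node"], d, ci["size"] + cj["size"])
        # unweighted-average update into slot i
        for k in ids:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (
                ci["size"] * dist[k, i] + cj["size"] * dist[k, j]
            ) / (ci["size"] + cj["size"])
        active[i] = {
            "node": next_node,
            "size": ci["size"] + cj["size"],
            "members": tuple(sorted(ci["members"] + cj["members"])),
        }
        del active[j]
        next_node += 1
    return ClusterTree(merges=merges, labels=tuple(labels))


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Cut into exactly ``k`` flat clusters by removing the k−1 highest merges.

    Returns a Series mapping leaf label to cluster id (1..k); ids are
    assigned in leaf order of first appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ClusterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    # merges are height-sorted; applying the first n-k keeps k clusters
    for m in range(n - k):
        a, b = int(tree.merges[m, 0]), int(tree.merges[m, 1])
        ra = find(node_members[a][0])
        rb = find(node_members[b][0])
        parent[rb] = ra
        node_members[n + m] = node_members[a] + node_members[b]

    cluster_ids: dict[int, int] = {}
    assignment = np.zeros(n, dtype=int)
    for leaf in tree.leaf_order():
        root = find(leaf)
        if root not in cluster_ids:
            cluster_ids[root] = len(cluster_ids) + 1
        assignment[leaf] = cluster_ids[root]
    return pd.Series(assignment, index=list(tree.labels), name="cluster")
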
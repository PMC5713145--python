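"""Average-linkage clustering of the distance matrix and threshold estimation.

The dendrogram is built with UPGMA (average linkage): the distance between
two clusters X and Y is the mean of all |X|*|Y| pairwise dataset distances.
Two automatic cut-height estimators are provided: the height of the fastest
growth of the largest cluster, and the minimal height at which the pooled
reflections of the largest cluster exceed a completeness target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix, merged_key_arrays
from .reflection_io import PartialDataset
from .symmetry import d_spacings, unique_reflections

__all__ = [
    "LinkageTree",
    "ClusterSelection",
    "average_linkage",
    "cut",
    "threshold_by_growth",
    "threshold_by_completeness",
    "best_resolution",
    "pooled_completeness",
]


@dataclass
class LinkageTree:
    """The merge sequence defining the dendrogram.

    ``merges[k] = (left, right, height, size)`` with leaves numbered
    0..n_leaves-1 in input order and internal node k getting id
    ``n_leaves + k``.
    """

    merges: list[tuple[int, int, float, int]]
    n_leaves: int
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a binary merge tree has exactly n_leaves - 1 merges")

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def member_leaves(self) -> list[list[int]]:
        """Leaf sets of every node (leaves then internal nodes, by id)."""
        members: list[list[int]] = [[i] for i in range(self.n_leaves)]
        for left, right, _, _ in self.merges:
            members.append(members[left] + members[right])
        return members


@dataclass
class ClusterSelection:
    """Clusters selected at a threshold; members listed by dataset id."""

    threshold: float
    mode: str
    clusters: list[list[str]]

    def __post_init__(self) -> None:
        flat = [m for c in self.clusters for m in c]
        if len(flat) != len(set(flat)):
            raise ValueError("cluster memberships must be disjoint")


def average_linkage(dm: DistanceMatrix) -> LinkageTree:
    """Agglomerative UPGMA clustering of a distance matrix."""
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    if dm.n < 2:
        raise ValueError("need at least two leaves")
    z = _scipy_linkage(squareform(dm.d, checks=False), method="average")
    merges = [
        (int(left), int(right), float(height), int(size))
        for left, right, height, size in z
    ]
    return LinkageTree(merges=merges, n_leaves=dm.n, labels=list(dm.labels))


def _leaf_partition(tree: LinkageTree, threshold: float) -> list[list[int]]:
    """Partition of leaf indices induced by keeping merges at height <= t."""
    parent = list(range(tree.n_leaves + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (left, right, height, _) in enumerate(tree.merges):
        if height <= threshold + 1e-12:
            node = tree.n_leaves + k
            parent[find(left)] = node
            parent[find(right)] = node
    groups: dict[int, list[int]] = {}
    for leaf in range(tree.n_leaves):
        groups.setdefault(find(leaf), []).append(leaf)
    # deterministic order: by smallest member leaf
    return sorted(groups.values(), key=lambda g: g[0])


def cut(tree: LinkageTree, threshold: float, mode: str = "largest") -> ClusterSelection:
    """Cut the dendrogram at a height.

    ``mode="all"`` returns the full partition; ``mode="largest"`` only the
    biggest cluster (ties broken toward the cluster containing the smallest
    leaf index).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    partition = _leaf_partition(tree, threshold)
    if mode == "all":
        clusters = partition
    elif mode == "largest":
        best = max(partition, key=lambda g: (len(g), -g[0]))
        clusters = [best]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ClusterSelection(
        threshold=threshold,
        mode=mode,
        clusters=[[tree.labels[i] for i in c] for c in clusters],
    )


def _scan_heights(tree: LinkageTree) -> np.ndarray:
    """Ascending unique merge heights prefixed with 0 (cluster changes only there)."""
    h = np.unique(tree.heights())
    if len(h) == 0 or h[0] > 0:
        h = np.concatenate([[0.0], h])
    return h


def threshold_by_growth(tree: LinkageTree) -> float:
    """Cut height where the largest cluster grows fastest.

    Evaluates the largest-cluster size at each merge height in ascending
    order and returns the height with the maximal increase over the previous
    height (earliest height on ties).  The final merge height is not a
    candidate (unless it is the only one): the root join always absorbs
    every remaining dataset, so a threshold there defines no clustering.
    """
    heights = _scan_heights(tree)
    sizes = []
    for h in heights:
        partition = _leaf_partition(tree, h)
        sizes.append(max(len(g) for g in partition))
    sizes = np.asarray(sizes)
    increases = np.diff(sizes)
    if len(increases) == 0:
        return float(heights[-1])
    if len(increases) > 1:
        increases = increases[:-1]
    best = int(np.argmax(increases))  # argmax takes the earliest maximum
    return float(heights[best + 1])


def best_resolution(datasets: Sequence[PartialDataset]) -> float:
    """Highest resolution (smallest d) observed across all datasets."""
    return min(float(d_spacings(ds.hkl_array(), ds.cell).min()) for ds in datasets)


def pooled_completeness(
    datasets: Sequence[PartialDataset],
    d_min: float,
    anomalous: bool = False,
) -> float:
    """Fraction of theoretically observable unique reflections present in a pool."""
    ref = datasets[0]
    theory, _ = unique_reflections(ref.cell, ref.spacegroup, d_min, anomalous=anomalous)
    observed = np.unique(
        np.concatenate([merged_key_arrays(ds, anomalous=anomalous)[0] for ds in datasets])
    )
    present = np.intersect1d(theory, observed, assume_unique=True)
    return len(present) / len(theory)


def threshold_by_completeness(
    tree: LinkageTree,
    datasets: Sequence[PartialDataset],
    target: float = 0.98,
    anomalous: bool = False,
    d_min: float | None = None,
) -> float:
    """Minimal cut height at which the largest cluster is complete enough.

    Scans the merge heights in ascending order, pooling the reflections of
    the largest cluster at each height, and returns the smallest height
    whose pooled completeness reaches ``target``.  If the target is never
    reached, the maximal height is returned with a warning.
    """
    if len(datasets) != tree.n_leaves:
        raise ValueError("datasets must correspond one-to-one to tree leaves")
    if d_min is None:
        d_min = best_resolution(datasets)
    ref = datasets[0]
    theory, _ = unique_reflections(ref.cell, ref.spacegroup, d_min, anomalous=anomalous)
    keys = {
        ds.id: merged_key_arrays(ds, anomalous=anomalous)[0] for ds in datasets
    }
    heights = _scan_heights(tree)
    for h in heights:
        selection = cut(tree, float(h), mode="largest")
        observed = np.unique(np.concatenate([keys[m] for m in selection.clusters[0]]))
        present = np.intersect1d(theory, observed, assume_unique=True)
        if len(present) / len(theory) >= target:
            return float(h)
    warnings.warn(
        f"completeness target {target:.2%} not reached at any height; "
        "returning the maximal merge height",
        stacklevel=2,
    )
    return float(heights[-1])
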
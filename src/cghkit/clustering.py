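"""UPGMA dendrograms over ternary gain/loss profiles.

Samples are compared by the mean absolute difference of their ternary
calls (-1/0/+1) over a chosen set of regions, with pairwise deletion of
coordinates where either sample is missing; the distance lies in [0, 2].
Clusters are built bottom-up: at each step the two clusters at the
smallest distance merge at a height equal to that distance, and the
distance from the merged cluster to every other one is the unweighted
average over all leaf pairs (UPGMA), maintained by the size-weighted
recurrence d(A+B, K) = (|A| d(A,K) + |B| d(B,K)) / (|A| + |B|).

Ties on the minimal distance are broken by the lexicographically smallest
pair of cluster-creation indices, which makes the tree fully
deterministic.  The authored implementation is deliberately simple
(O(n^3)); scipy's hierarchy routines are used only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GroupLabels, SegmentMatrix

__all__ = [
    "ClusterTree",
    "ternary_distance",
    "distance_matrix",
    "upgma",
    "cophenetic",
    "cut_tree",
    "reassign",
]


@dataclass
class ClusterTree:
    """Binary merge tree.

    Nodes 0..n-1 are the leaves (height 0); node n+i is created by
    ``merges[i] = (left, right, height)``.  Merge heights are
    non-decreasing (UPGMA ultrametric monotonicity).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_size(self, node: int) -> int:
        return len(self.leaf_set(node))

    def leaf_set(self, node: int) -> frozenset[int]:
        n = self.n_leaves
        if node < n:
            return frozenset({node})
        left, right, _ = self.merges[node - n]
        return self.leaf_set(left) | self.leaf_set(right)

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = [0.0] * n + [h for _, _, h in self.merges]

        def render(node: int, parent_height: float) -> str:
            blen = repr(float(parent_height - heights[node]))
            if node < n:
                return f"{self.leaves[node]}:{blen}"
            left, right, h = self.merges[node - n]
            return f"({render(left, h)},{render(right, h)}):{blen}"

        if not self.merges:
            return f"({self.leaves[0]}:0);" if n == 1 else ";"
        left, right, h = self.merges[-1]
        return f"({render(left, h)},{render(right, h)});"


def ternary_distance(
    a: np.ndarray,
    b: np.ndarray,
    a_missing: np.ndarray | None = None,
    b_missing: np.ndarray | None = None,
) -> float:
    """Mean |a_i - b_i| over coordinates where both calls are present; in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if a_missing is not None:
        ok &= ~np.asarray(a_missing, dtype=bool)
    if b_missing is not None:
        ok &= ~np.asarray(b_missing, dtype=bool)
    if not ok.any():
        raise ValueError("no shared non-missing coordinate between profiles")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def distance_matrix(
    calls: SegmentMatrix, region_mask: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise ternary distances between samples over the masked regions.

    ``region_mask`` is a boolean selector over regions (clustering may be
    restricted to the chromosomes or highlighted segments of interest);
    None uses every region.
    """
    if region_mask is None:
        region_mask = np.ones(calls.n_regions, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != (calls.n_regions,):
        raise ValueError("region_mask shape must be (n_regions,)")
    if not region_mask.any():
        raise ValueError("region mask selects no regions")
    v = calls.values[region_mask]
    miss = calls.missing[region_mask]
    n = calls.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ternary_distance(
                v[:, i], v[:, j], miss[:, i], miss[:, j]
            )
    return d


def upgma(d: np.ndarray, ids: list[str]) -> ClusterTree:
    """Average-linkage agglomeration of a symmetric distance matrix."""
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have zero diagonal")

    # active clusters: creation index -> (node id, size); distances in a dict
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])
    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_index = n
    while len(active) > 1:
        best = min(dist, key=lambda pair: (dist[pair], pair))
        height = dist[best]
        i, j = best
        node_i, size_i = active[i]
        node_j, size_j = active[j]
        merges.append((node_i, node_j, height))
        del active[i], active[j]
        new_dist: dict[int, float] = {}
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[k] = (size_i * dik + size_j * djk) / (size_i + size_j)
        dist = {
            pair: v for pair, v in dist.items() if i not in pair and j not in pair
        }
        for k, v in new_dist.items():
            dist[(min(k, next_index), max(k, next_index))] = v
        active[next_index] = (n + len(merges) - 1, size_i + size_j)
        next_index += 1
    return ClusterTree(list(ids), merges)


def cophenetic(tree: ClusterTree) -> np.ndarray:
    """Matrix of merge heights at which each leaf pair first joins."""
    n = tree.n_leaves
    coph = np.zeros((n, n))
    for idx, (left, right, height) in enumerate(tree.merges):
        for a in tree.leaf_set(left):
            for b in tree.leaf_set(right):
                coph[a, b] = coph[b, a] = height
    return coph


def cut_tree(tree: ClusterTree, k: int) -> GroupLabels:
    """Cut the dendrogram into k groups by removing the k-1 highest merges.

    Groups are named cluster_1, cluster_2, ... in order of each group's
    first leaf.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for left, right, _ in tree.merges[: n - k]:
        la = sorted(tree.leaf_set(left))[0]
        lb = sorted(tree.leaf_set(right))[0]
        parent[find(la)] = find(lb)
    names: dict[int, str] = {}
    labels = GroupLabels()
    for leaf in range(n):
        root = find(leaf)
        if root not in names:
            names[root] = f"cluster_{len(names) + 1}"
        labels[tree.leaves[leaf]] = names[root]
    return labels


def reassign(labels: GroupLabels, sample: str, new_group: str) -> GroupLabels:
    """Manual correction of a clustering: move one sample to another group."""
    if sample not in labels:
        raise KeyError(f"unknown sample {sample!r}")
    out = GroupLabels(labels)
    out[sample] = new_group
    return out
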
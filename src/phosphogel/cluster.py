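"""UPGMA clustering of phosphoproteins on |RC|-derived distances.

Significant phosphoproteins are clustered by unweighted pair-group average
linkage (UPGMA) on the matrix of pairwise absolute differences of their
|RC| values, d(i, j) = ||rc_i| - |rc_j||. The absolute values are compared
(rather than signed RCs) because a "strong change" cluster can legitimately
mix directions: a protein unique to the control group (RC near -1) changes
as strongly as one unique to the treated group (RC near +1). The signed
metric |rc_i - rc_j| is available as an option.

The dendrogram is ultrametric (merge height = half the merged distance,
monotone along every root-to-leaf path); cutting at the root yields the
two major clusters, whose mean |RC| values are summarized with
bias-corrected percentile bootstrap CIs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .stats import bc_bootstrap_ci


@dataclass
class DendrogramNode:
    """Binary UPGMA tree node; leaves carry labels and height 0."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for ch in self.children for l in ch.leaves()]

    def cophenetic(self) -> dict[tuple[str, str], float]:
        """Pairwise cophenetic distances (2x the merge height of the LCA)."""
        out: dict[tuple[str, str], float] = {}

        def walk(node):
            if node.is_leaf:
                return
            left, right = node.children
            for a in left.leaves():
                for b in right.leaves():
                    key = (a, b) if a <= b else (b, a)
                    out[key] = 2.0 * node.height
            walk(left)
            walk(right)

        walk(self)
        return out


@dataclass
class ClusterSummary:
    """One of the two major clusters with its mean |RC| and bootstrap CI."""

    cluster_id: int
    members: list[str]
    mean_abs_rc: float
    ci: tuple[float, float]
    conf: float


def rc_distance_matrix(rc_values: dict[str, float], signed: bool = False):
    """Pairwise distance matrix over RC values.

    Default metric: d(i, j) = ||rc_i| - |rc_j|| (magnitude of change);
    ``signed=True`` uses |rc_i - rc_j| instead. Returns ``(matrix, labels)``
    with labels in input order.
    """
    labels = list(rc_values)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    v = np.array([rc_values[l] for l in labels], dtype=float)
    if not signed:
        v = np.abs(v)
    d = np.abs(v[:, None] - v[None, :])
    return d, labels


def upgma(dist: np.ndarray, labels: list[str]) -> DendrogramNode:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    At each step the pair of clusters at minimal average cross-pair distance
    is merged at height d/2; the inter-cluster distance to every other
    cluster is updated as the size-weighted arithmetic mean of all cross
    pairs. Ties are broken deterministically by the lexicographically lowest
    pair of cluster labels (a cluster is labelled by its smallest member).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels do not match")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    if n == 1:
        return DendrogramNode(height=0.0, label=labels[0])

    nodes = {i: DendrogramNode(height=0.0, label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    names = {i: str(labels[i]) for i in range(n)}  # smallest member label
    dm = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            dm.items(),
            key=lambda kv: (kv[1], tuple(sorted((names[kv[0][0]], names[kv[0][1]])))),
        )
        (i, j), dij = best
        node = DendrogramNode(height=dij / 2.0, children=(nodes[i], nodes[j]))
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        names[next_id] = min(names[i], names[j])
        active -= {i, j}
        for k in active:
            dik = dm.pop((min(i, k), max(i, k)))
            djk = dm.pop((min(j, k), max(j, k)))
            dm[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / sizes[next_id]
        del dm[(i, j)]
        active.add(next_id)
        nodes.pop(i), nodes.pop(j)
        next_id += 1
    return nodes[next_id - 1]


def cut_two_clusters(tree: DendrogramNode) -> tuple[list[str], list[str]]:
    """Remove the root: the two subtrees' leaf sets are the major clusters."""
    if tree.is_leaf:
        raise ValueError("tree has a single leaf; nothing to cut")
    left, right = tree.children
    return left.leaves(), right.leaves()


def cluster_mean_ci(members: list[str], rc_values: dict[str, float],
                    conf: float = 0.99, n_boot: int = 20_000, seed=None,
                    cluster_id: int = 1) -> ClusterSummary:
    """Mean |RC| of a cluster with its BC percentile bootstrap CI.

    Single-member clusters (and clusters of identical |RC|) get the
    degenerate interval (v, v).
    """
    if not members:
        raise ValueError("cluster has no members")
    vals = np.abs(np.array([rc_values[m] for m in members], dtype=float))
    mean = float(vals.mean())
    if vals.size == 1:
        ci = (mean, mean)
    else:
        ci = bc_bootstrap_ci(vals, conf=conf, n_boot=n_boot, seed=seed)
    return ClusterSummary(cluster_id=cluster_id, members=list(members),
                          mean_abs_rc=mean, ci=ci, conf=conf)


def two_cluster_summaries(rc_values: dict[str, float], conf: float = 0.99,
                          n_boot: int = 20_000, seed=None, signed: bool = False):
    """Cluster, cut at the root and summarize both clusters.

    Cluster 1 is the one with the higher mean |RC|. Returns
    ``(tree, [summary1, summary2])``.
    """
    d, labels = rc_distance_matrix(rc_values, signed=signed)
    tree = upgma(d, labels)
    a, b = cut_two_clusters(tree)
    sa = cluster_mean_ci(a, rc_values, conf, n_boot, seed, cluster_id=1)
    sb = cluster_mean_ci(b, rc_values, conf, n_boot, seed, cluster_id=2)
    if sb.mean_abs_rc > sa.mean_abs_rc:
        sa, sb = sb, sa
        sa.cluster_id, sb.cluster_id = 1, 2
    return tree, [sa, sb]


def clusters_differ(summaries) -> bool:
    """Cluster-difference call: True when the two CIs do not overlap."""
    (l1, u1), (l2, u2) = summaries[0].ci, summaries[1].ci
    return l1 > u2 or l2 > u1


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: DendrogramNode) -> str:
    """Newick serialization with branch lengths = height differences."""

    def fmt(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{length:g}"
        left, right = node.children
        inner = f"({fmt(left, node.height)},{fmt(right, node.height)})"
        return f"{inner}:{length:g}"

    if tree.is_leaf:
        return f"{_newick_label(tree.label)}:0;"
    left, right = tree.children
    return f"({fmt(left, tree.height)},{fmt(right, tree.height)});"
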
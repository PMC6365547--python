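"""Topological-overlap similarity and hierarchical clustering.

The module-detection heuristic: bones that articulate with the same other
bones likely belong to the same anatomical module.  Topological overlap
between nodes *i* and *j* is

    TO(i, j) = J(i, j) / min(k_i, k_j)

where ``J`` is the number of neighbors the two nodes share and ``k`` their
degrees.  TO is 1 when the nodes connect to exactly the same other nodes
and 0 when their neighborhoods are disjoint.  ``1 - TO`` is then used as a
dissimilarity for agglomerative hierarchical clustering, producing the
dendrogram that the partition-selection stage cuts.

Two variants are available for sensitivity analysis and are off by
default:

* ``adjacency_correction`` — the weighted-network-style TOM that adds the
  direct adjacency to the numerator and corrects the denominator:
  ``(J + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
* ``m > 1`` — generalized (m-step) overlap: neighborhoods are all nodes
  reachable within ``m`` links (excluding the node itself).

Clustering is deterministic: ties between candidate merges are broken by
the smallest lexicographic pair of cluster label sets, so a given network
always yields the same dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .net_model import AnatomicalNetwork

__all__ = [
    "TOMatrix",
    "MergeTree",
    "topological_overlap",
    "to_dissimilarity",
    "hierarchical_cluster",
]

LINKAGES = ("average", "single", "complete")

#: Absolute tolerance for treating two merge heights as tied.
_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class TOMatrix:
    """Symmetric topological-overlap similarity, entries in [0, 1], unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"TO matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("TO matrix must be symmetric")
        if v.min() < -_TIE_ATOL or v.max() > 1 + _TIE_ATOL:
            raise ValueError("TO entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _m_step_neighborhoods(net: AnatomicalNetwork, m: int) -> list[set[int]]:
    """Index sets of nodes reachable within m links, excluding the node itself."""
    idx = {l: i for i, l in enumerate(net.labels)}
    adj: list[set[int]] = [set() for _ in net.labels]
    for a, b in net.edges:
        adj[idx[a]].add(idx[b])
        adj[idx[b]].add(idx[a])
    if m == 1:
        return adj
    hoods: list[set[int]] = []
    for i in range(net.n):
        frontier = {i}
        reached = {i}
        for _ in range(m):
            frontier = {w for v in frontier for w in adj[v]} - reached
            if not frontier:
                break
            reached |= frontier
        hoods.append(reached - {i})
    return hoods


def topological_overlap(
    net: AnatomicalNetwork,
    m: int = 1,
    adjacency_correction: bool = False,
) -> TOMatrix:
    """Pairwise topological overlap of all nodes.

    The plain (default) form counts strictly common neighbors: ``J``
    excludes the two nodes themselves and the direct i–j adjacency is not
    added.  Pairs where either node has an empty neighborhood get TO = 0;
    the diagonal is defined as 1.
    """
    if m < 1:
        raise ValueError("neighborhood depth m must be >= 1")
    hoods = _m_step_neighborhoods(net, m)
    sizes = np.array([len(h) for h in hoods], dtype=float)
    idx = {l: i for i, l in enumerate(net.labels)}
    n = net.n
    adj = np.zeros((n, n), dtype=float)
    for a, b in net.edges:
        adj[idx[a], idx[b]] = 1.0
        adj[idx[b], idx[a]] = 1.0

    to = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            shared = len((hoods[i] & hoods[j]) - {i, j})
            low = min(sizes[i], sizes[j])
            if adjacency_correction:
                a_ij = adj[i, j]
                denom = low + 1.0 - a_ij
                val = (shared + a_ij) / denom if denom > 0 else 0.0
            else:
                val = shared / low if low > 0 else 0.0
            to[i, j] = to[j, i] = val
    np.fill_diagonal(to, 1.0)
    return TOMatrix(labels=net.labels, values=to)


def to_dissimilarity(tom: TOMatrix) -> pd.DataFrame:
    """Entrywise ``1 - TO`` with a zero diagonal, as a labeled DataFrame."""
    dis = 1.0 - tom.values
    np.fill_diagonal(dis, 0.0)
    return pd.DataFrame(dis, index=list(tom.labels), columns=list(tom.labels))


@dataclass(frozen=True)
class MergeTree:
    """Binary merge hierarchy from agglomerative clustering.

    Leaves are numbered ``0 .. N-1`` in ``labels`` order; the internal
    node created by merge step ``s`` (0-based) has id ``N + s``.  Each
    merge records its two child node ids and the dissimilarity height at
    which they join; heights are non-decreasing along the merge sequence.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(b < a - _TIE_ATOL for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @cached_property
    def _members(self) -> tuple[frozenset[str], ...]:
        """Member label set of every node id (leaves then internal nodes)."""
        members: list[frozenset[str]] = [frozenset({l}) for l in self.labels]
        for left, right, _ in self.merges:
            members.append(members[left] | members[right])
        return tuple(members)

    def members(self, node_id: int) -> frozenset[str]:
        return self._members[node_id]

    def internal_nodes(self) -> list[tuple[int, frozenset[str], float]]:
        """(node id, member set, height) for every internal node, in merge order."""
        n = self.n_leaves
        return [
            (n + s, self._members[n + s], h)
            for s, (_, _, h) in enumerate(self.merges)
        ]

    def cut(self, threshold: float) -> list[frozenset[str]]:
        """Clusters from the horizontal cut at ``threshold``.

        Applies every merge with height strictly below the threshold; the
        resulting clusters are returned ordered by their first label in
        leaf order.
        """
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for s, (left, right, h) in enumerate(self.merges):
            if h < threshold:
                new = n + s
                parent[find(left)] = new
                parent[find(right)] = new
        groups: dict[int, list[str]] = {}
        for i, label in enumerate(self.labels):
            groups.setdefault(find(i), []).append(label)
        order = {l: i for i, l in enumerate(self.labels)}
        return [
            frozenset(g)
            for g in sorted(groups.values(), key=lambda g: min(order[l] for l in g))
        ]

    def merge_table(self) -> pd.DataFrame:
        """Flat merge table: step, the two children, and the merge height.

        Children are named by their own label for leaves and ``node<step>``
        for internal nodes.
        """
        n = self.n_leaves

        def node_name(node_id: int) -> str:
            return (
                self.labels[node_id] if node_id < n else f"node{node_id - n}"
            )

        rows = [
            {
                "step": s,
                "child1": node_name(left),
                "child2": node_name(right),
                "height": h,
            }
            for s, (left, right, h) in enumerate(self.merges)
        ]
        return pd.DataFrame(rows, columns=["step", "child1", "child2", "height"])

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences.

        A node's branch length is its parent's merge height minus its own
        height (leaves sit at height 0), so root-to-leaf path lengths equal
        the root merge height.
        """
        n = self.n_leaves
        height = [0.0] * n + [h for _, _, h in self.merges]

        def quote(label: str) -> str:
            if any(c in label for c in "():;,' \t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(node_id: int) -> str:
            if node_id < n:
                return quote(self.labels[node_id])
            left, right, h = self.merges[node_id - n]
            parts = [
                f"{render(child)}:{max(h - height[child], 0.0):.10g}"
                for child in (left, right)
            ]
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def _as_matrix(dis: pd.DataFrame | np.ndarray, labels=None):
    if isinstance(dis, pd.DataFrame):
        return dis.to_numpy(dtype=float), tuple(str(c) for c in dis.columns)
    if labels is None:
        raise ValueError("labels required when dissimilarity is a bare array")
    return np.asarray(dis, dtype=float), tuple(labels)


def hierarchical_cluster(
    dis: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    labels: tuple[str, ...] | None = None,
) -> MergeTree:
    """Agglomerative clustering of a dissimilarity matrix into a MergeTree.

    Cluster–cluster dissimilarity is computed from the original matrix at
    every step: the mean (``average``, the default/UPGMA), minimum
    (``single``) or maximum (``complete``) over all cross pairs.  Among
    merges tied at the minimal height the pair whose (sorted) label sets
    are lexicographically smallest is chosen, making the tree a pure
    function of the input.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    mat, lab = _as_matrix(dis, labels)
    n = len(lab)
    if mat.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("dissimilarity diagonal must be zero")
    if n < 2:
        raise ValueError("need at least two items to cluster")

    # active clusters: node id -> (member indices, sorted member labels)
    active: dict[int, tuple[list[int], tuple[str, ...]]] = {
        i: ([i], (lab[i],)) for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []

    def link_value(members_a: list[int], members_b: list[int]) -> float:
        block = mat[np.ix_(members_a, members_b)]
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        return float(block.max())

    for step in range(n - 1):
        best: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_pair: tuple[int, int] | None = None
        best_d = np.inf
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = link_value(active[a][0], active[b][0])
                if d < best_d - _TIE_ATOL:
                    tie = False
                elif d <= best_d + _TIE_ATOL:
                    tie = True
                else:
                    continue
                key = tuple(sorted((active[a][1], active[b][1])))
                if not tie or best is None or key < best:
                    best_d = min(best_d, d)
                    best = key
                    best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        new_id = n + step
        merged_members = active[a][0] + active[b][0]
        merged_labels = tuple(sorted(active[a][1] + active[b][1]))
        merges.append((a, b, best_d))
        del active[a], active[b]
        active[new_id] = (merged_members, merged_labels)

    return MergeTree(labels=lab, merges=tuple(merges))
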
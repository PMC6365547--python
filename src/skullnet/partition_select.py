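"""Modularity scoring of dendrogram cuts and jackknife error of Q_max.

Newman–Girvan modularity of a partition into modules s = 1..m:

    Q = sum_s [ l_s / K  -  (d_s / 2K)^2 ]

with ``l_s`` the number of links inside module s, ``d_s`` the summed
degree of its nodes, and ``K`` the total link count.  Q is near 0 when
within-module link density is no better than random and approaches 1 for
strongly separated modules; strongly modular networks typically score
between 0.3 and 0.7.

The dendrogram is cut horizontally immediately below each merge height
(plus the one-module root partition); the cut with the highest Q defines
the Q-modules.  The expected error of Q_max treats every link as an
independent observation: a delete-one-link jackknife recomputes Q for
each leave-one-out network under the same, fixed partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .net_model import AnatomicalNetwork
from .tom_cluster import MergeTree

import math

__all__ = [
    "Partition",
    "modularity_q",
    "candidate_cuts",
    "best_partition",
    "jackknife_q_error",
]

#: Q ties within this tolerance are broken toward fewer modules.
_Q_ATOL = 1e-12


@dataclass
class Partition:
    """A node→module assignment with its modularity score.

    Module ids are contiguous integers starting at 1, numbered by first
    appearance in the network's label order.
    """

    assignment: dict[str, int]
    q: float
    q_error: Optional[float] = None

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"module ids must be contiguous from 1, got {ids}")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> list[tuple[str, ...]]:
        """Member labels per module, in module-id order."""
        groups: dict[int, list[str]] = {}
        for label, mod in self.assignment.items():
            groups.setdefault(mod, []).append(label)
        return [tuple(sorted(groups[m])) for m in sorted(groups)]


def _number_modules(
    net: AnatomicalNetwork, clusters: Sequence[frozenset[str]]
) -> dict[str, int]:
    """Assign contiguous module ids by first label appearance."""
    order = {l: i for i, l in enumerate(net.labels)}
    ranked = sorted(clusters, key=lambda c: min(order[l] for l in c))
    assignment: dict[str, int] = {}
    for mod_id, cluster in enumerate(ranked, start=1):
        for label in cluster:
            assignment[label] = mod_id
    return assignment


def modularity_q(net: AnatomicalNetwork, partition: Mapping[str, int]) -> float:
    """Newman–Girvan Q of a full node→module assignment.

    Isolated nodes contribute nothing to either term of their module.
    """
    if net.k < 1:
        raise ValueError("modularity undefined for a network without links")
    missing = [l for l in net.labels if l not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    k = net.k
    internal: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for label in net.labels:
        degsum.setdefault(partition[label], 0)
    for a, b in net.edges:
        degsum[partition[a]] += 1
        degsum[partition[b]] += 1
        if partition[a] == partition[b]:
            internal[partition[a]] = internal.get(partition[a], 0) + 1
    return sum(
        internal.get(s, 0) / k - (degsum[s] / (2 * k)) ** 2 for s in degsum
    )


def candidate_cuts(tree: MergeTree) -> list[list[frozenset[str]]]:
    """Partitions induced by every horizontal cut of the dendrogram.

    One cut immediately below each distinct merge height (all merges
    strictly lower are applied), plus the one-module root partition.
    """
    partitions = []
    seen_heights: set[float] = set()
    for _, _, h in tree.merges:
        if h not in seen_heights:
            seen_heights.add(h)
            partitions.append(tree.cut(h))
    root_height = tree.merges[-1][2] if tree.merges else 0.0
    partitions.append(tree.cut(root_height + 1.0))
    return partitions


def best_partition(net: AnatomicalNetwork, tree: MergeTree) -> Partition:
    """The dendrogram cut maximizing Q; ties go to fewer modules."""
    if set(tree.labels) != set(net.labels):
        raise ValueError("tree leaves do not match network nodes")
    best_clusters: Optional[list[frozenset[str]]] = None
    best_q = -math.inf
    for clusters in candidate_cuts(tree):
        assignment = _number_modules(net, clusters)
        q = modularity_q(net, assignment)
        if q > best_q + _Q_ATOL:
            better = True
        elif q >= best_q - _Q_ATOL and best_clusters is not None:
            better = len(clusters) < len(best_clusters)
        else:
            better = False
        if better:
            best_q = max(best_q, q) if best_clusters is not None else q
            best_clusters = clusters
    assert best_clusters is not None
    assignment = _number_modules(net, best_clusters)
    return Partition(assignment=assignment, q=modularity_q(net, assignment))


def jackknife_q_error(
    net: AnatomicalNetwork, partition: Partition | Mapping[str, int]
) -> float:
    """Delete-one-link jackknife standard error of Q at a fixed partition.

    For each link e the network minus e is rescored under the same module
    assignment, giving K leave-one-out values Q_(e); the standard error is

        SE = sqrt( (K-1)/K * sum_e (Q_(e) - mean)^2 )

    The partition is NOT re-estimated per replicate: the jackknife
    quantifies sampling noise of the Q statistic given the identified
    modules, with links as the independent observations.
    """
    assignment = (
        partition.assignment if isinstance(partition, Partition) else dict(partition)
    )
    if net.k < 2:
        raise ValueError("jackknife needs at least two links")
    replicates = [
        modularity_q(net.without_edge(a, b), assignment) for a, b in sorted(net.edges)
    ]
    k = len(replicates)
    mean = sum(replicates) / k
    return math.sqrt((k - 1) / k * sum((q - mean) ** 2 for q in replicates))
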
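"""Topological descriptors of a bone-contact network.

Six whole-network parameters summarize skull architecture:

* ``N`` — number of nodes (skeletal elements).
* ``K`` — number of links (physical contacts).
* ``D`` — density of connections, ``2K / (N(N-1))``; read as a proxy of
  morphological complexity.
* ``C`` — mean clustering coefficient, the average over nodes of the
  fraction of a node's neighbor pairs that are themselves connected; a
  proxy of anatomical integration.  Nodes of degree < 2 have no neighbor
  pair and are excluded from the average (the igraph local-transitivity
  convention), not counted as zero.
* ``Lpath`` — mean shortest path length over all reachable unordered node
  pairs; unreachable pairs (separate connected components) are excluded,
  so disconnected networks still get a finite value.  Lower values read
  as greater integration.
* ``H`` — heterogeneity of connections: sample standard deviation of the
  degree sequence divided by its mean; a proxy of anisomerism
  (differentiation among parts).  ``H = 0`` iff all degrees are equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .net_model import AnatomicalNetwork

logger = logging.getLogger("skullnet")

__all__ = [
    "DescriptorSet",
    "DegenerateNetworkError",
    "compute_density",
    "compute_mean_clustering",
    "compute_mean_path_length",
    "compute_heterogeneity",
    "compute_descriptors",
]

#: Column order of the comparative descriptor table (downstream modules
#: fill the last four).
TABLE_COLUMNS = (
    "name",
    "N",
    "K",
    "D",
    "C",
    "Lpath",
    "H",
    "S_modules",
    "Q_modules",
    "Qmax",
    "Qmax_error",
)


class DegenerateNetworkError(ValueError):
    """Raised when a descriptor is undefined for the given network."""


@dataclass
class DescriptorSet:
    """One comparative-table row for a network.

    The module-analysis fields (``S_modules``, ``Q_modules``, ``Qmax``,
    ``Qmax_error``) stay ``None`` until filled by the partitioning and
    significance stages.
    """

    name: str
    N: int
    K: int
    D: float
    C: float
    Lpath: float
    H: float
    S_modules: Optional[int] = None
    Q_modules: Optional[int] = None
    Qmax: Optional[float] = None
    Qmax_error: Optional[float] = None

    def as_row(self) -> dict:
        return {col: getattr(self, col) for col in TABLE_COLUMNS}


def compute_density(net: AnatomicalNetwork) -> float:
    """Realized links over the maximum possible, ``K / (N(N-1)/2)``."""
    if net.n < 2:
        raise DegenerateNetworkError(f"density undefined for N={net.n} < 2")
    return net.k / (net.n * (net.n - 1) / 2)


def compute_mean_clustering(net: AnatomicalNetwork) -> float:
    """Mean local clustering coefficient over nodes of degree >= 2.

    Returns 0 (with a logged note) when no node has two neighbors, e.g.
    a pure chain or an empty graph.
    """
    g = net.to_networkx()
    local = nx.clustering(g)
    eligible = [local[v] for v in net.labels if g.degree(v) >= 2]
    if not eligible:
        logger.info(
            "network %r has no node of degree >= 2; mean clustering set to 0",
            net.name,
        )
        return 0.0
    return float(np.mean(eligible))


def compute_mean_path_length(net: AnatomicalNetwork) -> float:
    """Mean shortest-path distance over reachable unordered pairs.

    Pairs in different connected components are excluded from the mean,
    so a skull with fully detached elements (e.g. ear ossicles) still has
    a finite path length.
    """
    if net.k == 0:
        raise DegenerateNetworkError("mean path length undefined without edges")
    g = net.to_networkx()
    total = 0
    pairs = 0
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        sub = g.subgraph(component)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # drop the zero self-distance
    # each unordered pair was counted twice
    return total / pairs


def compute_heterogeneity(net: AnatomicalNetwork) -> float:
    """Sample standard deviation of the degree sequence over its mean."""
    if net.k < 1:
        raise DegenerateNetworkError("heterogeneity undefined with mean degree 0")
    deg = net.degree_sequence()
    mean = deg.mean()
    if net.n < 2:
        return 0.0
    return float(np.std(deg, ddof=1) / mean)


def compute_descriptors(net: AnatomicalNetwork) -> DescriptorSet:
    """Bundle all six descriptors for one network."""
    return DescriptorSet(
        name=net.name,
        N=net.n,
        K=net.k,
        D=compute_density(net),
        C=compute_mean_clustering(net),
        Lpath=compute_mean_path_length(net),
        H=compute_heterogeneity(net),
    )
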
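"""Independent brute-force oracles for cross-checking the pipeline.

Everything here is deliberately naive — neighbor sets, hand-rolled BFS,
full enumeration — and never calls into the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np

from skullnet.net_model import AnatomicalNetwork


def adjacency_sets(net: AnatomicalNetwork) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {l: set() for l in net.labels}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def density(net: AnatomicalNetwork) -> float:
    return 2 * net.k / (net.n * (net.n - 1))


def mean_clustering(net: AnatomicalNetwork) -> float:
    adj = adjacency_sets(net)
    vals = []
    for v in net.labels:
        neigh = sorted(adj[v])
        if len(neigh) < 2:
            continue
        closed = sum(
            1 for a, b in itertools.combinations(neigh, 2) if b in adj[a]
        )
        vals.append(closed / math.comb(len(neigh), 2))
    return sum(vals) / len(vals) if vals else 0.0


def mean_path_length(net: AnatomicalNetwork) -> float:
    adj = adjacency_sets(net)
    total = 0
    pairs = 0
    for src in net.labels:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        total += sum(dist.values())
        pairs += len(dist) - 1
    return total / pairs


def heterogeneity(net: AnatomicalNetwork) -> float:
    adj = adjacency_sets(net)
    deg = [len(adj[v]) for v in net.labels]
    mean = sum(deg) / len(deg)
    var = sum((d - mean) ** 2 for d in deg) / (len(deg) - 1)
    return math.sqrt(var) / mean


def topological_overlap(net: AnatomicalNetwork) -> dict[tuple[str, str], float]:
    """Plain one-step TO for every unordered pair, by set intersection."""
    adj = adjacency_sets(net)
    out = {}
    for a, b in itertools.combinations(net.labels, 2):
        shared = (adj[a] & adj[b]) - {a, b}
        low = min(len(adj[a]), len(adj[b]))
        out[(a, b)] = len(shared) / low if low else 0.0
    return out


def modularity(net: AnatomicalNetwork, assignment: dict[str, int]) -> float:
    """Newman-Girvan Q via networkx community modularity."""
    modules: dict[int, set[str]] = {}
    for label, mod in assignment.items():
        modules.setdefault(mod, set()).add(label)
    return nx.community.modularity(net.to_networkx(), modules.values())


def jackknife_se(net: AnatomicalNetwork, assignment: dict[str, int]) -> float:
    reps = []
    for edge in net.edges:
        reduced = AnatomicalNetwork(net.labels, net.edges - {edge}, net.name)
        reps.append(modularity(reduced, assignment))
    k = len(reps)
    mean = sum(reps) / k
    return math.sqrt((k - 1) / k * sum((q - mean) ** 2 for q in reps))


def exact_rank_sum_greater(x, y) -> float:
    """One-sided (greater) exact rank-sum p by full enumeration (midranks)."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        midrank = (i + 1 + j) / 2
        for t in range(i, j):
            ranks[order[t]] = midrank
        i = j
    obs = sum(ranks[: len(x)])
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if sum(ranks[i] for i in idx) >= obs - 1e-9:
            hits += 1
    return hits / total


def random_network(seed: int, n_min: int = 5, n_max: int = 30) -> AnatomicalNetwork:
    """Seeded G(n, p) with at least one edge, labels in fixed order."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.08, 0.5))
    labels = [f"n{i:02d}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        edges = [(labels[0], labels[1])]
    return AnatomicalNetwork.from_edges(labels, edges, name=f"rand{seed}")
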
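"""Statistical significance of dendrogram clusters (S-modules).

A module, in the network sense, is a group of nodes more connected among
themselves than to the rest.  For every candidate cluster we split each
member's degree into internal links (to other members) and external links
(to non-members) and run a two-sample Wilcoxon rank-sum test of the
internal against the external degree vector, one-sided by default
(H0: internal = external; HA: internal > external).  Clusters significant
at p < 0.05 are S-modules; the 0.05 / 0.01 / 0.001 thresholds double as
the tier code used to annotate dendrograms.

No multiple-testing correction is applied; reports carry the number of
tests performed so readers can judge the family-wise error themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .net_model import AnatomicalNetwork
from .tom_cluster import MergeTree

__all__ = [
    "ClusterTest",
    "rank_sum_p",
    "wilcoxon_module_test",
    "test_all_clusters",
    "count_s_modules",
    "maximal_significant_clusters",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001)

#: Largest per-sample size for which the tie-free exact null distribution
#: is used.
_EXACT_LIMIT = 25

#: With ties present, full permutation enumeration is used as long as the
#: number of group assignments C(n1+n2, n1) stays below this bound.
_EXACT_TIE_COMBINATIONS = 20_000


@dataclass(frozen=True)
class ClusterTest:
    """One dendrogram cluster with its connectivity test.

    ``internal[i] + external[i]`` equals the total degree of member ``i``.
    ``tier`` is "none" or the strongest threshold passed
    ("p<0.05" / "p<0.01" / "p<0.001").
    """

    cluster_id: int
    members: tuple[str, ...]
    internal: tuple[int, ...]
    external: tuple[int, ...]
    p_value: float
    tier: str

    @property
    def size(self) -> int:
        return len(self.members)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _tier(p: float, thresholds: Sequence[float]) -> str:
    passed = [t for t in sorted(thresholds, reverse=True) if p < t]
    return f"p<{passed[-1]:g}" if passed else "none"


def _exact_tie_p(pooled: np.ndarray, n1: int, alternative: str) -> float:
    """Exact permutation p-value on midranks, valid with ties.

    Enumerates every assignment of n1 of the pooled observations to the
    first sample and compares the resulting rank sums with the observed
    one.
    """
    from itertools import combinations

    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    tol = 1e-9
    ge = le = extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w >= obs - tol:
            ge += 1
        if w <= obs + tol:
            le += 1
        if abs(w - mean) >= abs(obs - mean) - tol:
            extreme += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return extreme / total


def rank_sum_p(
    internal: Sequence[int],
    external: Sequence[int],
    alternative: str = "greater",
) -> float:
    """Two-sample Wilcoxon rank-sum p-value for internal vs external degrees.

    The null is evaluated exactly whenever feasible: the classical exact
    rank-sum distribution when both samples have at most 25 observations
    and the pooled data are tie-free, and a full midrank permutation
    enumeration when ties are present but the number of group assignments
    is small.  Degree vectors are small integers, so ties are the rule —
    the tied-zeros vector of a fully detached module still gets its exact
    minimal p this way.  Larger tied samples fall back to the normal
    approximation with tie and continuity correction (the R
    ``wilcox.test`` behavior).
    """
    x = np.asarray(internal, dtype=float)
    y = np.asarray(external, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully degenerate data carry no evidence either way
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(x) <= _EXACT_LIMIT and len(y) <= _EXACT_LIMIT:
        method = "exact"
    elif not tie_free and math.comb(len(pooled), len(x)) <= _EXACT_TIE_COMBINATIONS:
        return _exact_tie_p(pooled, len(x), alternative)
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue
    )


def wilcoxon_module_test(
    net: AnatomicalNetwork,
    members: Sequence[str] | frozenset[str],
    alternative: str = "greater",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    cluster_id: int = -1,
) -> ClusterTest:
    """Test whether a candidate module's internal connectivity exceeds its external.

    ``members`` must be a strict, non-trivial subset of the network's
    nodes (at least 2 members, fewer than all).
    """
    member_set = set(members)
    unknown = member_set - set(net.labels)
    if unknown:
        raise ValueError(f"members not in network: {sorted(unknown)[:5]}")
    if not 2 <= len(member_set) < net.n:
        raise ValueError(
            f"members must be a strict subset with >= 2 nodes, got {len(member_set)}"
            f" of {net.n}"
        )
    ordered = tuple(l for l in net.labels if l in member_set)
    internal = []
    external = []
    for label in ordered:
        neigh = net.neighbors(label)
        inside = len(neigh & member_set)
        internal.append(inside)
        external.append(len(neigh) - inside)
    p = rank_sum_p(internal, external, alternative=alternative)
    return ClusterTest(
        cluster_id=cluster_id,
        members=ordered,
        internal=tuple(internal),
        external=tuple(external),
        p_value=p,
        tier=_tier(p, thresholds),
    )


def test_all_clusters(
    net: AnatomicalNetwork,
    tree: MergeTree,
    alternative: str = "greater",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[ClusterTest]:
    """One ClusterTest per internal dendrogram node, in merge order.

    The root cluster contains every node, hence has no external links to
    compare against, and is skipped.
    """
    tests = []
    for node_id, members, _ in tree.internal_nodes():
        if len(members) >= net.n:
            continue  # root: the test is undefined without outside nodes
        tests.append(
            wilcoxon_module_test(
                net,
                members,
                alternative=alternative,
                thresholds=thresholds,
                cluster_id=node_id,
            )
        )
    return tests


def count_s_modules(tests: Sequence[ClusterTest], alpha: float = 0.05) -> int:
    """Number of significant clusters (nested significant clusters all count)."""
    return sum(1 for t in tests if t.significant(alpha))


def maximal_significant_clusters(
    tests: Sequence[ClusterTest], alpha: float = 0.05
) -> list[ClusterTest]:
    """The maximal non-overlapping significant clusters.

    Significant clusters are scanned largest-first; a cluster is kept
    unless its member set overlaps an already-kept (hence enclosing or
    disjoint larger) cluster.
    """
    kept: list[ClusterTest] = []
    covered: set[str] = set()
    for t in sorted(
        (t for t in tests if t.significant(alpha)),
        key=lambda t: (-t.size, t.members),
    ):
        if not covered & set(t.members):
            kept.append(t)
            covered |= set(t.members)
    return kept
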
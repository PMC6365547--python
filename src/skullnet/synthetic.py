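"""Synthetic bone-contact networks with known module structure.

Real skull networks are (a) modular — groups of bones articulate densely
among themselves and sparsely with the rest, (b) bilaterally symmetric —
left and right halves mirror each other and join through midline
elements, and (c) occasionally disconnected — elements like the
mammalian ear ossicles form small chains detached from the rest of the
skull.  The generators here emulate exactly those three features with a
planted-partition (stochastic block) model, so that module detection can
be validated against known ground truth without any empirical matrix.

What they do NOT emulate: real sutures are not independent coin flips —
bone contacts obey developmental and geometric constraints (planarity-ish
layouts, serial homology), and real degree distributions are shaped by
bone size and position.  Recovery results on these graphs therefore
certify the pipeline's correctness, not its power on any particular
empirical skull.

Default sizes (three blocks of eight, mirrored to ~48 nodes plus chains)
sit inside the 34–63-node range of amniote skull networks so runtimes
and Q values are comparable to real analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .net_model import AnatomicalNetwork

__all__ = [
    "SyntheticSpec",
    "generate_planted_partition",
    "generate_bilateral_skull",
    "fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-partition skull surrogate.

    Parameters
    ----------
    block_sizes
        Nodes per planted module (each >= 1); default three blocks of 8.
    p_in, p_out
        Within- and between-block link probabilities, ``0 <= p_out <
        p_in <= 1``.  Defaults (0.9 / 0.05) give strongly modular graphs
        whose Q_max falls in the 0.3–0.7 band typical of clearly modular
        networks.
    bilateral
        Mirror the blocks into ``L_`` / ``R_`` halves.
    midline
        Pairs of half-node names (x, y) adding the mirrored links
        ``L_x–R_y`` and ``L_y–R_x`` (a single ``L_x–R_x`` link when
        x == y), so the left/right swap stays an exact automorphism.
    detached_chains
        Lengths of path-graph components appended fully disconnected
        from the rest (ossicle-like).
    seed
        Seed of the pseudo-random generator; part of the spec so every
        draw is reproducible.
    """

    block_sizes: tuple[int, ...] = (8, 8, 8)
    p_in: float = 0.9
    p_out: float = 0.05
    bilateral: bool = False
    midline: tuple[tuple[str, str], ...] = ()
    detached_chains: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(
                f"require 0 <= p_out < p_in <= 1, got p_in={self.p_in},"
                f" p_out={self.p_out}"
            )
        total = sum(self.block_sizes) * (2 if self.bilateral else 1) + sum(
            self.detached_chains
        )
        if total < 4:
            raise ValueError(f"total nodes must be >= 4, got {total}")
        if self.midline and not self.bilateral:
            raise ValueError("midline pairs require bilateral=True")


def _half_names(block_sizes: Sequence[int]) -> list[list[str]]:
    return [
        [f"b{bi + 1}n{ni + 1}" for ni in range(size)]
        for bi, size in enumerate(block_sizes)
    ]


def _planted_edges(
    blocks: list[list[str]], p_in: float, p_out: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Draw block-model edges in a fixed pair order for reproducibility."""
    membership = {n: bi for bi, names in enumerate(blocks) for n in names}
    nodes = [n for names in blocks for n in names]
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        p = p_in if membership[a] == membership[b] else p_out
        if rng.random() < p:
            edges.append((a, b))
    return edges


def generate_planted_partition(
    spec: SyntheticSpec,
) -> tuple[AnatomicalNetwork, dict[str, int]]:
    """A planted-partition draw plus its ground-truth module labels.

    Bilateral specs delegate to :func:`generate_bilateral_skull`.  Planted
    labels are contiguous integers from 1 in block order.
    """
    if spec.bilateral:
        return generate_bilateral_skull(spec)
    rng = np.random.default_rng(spec.seed)
    blocks = _half_names(spec.block_sizes)
    edges = _planted_edges(blocks, spec.p_in, spec.p_out, rng)
    labels, planted = _append_chains(
        [n for b in blocks for n in b],
        {n: bi + 1 for bi, b in enumerate(blocks) for n in b},
        edges,
        spec.detached_chains,
    )
    net = AnatomicalNetwork.from_edges(
        labels, edges, name=f"planted_seed{spec.seed}"
    )
    return net, planted


def generate_bilateral_skull(
    spec: SyntheticSpec,
) -> tuple[AnatomicalNetwork, dict[str, int]]:
    """A mirrored two-half skull surrogate with midline links and chains.

    One half is drawn from the block model, duplicated with ``L_`` / ``R_``
    prefixes (so the within-half degree sequences are identical), midline
    links join declared pairs across the midline, and detached chains are
    appended.  Swapping the L/R prefixes is an exact automorphism of the
    result.
    """
    if not spec.bilateral:
        raise ValueError("spec.bilateral must be True")
    rng = np.random.default_rng(spec.seed)
    blocks = _half_names(spec.block_sizes)
    half_nodes = [n for b in blocks for n in b]
    half_edges = _planted_edges(blocks, spec.p_in, spec.p_out, rng)

    labels = [f"L_{n}" for n in half_nodes] + [f"R_{n}" for n in half_nodes]
    edges = [(f"L_{a}", f"L_{b}") for a, b in half_edges]
    edges += [(f"R_{a}", f"R_{b}") for a, b in half_edges]
    half_set = set(half_nodes)
    for x, y in spec.midline:
        if x not in half_set or y not in half_set:
            raise ValueError(f"midline pair ({x!r}, {y!r}) names unknown half nodes")
        edges.append((f"L_{x}", f"R_{y}"))
        if x != y:
            edges.append((f"L_{y}", f"R_{x}"))

    n_blocks = len(blocks)
    planted = {}
    for bi, names in enumerate(blocks):
        for n in names:
            planted[f"L_{n}"] = bi + 1
            planted[f"R_{n}"] = n_blocks + bi + 1
    labels, planted = _append_chains(labels, planted, edges, spec.detached_chains)
    net = AnatomicalNetwork.from_edges(
        labels, edges, name=f"bilateral_seed{spec.seed}"
    )
    return net, planted


def _append_chains(
    labels: list[str],
    planted: dict[str, int],
    edges: list[tuple[str, str]],
    chain_lengths: Sequence[int],
) -> tuple[list[str], dict[str, int]]:
    """Add detached path components; each chain is its own planted module."""
    next_module = max(planted.values(), default=0) + 1
    for ci, length in enumerate(chain_lengths):
        chain = [f"chain{ci + 1}n{j + 1}" for j in range(length)]
        labels = labels + chain
        for n in chain:
            planted[n] = next_module
        next_module += 1
        edges.extend(zip(chain, chain[1:]))
    return labels, planted


# -- hard-coded toy fixtures ------------------------------------------

FIXTURE_NAMES = ("triangle", "square", "star4", "path3", "two_triangle_bridge")


def fixture(name: str) -> AnatomicalNetwork:
    """Small closed-form networks used across the test examples.

    * ``triangle`` — K3; clustering 1, path length 1.
    * ``square`` — 4-cycle; no triangles, all degrees equal.
    * ``star4`` — hub with three leaves; degree sequence (3,1,1,1).
    * ``path3`` — a–b–c; mean path length 4/3.
    * ``two_triangle_bridge`` — two triangles joined by one bridge link
      (N=6, K=7); its best modular split is the two triangles with
      Q = 5/14.
    """
    if name == "triangle":
        return AnatomicalNetwork.from_edges(
            "abc", [("a", "b"), ("b", "c"), ("a", "c")], name=name
        )
    if name == "square":
        return AnatomicalNetwork.from_edges(
            "abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")], name=name
        )
    if name == "star4":
        return AnatomicalNetwork.from_edges(
            ["hub", "a", "b", "c"],
            [("hub", "a"), ("hub", "b"), ("hub", "c")],
            name=name,
        )
    if name == "path3":
        return AnatomicalNetwork.from_edges(
            "abc", [("a", "b"), ("b", "c")], name=name
        )
    if name == "two_triangle_bridge":
        return AnatomicalNetwork.from_edges(
            "abcdef",
            [
                ("a", "b"),
                ("b", "c"),
                ("a", "c"),
                ("d", "e"),
                ("e", "f"),
                ("d", "f"),
                ("c", "d"),
            ],
            name=name,
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
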
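"""Bone-contact network model and its file formats.

An anatomical network represents a skull (or any articulated skeleton) as a
simple graph: nodes are skeletal elements (bones), links are physical
contacts (sutures, articulations).  Networks are binary, undirected and
unweighted — a contact is present or absent.  Isolated nodes are legal:
elements such as the mammalian ear ossicles may articulate with nothing
else in the skull yet belong to the analysis.

Supported on-disk dialects:

``matrix-csv``
    UTF-8 comma-separated square adjacency matrix; first row and first
    column carry bone labels; cells are 0/1.
``matrix-xlsx``
    Same layout on the first worksheet of an Excel workbook.
``edge-list``
    Two-column CSV of label pairs, ``#`` comment lines allowed; an optional
    sidecar node list (one label per line) declares the full node set so
    that isolated nodes survive the round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("skullnet")

__all__ = [
    "AnatomicalNetwork",
    "InvalidNetworkError",
    "NonSquareMatrixError",
    "LabelMismatchError",
    "AsymmetricMatrixError",
    "NonBinaryCellError",
    "NonzeroDiagonalError",
    "SelfLoopError",
    "DuplicateLabelError",
    "UnknownLabelError",
    "EmptyInputError",
    "read_adjacency",
    "read_edge_list",
    "write_network",
]


class InvalidNetworkError(ValueError):
    """Base class for every validation failure on input networks."""


class NonSquareMatrixError(InvalidNetworkError):
    pass


class LabelMismatchError(InvalidNetworkError):
    pass


class AsymmetricMatrixError(InvalidNetworkError):
    pass


class NonBinaryCellError(InvalidNetworkError):
    pass


class NonzeroDiagonalError(InvalidNetworkError):
    pass


class SelfLoopError(InvalidNetworkError):
    pass


class DuplicateLabelError(InvalidNetworkError):
    pass


class UnknownLabelError(InvalidNetworkError):
    pass


class EmptyInputError(InvalidNetworkError):
    pass


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AnatomicalNetwork:
    """A labeled simple undirected binary graph of bones and articulations.

    Parameters
    ----------
    labels
        Ordered unique bone names.  Convention for paired elements: side
        prefix ``L_`` / ``R_``; midline bones carry no prefix.
    edges
        Unordered label pairs; stored canonically (lexicographically
        sorted within each pair).
    name
        Free-text identifier, e.g. the taxon.
    """

    labels: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            seen: set[str] = set()
            dup = next(l for l in self.labels if l in seen or seen.add(l))
            raise DuplicateLabelError(f"duplicate node label {dup!r}")
        label_set = set(self.labels)
        for a, b in self.edges:
            if a == b:
                raise SelfLoopError(f"self-loop on node {a!r}")
            if a not in label_set:
                raise UnknownLabelError(f"edge endpoint {a!r} is not a declared label")
            if b not in label_set:
                raise UnknownLabelError(f"edge endpoint {b!r} is not a declared label")
            if a > b:
                raise InvalidNetworkError(
                    f"edge {(a, b)!r} is not canonically ordered; use from_edges()"
                )

    @classmethod
    def from_edges(
        cls,
        labels: Iterable[str],
        edges: Iterable[tuple[str, str]],
        name: str = "",
    ) -> "AnatomicalNetwork":
        """Build a network, canonicalizing edge orientation."""
        return cls(
            labels=tuple(labels),
            edges=frozenset(_canonical_edge(a, b) for a, b in edges),
            name=name,
        )

    # -- basic topology ------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes (bones)."""
        return len(self.labels)

    @property
    def k(self) -> int:
        """Number of links (articulations)."""
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canonical_edge(a, b) in self.edges

    def neighbors(self, label: str) -> frozenset[str]:
        return frozenset(
            (b if a == label else a) for a, b in self.edges if label in (a, b)
        )

    def degree(self, label: str) -> int:
        return len(self.neighbors(label))

    def degree_sequence(self) -> np.ndarray:
        """Degrees in label order."""
        deg = dict.fromkeys(self.labels, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return np.array([deg[l] for l in self.labels], dtype=int)

    def adjacency_matrix(self) -> pd.DataFrame:
        """Dense 0/1 adjacency as a label-indexed DataFrame."""
        idx = {l: i for i, l in enumerate(self.labels)}
        mat = np.zeros((self.n, self.n), dtype=int)
        for a, b in self.edges:
            mat[idx[a], idx[b]] = 1
            mat[idx[b], idx[a]] = 1
        return pd.DataFrame(mat, index=list(self.labels), columns=list(self.labels))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.labels)
        g.add_edges_from(sorted(self.edges))
        return g

    def without_edge(self, a: str, b: str) -> "AnatomicalNetwork":
        e = _canonical_edge(a, b)
        if e not in self.edges:
            raise KeyError(f"edge {e!r} not in network")
        return AnatomicalNetwork(self.labels, self.edges - {e}, self.name)

    def relabeled(self, mapping: Mapping[str, str]) -> "AnatomicalNetwork":
        return AnatomicalNetwork.from_edges(
            (mapping.get(l, l) for l in self.labels),
            ((mapping.get(a, a), mapping.get(b, b)) for a, b in self.edges),
            name=self.name,
        )


# -- readers -----------------------------------------------------------


def _load_table(path: Path, dialect: str) -> pd.DataFrame:
    if dialect == "matrix-csv":
        return pd.read_csv(path, index_col=0, dtype=object)
    if dialect == "matrix-xlsx":
        return pd.read_excel(path, sheet_name=0, index_col=0, dtype=object)
    raise ValueError(f"unknown adjacency dialect {dialect!r}")


def read_adjacency(
    path: str | Path, dialect: str = "matrix-csv", name: str | None = None
) -> AnatomicalNetwork:
    """Read a labeled square 0/1 adjacency matrix.

    Labels are whitespace-trimmed but case-sensitive (supplement-style
    sheets often carry stray spaces).  The matrix must be square with
    matching row/column labels, binary, zero-diagonal and symmetric; each
    violation raises a distinct :class:`InvalidNetworkError` subclass
    naming the offending cell.
    """
    path = Path(path)
    table = _load_table(path, dialect)
    rows = [str(r).strip() for r in table.index]
    cols = [str(c).strip() for c in table.columns]
    if len(rows) != len(cols):
        raise NonSquareMatrixError(
            f"{path.name}: {len(rows)} rows but {len(cols)} columns"
        )
    if rows != cols:
        bad = next((r, c) for r, c in zip(rows, cols) if r != c)
        raise LabelMismatchError(
            f"{path.name}: row/column label mismatch at {bad[0]!r} vs {bad[1]!r}"
        )
    n = len(rows)
    mat = np.empty((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            raw = table.iat[i, j]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                val = np.nan
            if val not in (0.0, 1.0):
                raise NonBinaryCellError(
                    f"{path.name}: cell ({rows[i]}, {cols[j]}) = {raw!r} is not 0/1"
                )
            mat[i, j] = val
    for i in range(n):
        if mat[i, i] != 0:
            raise NonzeroDiagonalError(
                f"{path.name}: nonzero diagonal at ({rows[i]}, {rows[i]})"
            )
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] != mat[j, i]:
                raise AsymmetricMatrixError(
                    f"{path.name}: asymmetric pair ({rows[i]}, {rows[j]})="
                    f"{int(mat[i, j])} vs ({rows[j]}, {rows[i]})={int(mat[j, i])}"
                )
    edges = [
        (rows[i], rows[j]) for i in range(n) for j in range(i + 1, n) if mat[i, j] == 1
    ]
    return AnatomicalNetwork.from_edges(rows, edges, name=name or path.stem)


def read_edge_list(
    path: str | Path,
    nodes_path: str | Path | None = None,
    name: str | None = None,
) -> AnatomicalNetwork:
    """Read a two-column delimited edge list, optional ``#`` comments.

    Duplicate pairs (in either order) collapse to a single edge with a
    logged warning.  A sidecar node list (one label per line) may declare
    isolated nodes and fixes the label order.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2 or not all(parts):
            raise InvalidNetworkError(
                f"{path.name}:{lineno}: expected two comma-separated labels, got {line!r}"
            )
        a, b = parts
        if a == b:
            raise SelfLoopError(f"{path.name}:{lineno}: self-pair ({a!r}, {b!r})")
        pairs.append((a, b))
    if not pairs:
        raise EmptyInputError(f"{path.name}: no edges found")

    labels: list[str] = []
    seen: set[str] = set()
    if nodes_path is not None:
        for raw in Path(nodes_path).read_text(encoding="utf-8").splitlines():
            label = raw.strip()
            if label and not label.startswith("#") and label not in seen:
                labels.append(label)
                seen.add(label)
    for a, b in pairs:
        for l in (a, b):
            if l not in seen:
                labels.append(l)
                seen.add(l)

    edges: set[tuple[str, str]] = set()
    for a, b in pairs:
        e = _canonical_edge(a, b)
        if e in edges:
            logger.warning("%s: duplicate edge %s collapsed", path.name, e)
        edges.add(e)
    return AnatomicalNetwork.from_edges(labels, edges, name=name or path.stem)


# -- writer ------------------------------------------------------------


def write_network(
    net: AnatomicalNetwork,
    path: str | Path,
    dialect: str = "matrix-csv",
    nodes_path: str | Path | None = None,
) -> Path:
    """Write a network so that reading it back yields an identical network.

    For the edge-list dialect a ``nodes_path`` sidecar is written too
    (default: ``<path>.nodes``) because isolated nodes are otherwise not
    representable in an edge list.
    """
    path = Path(path)
    if dialect == "matrix-csv":
        net.adjacency_matrix().to_csv(path)
    elif dialect == "matrix-xlsx":
        net.adjacency_matrix().to_excel(path)
    elif dialect == "edge-list":
        lines = [f"{a},{b}" for a, b in sorted(net.edges)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        sidecar = Path(nodes_path) if nodes_path is not None else path.with_suffix(
            path.suffix + ".nodes"
        )
        sidecar.write_text("\n".join(net.labels) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
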
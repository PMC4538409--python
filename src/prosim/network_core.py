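"""Graph data model, edge-list I/O, and degree normalization.

The central object is :class:`PPINetwork`, an undirected weighted graph
``G = (V, E, w)`` of protein-protein interactions.  Node order is the sorted
order of identifiers, fixed at construction; every vector and matrix produced
downstream (priors, proximity, propagation scores) shares this order, which
makes the whole pipeline deterministic.

The symmetric degree normalization ``W' = D^(-1/2) W D^(-1/2)`` computed here
is what both the random walk and the label-propagation iteration consume; its
spectral radius is at most 1, which is what guarantees the propagation
contracts for any damping factor below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "NormalizedAdjacency",
    "read_edge_list",
    "normalize_adjacency",
    "write_weighted_edges",
]


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) key for the undirected edge {u, v}."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected weighted protein-protein interaction network.

    Parameters
    ----------
    nodes
        Sorted tuple of protein identifiers.  Defines the index order of all
        derived vectors and matrices.
    edges
        Mapping from canonical node pairs ``(u, v)`` with ``u < v`` to a
        nonnegative weight.  A weight of 0 behaves as edge absence during
        normalization.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if list(self.nodes) != sorted(self.nodes):
            raise ValueError("nodes must be in sorted order")
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u > v:
                raise ValueError(f"edge key {(u, v)!r} not canonical")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {(u, v)!r} has endpoint outside node set")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge {(u, v)!r} has invalid weight {w!r}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network from (u, v, weight) triples.

        Reversed duplicates are merged keeping the maximum weight; self-loops
        are dropped with a warning.
        """
        merged: dict[tuple[str, str], float] = {}
        nodes: set[str] = set(extra_nodes)
        n_loops = 0
        for u, v, w in edges:
            nodes.add(u)
            nodes.add(v)
            if u == v:
                n_loops += 1
                continue
            k = edge_key(u, v)
            if k in merged:
                merged[k] = max(merged[k], w)
            else:
                merged[k] = float(w)
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        return cls(tuple(sorted(nodes)), merged)

    # -- basic accessors --------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_index(self) -> dict[str, int]:
        if "node_index" not in self._cache:
            self._cache["node_index"] = {n: i for i, n in enumerate(self.nodes)}
        return self._cache["node_index"]

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges in deterministic (sorted) order."""
        return sorted(self.edges)

    def neighbor_map(self) -> dict[str, frozenset[str]]:
        """Adjacency sets keyed by node (zero-weight edges excluded)."""
        if "nbrs" not in self._cache:
            nbrs: dict[str, set[str]] = {n: set() for n in self.nodes}
            for (u, v), w in self.edges.items():
                if w > 0:
                    nbrs[u].add(v)
                    nbrs[v].add(u)
            self._cache["nbrs"] = {n: frozenset(s) for n, s in nbrs.items()}
        return self._cache["nbrs"]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix in node order."""
        idx = self.node_index
        n = self.N
        rows, cols, vals = [], [], []
        for (u, v), w in self.edges.items():
            if w <= 0:
                continue
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        """Weighted degree d(x) = sum_y w(x, y), in node order."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    # -- derived networks -------------------------------------------------

    def with_weights(self, weights: Mapping[tuple[str, str], float]) -> "PPINetwork":
        """Copy of the network with new edge weights (same topology)."""
        missing = set(self.edges) - set(weights)
        if missing:
            raise KeyError(f"missing weight for edge {sorted(missing)[0]!r}")
        return PPINetwork(self.nodes, {e: float(weights[e]) for e in self.edges})

    def drop_edges(self, to_drop: Iterable[tuple[str, str]]) -> "PPINetwork":
        """Copy without the listed edges (node set unchanged)."""
        drop = {edge_key(u, v) for u, v in to_drop}
        kept = {e: w for e, w in self.edges.items() if e not in drop}
        return PPINetwork(self.nodes, kept)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Degree-normalized adjacency W' = D^(-1/2) W D^(-1/2).

    Symmetric, entries in [0, 1], spectral radius at most 1.  Rows and columns
    of isolated nodes are zero.
    """

    nodes: tuple[str, ...]
    matrix: sp.csr_matrix

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def normalize_adjacency(net: PPINetwork) -> NormalizedAdjacency:
    """Normalize edge weights by the degrees of their endpoints.

    ``W'[v, u] = w(v, u) / sqrt(d(v) d(u))`` with ``d(x) = sum_y w(x, y)``.
    Isolated nodes (degree 0) get all-zero rows and columns rather than a
    division by zero.
    """
    W = net.adjacency()
    d = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(inv_sqrt)
    Wn = (D @ W @ D).tocsr()
    return NormalizedAdjacency(net.nodes, Wn)


def read_edge_list(path, has_weights: bool | None = None) -> PPINetwork:
    """Read a 2- or 3-column TSV edge list into a :class:`PPINetwork`.

    Lines starting with ``#`` are ignored.  Reversed duplicate edges are
    merged keeping the maximum weight; self-loops are dropped with a warning.

    Parameters
    ----------
    path
        TSV file, one edge per line: ``protein_a<TAB>protein_b[<TAB>weight]``.
    has_weights
        Force 3-column (True) or 2-column (False) parsing; ``None``
        autodetects per line.
    """
    triples: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if has_weights is True and len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected a weight column")
            if has_weights is False:
                parts = parts[:2]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if not np.isfinite(w) or w < 0:
                    raise ValueError(f"{path}:{lineno}: negative or non-finite weight {w}")
            else:
                w = 1.0
            triples.append((parts[0], parts[1], w))
    return PPINetwork.from_edges(triples)


def write_weighted_edges(net: PPINetwork, path) -> None:
    """Write a 3-column TSV round-trippable by :func:`read_edge_list`.

    Weights are serialized with 17 significant digits so that a
    read-write-read cycle is bit-stable.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\tweight\n")
        for u, v in net.edge_list():
            fh.write(f"{u}\t{v}\t{net.edges[(u, v)]:.17g}\n")
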
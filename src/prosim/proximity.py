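"""Random walk with restart: network proximity to known disease genes.

A walker starts on the seed genes of the query disease and at each step
either follows a reliability-weighted interaction (probability ``1 - r``) or
restarts uniformly on the seeds (probability ``r``).  The stationary
distribution ``Pro(v)`` of this walk measures each protein's proximity to the
disease; it generalizes personalized PageRank to a seeded protein network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network_core import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["SeedSet", "ProximityVector", "rwr", "rank_by_proximity", "write_proximity"]


@dataclass(frozen=True)
class SeedSet:
    """Genes known to be associated with a query disease."""

    disease: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def without(self, gene: str) -> "SeedSet":
        return SeedSet(self.disease, self.genes - {gene})

    def restricted_to(self, nodes) -> "SeedSet":
        return SeedSet(self.disease, self.genes & set(nodes))


@dataclass(frozen=True)
class ProximityVector:
    """Stationary probability Pro(v) per node, plus walk metadata."""

    nodes: tuple[str, ...]
    scores: np.ndarray
    restart: float
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.nodes),):
            raise ValueError("score vector does not match node order")
        if np.any(self.scores < -1e-12):
            raise ValueError("negative proximity score")

    def score(self, node: str) -> float:
        return float(self.scores[self.nodes.index(node)])


def _transition_matrix(net: PPINetwork) -> sp.csr_matrix:
    """Column-stochastic transition matrix; dangling nodes get a self-loop."""
    W = net.adjacency()
    col = np.asarray(W.sum(axis=0)).ravel()
    n = net.N
    inv = np.where(col > 0, 1.0 / np.where(col > 0, col, 1.0), 0.0)
    T = (W @ sp.diags(inv)).tolil()
    for j in np.flatnonzero(col == 0):
        T[j, j] = 1.0
    return T.tocsr()


def rwr(
    net: PPINetwork,
    seeds: SeedSet,
    restart: float = 0.75,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ProximityVector:
    """Iterate the restart walk to its stationary distribution.

    ``p <- (1 - r) T p + r p0`` where ``T`` is the column-stochastic
    transition matrix built from edge weights and ``p0`` is uniform over the
    seeds present in the network (absent seeds are dropped with a warning).
    Stops when the L1 change falls below ``tol`` or after ``max_iter`` steps.
    """
    if not (0.0 < restart <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {restart}")
    present = seeds.genes & set(net.nodes)
    dropped = seeds.genes - present
    if dropped:
        logger.warning(
            "%d seed(s) absent from the network: %s", len(dropped), sorted(dropped)[:5]
        )
    if not present:
        raise ValueError("no seed gene present in the network")
    idx = net.node_index
    p0 = np.zeros(net.N)
    for g in present:
        p0[idx[g]] = 1.0 / len(present)
    T = _transition_matrix(net)
    p = p0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_new = (1.0 - restart) * (T @ p) + restart * p0
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return ProximityVector(
        nodes=net.nodes,
        scores=p,
        restart=restart,
        iterations=it,
        converged=converged,
    )


def rank_by_proximity(pro: ProximityVector) -> list[str]:
    """Nodes sorted by proximity descending, ties broken lexicographically."""
    order = sorted(range(len(pro.nodes)), key=lambda i: (-pro.scores[i], pro.nodes[i]))
    return [pro.nodes[i] for i in order]


def write_proximity(pro: ProximityVector, path) -> None:
    """Write a 2-column TSV (protein, score) sorted descending."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein\tproximity\n")
        for node in rank_by_proximity(pro):
            fh.write(f"{node}\t{pro.score(node):.17g}\n")
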
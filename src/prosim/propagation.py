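"""The ProSim scoring iteration and the end-to-end prioritization pipeline.

The relevance of protein v to the query disease obeys

    F(v) = alpha * sum_{u in N(v)} F(u) w'(v, u) + (1 - alpha) * (Y(v) + Pro(v))

where w' is the degree-normalized adjacency, Y the disease-similarity prior
and Pro the random-walk proximity to the seed genes.  The fixed point is
reached by damped iteration F_t = alpha W' F_{t-1} + (1 - alpha)(Y + Pro),
which is a contraction whenever alpha < 1 (the spectral radius of W' is at
most 1).  Setting Y = 0 recovers a proximity-smoothed ranking; setting
Pro = 0 recovers a PRINCE-style prior propagation — both serve as ablation
baselines in the evaluation module.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .disease_prior import (
    DiseaseSimilarityMatrix,
    PriorVector,
    SimilarityLogistic,
    build_prior,
    read_associations,
    read_similarity_matrix,
)
from .network_core import (
    NormalizedAdjacency,
    PPINetwork,
    normalize_adjacency,
    read_edge_list,
)
from .proximity import ProximityVector, SeedSet, rank_by_proximity, rwr

__all__ = [
    "PropagationParams",
    "ScoreVector",
    "RankedList",
    "propagate",
    "rank_candidates",
    "Prioritizer",
    "PipelineConfig",
    "prosim_pipeline",
    "write_ranking",
]


@dataclass(frozen=True)
class PropagationParams:
    """Damping factor, iteration cap and convergence tolerance."""

    alpha: float = 0.9
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class ScoreVector:
    """Final relevance scores F(v) with convergence metadata."""

    nodes: tuple[str, ...]
    F: np.ndarray
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        if self.F.shape != (len(self.nodes),):
            raise ValueError("score vector does not match node order")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite score")

    def score(self, node: str) -> float:
        return float(self.F[self.nodes.index(node)])


@dataclass(frozen=True)
class RankedList:
    """Candidates ordered by score descending; ranks run 1..n."""

    nodes: tuple[str, ...]  # rank order
    scores: np.ndarray  # aligned with nodes
    tie_rule: str = "lexicographic"

    def rank_of(self, node: str) -> int:
        return self.nodes.index(node) + 1

    def __len__(self) -> int:
        return len(self.nodes)


def propagate(
    Wn: NormalizedAdjacency,
    Y: PriorVector | np.ndarray,
    Pro: ProximityVector | np.ndarray,
    params: PropagationParams = PropagationParams(),
) -> ScoreVector:
    """Iterate F_t = alpha W' F_{t-1} + (1 - alpha)(Y + Pro) to its fixed point.

    Starts from F_0 = Y + Pro and stops when the L1 change drops below
    ``params.tol`` or after ``params.max_iter`` iterations.
    """
    y = Y.values if isinstance(Y, PriorVector) else np.asarray(Y, dtype=float)
    pro = Pro.scores if isinstance(Pro, ProximityVector) else np.asarray(Pro, dtype=float)
    n = len(Wn.nodes)
    if y.shape != (n,) or pro.shape != (n,):
        raise ValueError("prior/proximity vectors do not match the network order")
    if isinstance(Y, PriorVector) and Y.nodes != Wn.nodes:
        raise ValueError("prior node order differs from the adjacency order")
    if isinstance(Pro, ProximityVector) and Pro.nodes != Wn.nodes:
        raise ValueError("proximity node order differs from the adjacency order")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(pro))):
        raise ValueError("non-finite prior or proximity value")
    base = y + pro
    alpha = params.alpha
    F = base.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        F_new = alpha * (Wn.matrix @ F) + (1.0 - alpha) * base
        if np.abs(F_new - F).sum() < params.tol:
            F = F_new
            converged = True
            break
        F = F_new
    return ScoreVector(nodes=Wn.nodes, F=F, converged=converged, iterations=it)


def rank_candidates(F: ScoreVector, seeds: SeedSet) -> RankedList:
    """Rank non-seed proteins by relevance, ties broken lexicographically."""
    seed_set = seeds.genes
    cand = [i for i, n in enumerate(F.nodes) if n not in seed_set]
    order = sorted(cand, key=lambda i: (-F.F[i], F.nodes[i]))
    return RankedList(
        nodes=tuple(F.nodes[i] for i in order),
        scores=np.array([F.F[i] for i in order]),
    )


@dataclass(frozen=True)
class Prioritizer:
    """All fitted inputs needed to rank candidates for one query disease.

    Bundles the reliability-weighted network, its normalized adjacency, the
    disease-similarity matrix and the association map, so that repeated
    prioritizations (for example leave-one-out trials) reuse the expensive
    pieces and only recompute the walk, the prior and the propagation.
    """

    net: PPINetwork  # reliability-weighted
    similarity: DiseaseSimilarityMatrix
    assoc: dict[str, set[str]]
    disease: str
    params: PropagationParams = PropagationParams()
    restart: float = 0.75
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 1000
    logistic: SimilarityLogistic = SimilarityLogistic()
    # optional rescaling of prior and proximity to a common max of 1 before
    # summing (default: the raw sum Y + Pro)
    normalize_terms: bool = False
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def Wn(self) -> NormalizedAdjacency:
        if "Wn" not in self._cache:
            self._cache["Wn"] = normalize_adjacency(self.net)
        return self._cache["Wn"]

    def seed_set(self) -> SeedSet:
        genes = self.assoc.get(self.disease, set())
        return SeedSet(self.disease, frozenset(genes)).restricted_to(self.net.nodes)

    def rank(
        self,
        seeds: SeedSet | None = None,
        assoc: dict[str, set[str]] | None = None,
        method: str = "prosim",
    ) -> tuple[RankedList, ScoreVector | None]:
        """Rank candidates for the query disease.

        ``method`` selects the full model ("prosim") or an ablation:
        "rwr" ranks by raw walk proximity; "prior" propagates the disease
        prior alone (PRINCE-style); "proximity_smoothed" propagates the
        proximity alone.
        """
        if seeds is None:
            seeds = self.seed_set()
        if assoc is None:
            assoc = self.assoc
        pro = rwr(
            self.net, seeds, restart=self.restart,
            tol=self.rwr_tol, max_iter=self.rwr_max_iter,
        )
        if method == "rwr":
            order = [n for n in rank_by_proximity(pro) if n not in seeds.genes]
            idx = {n: i for i, n in enumerate(pro.nodes)}
            ranked = RankedList(
                nodes=tuple(order),
                scores=np.array([pro.scores[idx[n]] for n in order]),
            )
            return ranked, None
        zeros = np.zeros(self.net.N)
        pro_vec = pro.scores
        if self.normalize_terms and pro_vec.max() > 0:
            pro_vec = pro_vec / pro_vec.max()
        if method == "prior":
            y = build_prior(self.similarity, self.disease, assoc, self.net, self.logistic)
            F = propagate(self.Wn, y, zeros, self.params)
        elif method == "proximity_smoothed":
            F = propagate(self.Wn, zeros, pro_vec, self.params)
        elif method == "prosim":
            y = build_prior(self.similarity, self.disease, assoc, self.net, self.logistic)
            y_vec = y.values
            if self.normalize_terms and y_vec.max() > 0:
                y_vec = y_vec / y_vec.max()
            F = propagate(self.Wn, y_vec, pro_vec, self.params)
        else:
            raise ValueError(f"unknown method {method!r}")
        return rank_candidates(F, seeds), F


@dataclass
class PipelineConfig:
    """File paths and parameters for a file-driven prioritization run."""

    weighted_edges: str
    similarity: str
    associations: str
    disease: str
    alpha: float = 0.9
    restart: float = 0.75
    tol: float = 1e-6
    max_iter: int = 100
    rwr_max_iter: int = 1000
    method: str = "prosim"
    top_k: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def prosim_pipeline(config: PipelineConfig):
    """Run weighting -> normalization -> walk -> prior -> propagation -> ranking.

    Expects the edge list to already carry reliability weights (produced by
    ``prosim weight`` or :func:`prosim.reliability.weight_network`).  Returns
    (RankedList, ScoreVector or None, provenance dict); the provenance dict
    records every parameter and the SHA-256 checksum of every input file.
    """
    net = read_edge_list(config.weighted_edges, has_weights=None)
    S = read_similarity_matrix(config.similarity)
    assoc = read_associations(config.associations)
    params = PropagationParams(
        alpha=config.alpha, max_iter=config.max_iter, tol=config.tol
    )
    prio = Prioritizer(
        net=net,
        similarity=S,
        assoc=assoc,
        disease=config.disease,
        params=params,
        restart=config.restart,
        rwr_tol=config.tol,
        rwr_max_iter=config.rwr_max_iter,
    )
    ranked, F = prio.rank(method=config.method)
    provenance = {
        **asdict(config),
        "seeds": sorted(prio.seed_set().genes),
        "checksums": {
            "weighted_edges": _sha256(config.weighted_edges),
            "similarity": _sha256(config.similarity),
            "associations": _sha256(config.associations),
        },
    }
    return ranked, F, provenance


def write_ranking(
    ranked: RankedList,
    path,
    F: ScoreVector | None = None,
    Y: PriorVector | None = None,
    Pro: ProximityVector | None = None,
    top_k: int | None = None,
) -> None:
    """Write the ranking as TSV: rank, protein, score[, prior, proximity]."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["#rank", "protein", "F"]
        if Y is not None:
            cols.append("Y")
        if Pro is not None:
            cols.append("Pro")
        fh.write("\t".join(cols) + "\n")
        limit = len(ranked) if top_k is None else min(top_k, len(ranked))
        for r in range(limit):
            node = ranked.nodes[r]
            row = [str(r + 1), node, f"{ranked.scores[r]:.17g}"]
            if Y is not None:
                row.append(f"{Y.value(node):.17g}")
            if Pro is not None:
                row.append(f"{Pro.score(node):.17g}")
            fh.write("\t".join(row) + "\n")
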
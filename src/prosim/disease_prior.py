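"""Disease-similarity prior over network proteins.

Phenotype-record similarities (MimMiner-style, in [0, 1]) are mapped through
a calibrated logistic ``L(x) = 1 / (1 + exp(c x + d))`` with ``c = -15`` and
``d = ln(9999)``, chosen so that L(0) = 1e-4 and the transition from
"uninformative" (similarity below ~0.3) to "informative" (above ~0.6) is
sharp.  Each protein's prior ``Y(v)`` is L applied to the highest similarity
between the query disease and any disease the protein is associated with;
unassociated proteins get prior 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_core import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseSimilarityMatrix",
    "SimilarityLogistic",
    "PriorVector",
    "similarity_logistic",
    "build_prior",
    "read_similarity_matrix",
    "read_associations",
]


@dataclass(frozen=True)
class DiseaseSimilarityMatrix:
    """Symmetric disease-disease similarity with unit diagonal, entries in [0,1]."""

    diseases: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.diseases)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if np.any(self.S < 0) or np.any(self.S > 1):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")

    def similarity(self, q: str, p: str) -> float:
        i = self.diseases.index(q)
        j = self.diseases.index(p)
        return float(self.S[i, j])


@dataclass(frozen=True)
class SimilarityLogistic:
    """Parameters of the similarity-to-probability logistic L."""

    c: float = -15.0
    d: float = math.log(9999.0)


@dataclass(frozen=True)
class PriorVector:
    """Per-node prior Y(v) in [0, 1) for a query disease."""

    disease: str
    nodes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.nodes),):
            raise ValueError("prior vector does not match node order")
        if np.any(self.values < 0) or np.any(self.values >= 1):
            raise ValueError("priors must lie in [0, 1)")

    def value(self, node: str) -> float:
        return float(self.values[self.nodes.index(node)])


def similarity_logistic(x, params: SimilarityLogistic = SimilarityLogistic()):
    """Probability that two diseases are related: L(x) = 1/(1 + e^(c x + d))."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite similarity value")
    out = 1.0 / (1.0 + np.exp(params.c * x + params.d))
    return float(out) if out.ndim == 0 else out


def build_prior(
    S: DiseaseSimilarityMatrix,
    q: str,
    assoc: dict[str, set[str]],
    net: PPINetwork,
    params: SimilarityLogistic = SimilarityLogistic(),
) -> PriorVector:
    """Prior knowledge Y(v) of every network protein for query disease q.

    ``Y(v) = L(max over diseases p with v in assoc(p) of S(q, p))``; proteins
    with no disease association get 0; proteins associated with q itself get
    ``L(1)`` since S(q, q) = 1.  Association entries naming proteins absent
    from the network are dropped with a warning.
    """
    if q not in S.diseases:
        raise KeyError(f"query disease {q!r} absent from similarity matrix")
    node_set = set(net.nodes)
    best_sim: dict[str, float] = {}
    n_unresolved = 0
    for p, genes in assoc.items():
        if p not in S.diseases:
            logger.warning("disease %r absent from similarity matrix; skipped", p)
            continue
        s_qp = S.similarity(q, p)
        for g in genes:
            if g not in node_set:
                n_unresolved += 1
                continue
            if s_qp > best_sim.get(g, -1.0):
                best_sim[g] = s_qp
    if n_unresolved:
        logger.warning("%d association gene(s) not in the network; dropped", n_unresolved)
    values = np.zeros(net.N)
    idx = net.node_index
    for g, s in best_sim.items():
        values[idx[g]] = similarity_logistic(s, params)
    return PriorVector(disease=q, nodes=net.nodes, values=values)


def read_similarity_matrix(path) -> DiseaseSimilarityMatrix:
    """Read a square TSV with disease ids as first row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column disease ids differ")
    return DiseaseSimilarityMatrix(tuple(df.index), df.to_numpy(dtype=float))


def read_associations(path) -> dict[str, set[str]]:
    """Read a 2-column TSV (disease_id, gene_id) into a disease -> genes map."""
    assoc: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            assoc.setdefault(parts[0], set()).add(parts[1])
    return assoc
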
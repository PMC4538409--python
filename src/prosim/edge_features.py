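"""Per-edge features feeding the interaction-reliability model.

Three features are computed for every interaction (v, u):

1. **Small-world clustering coefficient** ``C_vu`` — minus the natural log of
   the hypergeometric tail probability of observing at least
   ``k = |N(v) ∩ N(u)|`` shared neighbors, given the two degree counts and the
   network size.  Large values mean the edge sits in an unexpectedly cliquish
   neighborhood, the signature of a genuine small-world interaction.
2. **Pearson correlation** ``rho_vu`` of the two genes' expression profiles
   (population 1/m convention), since co-regulated genes are more likely to
   encode interacting proteins.
3. **Subcellular-localization compatibility** ``loc_vu`` in {0, 1} — whether
   some annotated compartment of v is biologically compatible with some
   compartment of u (a compartment is always compatible with itself).

Features are computed separately on the positive and the negative interaction
set, each using its own network's topology for the clustering coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .network_core import PPINetwork, edge_key

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_VOCABULARY",
    "ExpressionMatrix",
    "LocalizationTable",
    "EdgeFeatures",
    "small_world_coefficient",
    "pearson_cc",
    "localization_compat",
    "build_edge_features",
    "read_expression",
    "read_localization",
    "read_compatibility",
]

#: The 12 subcellular compartments of the localization vocabulary.
SITE_VOCABULARY = frozenset(
    {
        "cytoplasm",
        "mitochondria",
        "nucleus",
        "plasma membrane",
        "centriole",
        "cytoskeleton",
        "endoplasmic reticulum",
        "extracell",
        "Golgi apparatus",
        "lysosome",
        "microsome",
        "peroxisome",
    }
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene expression profiles, genes x samples."""

    data: pd.DataFrame  # index: gene ids; columns: sample names

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def has(self, gene: str) -> bool:
        return gene in self.data.index

    def vector(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class LocalizationTable:
    """Protein compartment annotations plus compartment compatibility pairs."""

    sites: dict[str, frozenset[str]]
    compatibility: frozenset[tuple[str, str]]  # canonical sorted pairs

    def __post_init__(self) -> None:
        for prot, ss in self.sites.items():
            bad = ss - SITE_VOCABULARY
            if bad:
                raise ValueError(f"unknown site(s) {sorted(bad)} for {prot!r}")
        for a, b in self.compatibility:
            if (a not in SITE_VOCABULARY) or (b not in SITE_VOCABULARY):
                raise ValueError(f"unknown site in compatibility pair ({a!r}, {b!r})")
            if a > b:
                raise ValueError("compatibility pairs must be canonically sorted")

    @classmethod
    def from_pairs(
        cls, sites: dict[str, set[str]], pairs: list[tuple[str, str]]
    ) -> "LocalizationTable":
        canon = frozenset(tuple(sorted(p)) for p in pairs)
        return cls({k: frozenset(v) for k, v in sites.items()}, canon)

    def compatible(self, site_a: str, site_b: str) -> bool:
        if site_a == site_b:
            return True
        return tuple(sorted((site_a, site_b))) in self.compatibility


@dataclass(frozen=True)
class EdgeFeatures:
    """Feature triples (C_vu, rho_vu, loc_vu) for a network's edges.

    ``X`` rows align with ``edges``; columns are (small-world coefficient,
    expression correlation, localization compatibility).  ``n_imputed_rho``
    counts edges whose correlation was missing (no expression record or zero
    variance) and imputed to the neutral value 0.
    """

    edges: tuple[tuple[str, str], ...]
    X: np.ndarray  # (n_edges, 3)
    n_imputed_rho: int = 0
    n_missing_loc: int = 0

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.edges), 3):
            raise ValueError("feature matrix shape does not match edge count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature value")

    def row(self, u: str, v: str) -> np.ndarray:
        return self.X[self.edges.index(edge_key(u, v))]


def _log_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N, K, n), computed via gammaln.

    N: population size, K: success states, n: draws.  The summation range is
    clamped to the valid support [max(0, n+K-N), min(K, n)].
    """
    lo = max(0, n + K - N)
    hi = min(K, n)
    k = max(k, lo)
    if k > hi:
        raise ValueError("shared-neighbor count above hypergeometric support")
    if k == lo:  # tail spans the whole support: probability exactly 1
        return 0.0
    i = np.arange(k, hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - (n - i) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return min(float(logsumexp(log_pmf)), 0.0)


def small_world_coefficient(
    net: PPINetwork, v: str, u: str, base: str = "e"
) -> float:
    """Cliquishness of the neighborhood around the pair (v, u).

    Returns ``-log P`` where ``P`` is the probability that a random placement
    of u's ``|N(u)|`` neighbors among the network's ``N`` proteins overlaps
    v's neighbor set in at least ``|N(v) ∩ N(u)|`` proteins (hypergeometric
    tail).  Zero shared neighbors give exactly 0; more sharing than chance
    predicts gives increasingly large values.

    Parameters
    ----------
    base
        ``"e"`` (default) for natural log, ``"10"`` for log base 10.
    """
    if v == u:
        raise ValueError("small-world coefficient requires two distinct proteins")
    nbrs = net.neighbor_map()
    if v not in nbrs:
        raise KeyError(v)
    if u not in nbrs:
        raise KeyError(u)
    k = len(nbrs[v] & nbrs[u])
    log_tail = _log_hypergeom_tail(k, net.N, len(nbrs[v]), len(nbrs[u]))
    c = -log_tail
    if base == "10":
        c /= math.log(10.0)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    return max(c, 0.0)


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Population Pearson correlation of two expression profiles.

    ``rho = ((1/m) sum x_i y_i - mean(x) mean(y)) / (sigma_x sigma_y)`` with
    population (1/m) standard deviations.  Returns NaN (logged, not raised)
    when either profile has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-D of equal length")
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 samples")
    sx = x.std()  # population convention (ddof=0)
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        logger.warning("zero-variance expression profile; correlation undefined")
        return float("nan")
    rho = ((x * y).mean() - x.mean() * y.mean()) / (sx * sy)
    return float(np.clip(rho, -1.0, 1.0))


def localization_compat(locs: LocalizationTable, v: str, u: str) -> int:
    """1 iff some compartment of v is compatible with some compartment of u.

    Proteins with no localization record score 0 (logged as missing data).
    """
    sv = locs.sites.get(v)
    su = locs.sites.get(u)
    if not sv or not su:
        logger.debug("no localization record for %r or %r", v, u)
        return 0
    for a in sv:
        for b in su:
            if locs.compatible(a, b):
                return 1
    return 0


def build_edge_features(
    net: PPINetwork,
    expr: ExpressionMatrix,
    locs: LocalizationTable,
) -> EdgeFeatures:
    """Compute the feature triple for every edge of ``net``.

    Missing expression correlations are imputed to 0 (neutral under the
    logistic reliability model) and counted in the returned summary.
    """
    edges = tuple(net.edge_list())
    X = np.zeros((len(edges), 3))
    n_imputed = 0
    n_missing_loc = 0
    for r, (u, v) in enumerate(edges):
        X[r, 0] = small_world_coefficient(net, u, v)
        if expr.has(u) and expr.has(v):
            rho = pearson_cc(expr.vector(u), expr.vector(v))
        else:
            rho = float("nan")
        if math.isnan(rho):
            rho = 0.0
            n_imputed += 1
        X[r, 1] = rho
        if u not in locs.sites or v not in locs.sites:
            n_missing_loc += 1
        X[r, 2] = localization_compat(locs, u, v)
    return EdgeFeatures(edges, X, n_imputed_rho=n_imputed, n_missing_loc=n_missing_loc)


# -- I/O ------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header of samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def read_localization(path) -> dict[str, set[str]]:
    """Read protein TAB semicolon-separated site names."""
    sites: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sites[parts[0]] = {s.strip() for s in parts[1].split(";") if s.strip()}
    return sites


def read_compatibility(path) -> list[tuple[str, str]]:
    """Read a two-column TSV of compatible compartment pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    return pairs
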
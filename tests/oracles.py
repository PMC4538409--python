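"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code:
exhaustive combinatorial enumeration instead of log-space gamma sums, and
dense linear solves instead of damped iteration.
"""

from itertools import combinations

import numpy as np

from prosim.network_core import PPINetwork, normalize_adjacency


def enumeration_small_world(net: PPINetwork, v: str, u: str) -> float:
    """-ln of the shared-neighbor tail probability by brute-force counting.

    Enumerates every placement of u's neighbor set among the N proteins and
    counts those overlapping v's neighbors in at least the observed number.
    """
    nbrs = net.neighbor_map()
    nv, nu = nbrs[v], nbrs[u]
    k = len(nv & nu)
    hits = total = 0
    for placement in combinations(net.nodes, len(nu)):
        total += 1
        if len(set(placement) & nv) >= k:
            hits += 1
    return -np.log(hits / total)


def rwr_direct_solve(net: PPINetwork, seed_nodes, restart: float) -> np.ndarray:
    """p = r (I - (1-r) T)^-1 p0 by dense linear algebra."""
    W = net.adjacency().toarray()
    col = W.sum(axis=0)
    T = np.zeros_like(W)
    for j in range(len(col)):
        if col[j] > 0:
            T[:, j] = W[:, j] / col[j]
        else:
            T[j, j] = 1.0
    idx = net.node_index
    p0 = np.zeros(net.N)
    for g in seed_nodes:
        p0[idx[g]] = 1.0 / len(seed_nodes)
    return np.linalg.solve(np.eye(net.N) - (1 - restart) * T, restart * p0)


def propagation_direct_solve(net: PPINetwork, base: np.ndarray, alpha: float) -> np.ndarray:
    """F = (1 - alpha)(I - alpha W')^-1 (Y + Pro) by dense linear algebra."""
    Wn = normalize_adjacency(net).toarray()
    return np.linalg.solve(np.eye(net.N) - alpha * Wn, (1 - alpha) * base)
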
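import numpy as np
import pytest

from prosim.benchmark import fit_prioritizer
from prosim.network_core import PPINetwork
from prosim.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Reduced-scale generator settings used by unit tests for speed."""
    return SynthConfig(
        n_nodes=200,
        module_size=15,
        n_samples=80,
        n_seed_genes=6,
        n_related_genes=8,
        n_shared_genes=5,
        negative_set_size=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def small_prio(small_bundle):
    return fit_prioritizer(small_bundle)


@pytest.fixture
def path_graph():
    """a - b - c - d path with unit weights."""
    return PPINetwork.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
    )


def random_network(rng: np.random.Generator, n: int, p: float) -> PPINetwork:
    """Erdos-Renyi network with random positive weights."""
    names = [f"n{i:03d}" for i in range(n)]
    triples = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                triples.append((names[i], names[j], float(rng.uniform(0.1, 2.0))))
    return PPINetwork.from_edges(triples, extra_nodes=names)
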
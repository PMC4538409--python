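"""End-to-end benchmark: fit the full pipeline on a synthetic bundle.

Glues the stages together in the order the method prescribes — edge features
on the positive and negative sets (each on its own topology), tenfold
logistic reliability training, reliability weighting of the positive
network, then prioritization — and exposes leave-one-out comparisons of the
full model against its ablations (raw walk proximity; prior-only
propagation).
"""

from __future__ import annotations

from typing import Sequence

from .edge_features import build_edge_features
from .evaluation import LOOCVReport, loocv_prioritizer
from .propagation import PropagationParams, Prioritizer
from .reliability import train_reliability, weight_network
from .synthetic_data import SynthBundle, SynthConfig, generate_bundle

__all__ = ["fit_prioritizer", "benchmark_loocv"]


def fit_prioritizer(
    bundle: SynthBundle,
    params: PropagationParams = PropagationParams(),
    restart: float = 0.75,
    train_seed: int = 0,
    ridge: float | None = None,
) -> Prioritizer:
    """Feature extraction, reliability training and network weighting."""
    pos_feat = build_edge_features(bundle.net, bundle.expr, bundle.locs)
    neg_feat = build_edge_features(bundle.neg_net, bundle.expr, bundle.locs)
    model = train_reliability(
        pos_feat, neg_feat, balance=True, seed=train_seed, ridge=ridge
    )
    weighted = weight_network(bundle.net, model, pos_feat)
    return Prioritizer(
        net=weighted,
        similarity=bundle.similarity,
        assoc=bundle.assoc,
        disease=bundle.truth.query_disease,
        params=params,
        restart=restart,
    )


def benchmark_loocv(
    cfg: SynthConfig,
    methods: Sequence[str] = ("prosim", "rwr", "prior"),
    threshold: int = 100,
) -> dict[str, LOOCVReport]:
    """Generate a bundle, fit the pipeline, and run LOOCV per method."""
    bundle = generate_bundle(cfg)
    prio = fit_prioritizer(bundle)
    return {
        m: loocv_prioritizer(prio, method=m, threshold=threshold) for m in methods
    }
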
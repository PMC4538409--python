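"""Evaluation protocol: leave-one-out recovery, enrichment, ROC, edge CV.

Each known disease gene is hidden in turn; the pipeline is rerun without it
(the gene is scrubbed from the seed set and from the query disease's
association row, so no information about it leaks into the walk or the
prior) and its recovered rank among the candidates is recorded.  Summary
statistics follow the field's conventions: the hit fraction at a rank
threshold (default 100, emulating prioritization within a linkage interval),
the mean enrichment 50/rank, and ROC curves over true versus unrelated
genes.  A tenfold edge-removal cross-validation probes robustness of the
ranking to missing interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .propagation import Prioritizer, RankedList
from .proximity import SeedSet

__all__ = [
    "LOOCVTrial",
    "LOOCVReport",
    "loocv",
    "loocv_prioritizer",
    "mean_enrichment",
    "roc_points",
    "tenfold_edge_cv",
    "compare_methods",
]

RankFn = Callable[[SeedSet, dict[str, set[str]]], RankedList]


@dataclass(frozen=True)
class LOOCVTrial:
    held_out: str
    rank: int
    n_candidates: int


@dataclass(frozen=True)
class LOOCVReport:
    disease: str
    trials: tuple[LOOCVTrial, ...]
    threshold: int

    @property
    def hit_fraction(self) -> float:
        hits = sum(1 for t in self.trials if t.rank <= self.threshold)
        return hits / len(self.trials)

    @property
    def ranks(self) -> list[int]:
        return [t.rank for t in self.trials]

    @property
    def enrichment(self) -> float:
        return mean_enrichment(self.ranks)


def loocv(
    rank_fn: RankFn,
    seeds: SeedSet,
    assoc: dict[str, set[str]],
    threshold: int = 100,
) -> LOOCVReport:
    """Leave-one-out trials over the seed genes of one disease.

    For every seed gene g, ``rank_fn`` is called with g removed from the seed
    set and from the query disease's association row, and g's rank in the
    returned list is recorded.  The hit fraction is the share of trials with
    rank at most ``threshold``.
    """
    genes = sorted(seeds.genes)
    if len(genes) < 2:
        raise ValueError("leave-one-out needs at least 2 seed genes")
    trials = []
    for g in genes:
        trial_seeds = seeds.without(g)
        trial_assoc = {d: set(gs) for d, gs in assoc.items()}
        trial_assoc[seeds.disease] = trial_assoc.get(seeds.disease, set()) - {g}
        ranked = rank_fn(trial_seeds, trial_assoc)
        trials.append(
            LOOCVTrial(held_out=g, rank=ranked.rank_of(g), n_candidates=len(ranked))
        )
    return LOOCVReport(disease=seeds.disease, trials=tuple(trials), threshold=threshold)


def loocv_prioritizer(
    prio: Prioritizer, method: str = "prosim", threshold: int = 100
) -> LOOCVReport:
    """LOOCV over the query disease's seeds using a fitted :class:`Prioritizer`."""

    def rank_fn(trial_seeds: SeedSet, trial_assoc: dict[str, set[str]]) -> RankedList:
        ranked, _ = prio.rank(seeds=trial_seeds, assoc=trial_assoc, method=method)
        return ranked

    return loocv(rank_fn, prio.seed_set(), prio.assoc, threshold=threshold)


def mean_enrichment(ranks: Iterable[int]) -> float:
    """Mean over trials of 50 / rank (higher means better recovery)."""
    ranks = list(ranks)
    if not ranks:
        raise ValueError("no ranks supplied")
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be >= 1")
    return float(np.mean([50.0 / r for r in ranks]))


def roc_points(
    ranked: RankedList | Sequence[str],
    positives: set[str],
    negatives: set[str],
) -> tuple[np.ndarray, float]:
    """ROC curve of a ranking against known true and unrelated genes.

    Sensitivity at threshold t is the fraction of true genes ranked within
    the top t; specificity is the fraction of unrelated genes ranked below t.
    Returns the (1 - specificity, sensitivity) points for t = 0..n and the
    trapezoidal area under the curve.
    """
    order = list(ranked.nodes) if isinstance(ranked, RankedList) else list(ranked)
    if not positives or not negatives:
        raise ValueError("positives and negatives must be non-empty")
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")
    missing = (positives | negatives) - set(order)
    if missing:
        raise ValueError(f"labeled gene {sorted(missing)[0]!r} not in the ranking")
    sens = [0.0]
    fpr = [0.0]
    tp = fp = 0
    for node in order:
        if node in positives:
            tp += 1
        elif node in negatives:
            fp += 1
        else:
            continue
        sens.append(tp / len(positives))
        fpr.append(fp / len(negatives))
    points = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def tenfold_edge_cv(
    prio: Prioritizer,
    folds: int = 10,
    seed: int = 0,
    method: str = "prosim",
    threshold: int = 100,
) -> tuple[list[LOOCVReport], list[list[tuple[str, str]]]]:
    """Robustness to missing interactions: drop a tenth of edges per fold.

    The edge set is partitioned at random (seeded) into ``folds`` parts; for
    each fold the prioritizer is refit on the reduced network and the full
    LOOCV is rerun.  Returns the per-fold reports and the edge partition.
    """
    edges = prio.net.edge_list()
    if len(edges) < folds:
        raise ValueError("fewer edges than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    partition: list[list[tuple[str, str]]] = [
        [edges[i] for i in part] for part in np.array_split(perm, folds)
    ]
    reports = []
    for part in partition:
        reduced = prio.net.drop_edges(part)
        prio_fold = replace(prio, net=reduced, _cache={})
        reports.append(loocv_prioritizer(prio_fold, method=method, threshold=threshold))
    return reports, partition


def compare_methods(
    prio: Prioritizer,
    methods: Sequence[str] = ("prosim", "rwr", "prior"),
    threshold: int = 100,
) -> pd.DataFrame:
    """Side-by-side LOOCV metrics for the full model and its ablations.

    Columns are methods, rows are metrics (hit fraction at the threshold and
    mean enrichment), all computed under identical leave-one-out trials.
    """
    table = {}
    for method in methods:
        report = loocv_prioritizer(prio, method=method, threshold=threshold)
        table[method] = {
            f"hit_fraction_top{threshold}": report.hit_fraction,
            "mean_enrichment": report.enrichment,
        }
    return pd.DataFrame(table)
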
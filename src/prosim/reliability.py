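"""Interaction-reliability scoring by logistic regression.

A logistic model ``P(true interaction | X) = 1 / (1 + exp(-b0 - sum b_i X_i))``
is trained on a gold-standard positive edge set against a curated negative
set, using the three per-edge features (small-world coefficient, expression
correlation, localization compatibility).  Training is tenfold: one plain
maximum-likelihood fit per fold's training split, with the final coefficient
vector taken as the arithmetic mean of the ten per-fold vectors (a median
option is provided because averaging an unstable fold can be fragile).

The fitted probabilities become the edge weights of the network used by both
the random walk and the propagation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .edge_features import EdgeFeatures
from .network_core import PPINetwork

__all__ = [
    "ReliabilityModel",
    "train_reliability",
    "predict_reliability",
    "weight_network",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ReliabilityModel:
    """Logistic regression coefficients for edge reliability.

    ``beta`` is (intercept, coef_smallworld, coef_pcc, coef_loc); when
    ``averaged`` is set it equals the component-wise mean (or median) of the
    per-fold vectors in ``fold_betas``.
    """

    beta: np.ndarray  # shape (4,)
    fold_betas: np.ndarray  # shape (folds, 4)
    averaged: bool = True
    average: str = "mean"

    def __post_init__(self) -> None:
        if self.beta.shape != (4,):
            raise ValueError("beta must be a 4-vector")


def _fit_fold(X: np.ndarray, y: np.ndarray, ridge: float | None) -> np.ndarray:
    # C = inf is sklearn's spelling of unpenalized maximum likelihood
    C = np.inf if ridge is None else 1.0 / ridge
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def train_reliability(
    pos_features: EdgeFeatures,
    neg_features: EdgeFeatures,
    folds: int = 10,
    balance: bool = True,
    seed: int = 0,
    ridge: float | None = None,
    average: str = "mean",
) -> ReliabilityModel:
    """Train the tenfold logistic reliability model.

    Parameters
    ----------
    pos_features, neg_features
        Feature triples of the positive and negative interaction sets.
    balance
        Truncate the positive set to the negative set's size, keeping the
        first ``|neg|`` rows in input order (mirroring training on the first
        block of the gold-standard set).
    folds
        Number of stratified folds; one maximum-likelihood fit per fold's
        training split.
    ridge
        Optional L2 penalty strength (default None = plain logistic
        regression).  Useful when clean synthetic features are linearly
        separable.
    average
        "mean" (default) or "median" combination of per-fold coefficients.

    Returns
    -------
    ReliabilityModel with the combined ``beta`` and all ``fold_betas``.
    """
    Xp = pos_features.X
    Xn = neg_features.X
    if balance and len(Xp) > len(Xn):
        Xp = Xp[: len(Xn)]
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xn))])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature value")
    if min(len(Xp), len(Xn)) < max(folds, 20):
        raise ValueError(
            f"need at least {max(folds, 20)} examples per class, got "
            f"{len(Xp)} positive / {len(Xn)} negative"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_betas = np.array(
        [_fit_fold(X[train], y[train], ridge) for train, _ in skf.split(X, y)]
    )
    if average == "mean":
        beta = fold_betas.mean(axis=0)
    elif average == "median":
        beta = np.median(fold_betas, axis=0)
    else:
        raise ValueError(f"unknown average {average!r}")
    return ReliabilityModel(beta=beta, fold_betas=fold_betas, average=average)


def predict_reliability(model: ReliabilityModel, X) -> np.ndarray | float:
    """Probability of true interaction for one feature triple or a matrix.

    ``1 / (1 + exp(-(b0 + b1 X1 + b2 X2 + b3 X3)))``.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature value")
    scalar = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != 3:
        raise ValueError("expected 3 features per edge")
    z = model.beta[0] + X2 @ model.beta[1:]
    # clip the logit so the probability stays strictly inside (0, 1)
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return float(p[0]) if scalar else p


def weight_network(
    net: PPINetwork, model: ReliabilityModel, features: EdgeFeatures
) -> PPINetwork:
    """Replace edge weights with predicted reliabilities (nodes unchanged)."""
    feat_index = {e: i for i, e in enumerate(features.edges)}
    missing = [e for e in net.edges if e not in feat_index]
    if missing:
        raise KeyError(f"no feature row for edge {missing[0]!r}")
    rows = np.array([feat_index[e] for e in net.edge_list()])
    probs = predict_reliability(model, features.X[rows])
    weights = dict(zip(net.edge_list(), probs))
    return net.with_weights(weights)


def save_model(model: ReliabilityModel, path) -> None:
    """Serialize the model as an auditable key-value text file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"average\t{model.average}\n")
        fh.write("beta\t" + "\t".join(f"{b:.17g}" for b in model.beta) + "\n")
        for i, fb in enumerate(model.fold_betas):
            fh.write(f"fold_{i}\t" + "\t".join(f"{b:.17g}" for b in fb) + "\n")


def load_model(path) -> ReliabilityModel:
    average = "mean"
    beta = None
    folds = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "average":
                average = parts[1]
            elif parts[0] == "beta":
                beta = np.array([float(x) for x in parts[1:]])
            elif parts[0].startswith("fold_"):
                folds.append([float(x) for x in parts[1:]])
    if beta is None:
        raise ValueError(f"{path}: no beta line")
    return ReliabilityModel(beta=beta, fold_betas=np.array(folds), average=average)
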
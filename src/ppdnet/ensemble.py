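"""Accuracy- and dropout-weighted two-network ensemble.

The model combines a fully connected network (member 1, dropout rate 0)
and a dropout-regularized network (member 2, rate > 0) by a convex
weighted average of their output probabilities.  The mixing weights
average two shares — each member's share of the summed training
accuracies and its share of the summed dropout rates:

    w1 = (Accuracy1 / (Accuracy1 + Accuracy2)
          + Dropout1 / (Dropout1 + Dropout2)) / 2
    w2 = (Accuracy2 / (Accuracy1 + Accuracy2)
          + Dropout2 / (Dropout1 + Dropout2)) / 2

so w1 + w2 = 1 identically.  A member with higher training accuracy, or
a larger dropout rate (a proxy for generalization), receives more mass.
When both dropout rates are 0 the dropout shares are taken as 1/2 each
(symmetric limit).  Note the asymmetry this formula builds in: with
Dropout1 = 0 the dropout term sends all of its mass to member 2, so the
dropout network dominates whenever the accuracies are comparable; the
formula is implemented as stated, not "corrected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    FitResult,
    Network,
    TrainConfig,
    init_network,
    predict_proba,
    train,
)
from .schema import Dataset

__all__ = ["EnsembleWeights", "EnsembleModel", "compute_weights", "fit_ensemble", "predict"]


@dataclass(frozen=True)
class EnsembleWeights:
    accuracy1: float
    accuracy2: float
    dropout1: float
    dropout2: float
    w1: float
    w2: float


@dataclass(frozen=True)
class EnsembleModel:
    fcnn: Network
    dnn: Network
    weights: EnsembleWeights
    threshold: float = 0.5
    fcnn_fit: FitResult | None = None
    dnn_fit: FitResult | None = None


def compute_weights(a1: float, a2: float, d1: float, d2: float) -> EnsembleWeights:
    """Mixing weights from training accuracies and dropout rates.

    Requires a1 + a2 > 0 (at least one member must classify better than
    never); dropout rates must be non-negative, with the 0/0 dropout
    case resolved symmetrically.
    """
    if not (0.0 <= a1 <= 1.0 and 0.0 <= a2 <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    if d1 < 0 or d2 < 0:
        raise ValueError("dropout rates must be non-negative")
    if a1 + a2 <= 0.0:
        raise ValueError("a1 + a2 must be positive (untrained models?)")
    acc_share1 = a1 / (a1 + a2)
    if d1 + d2 > 0.0:
        drop_share1 = d1 / (d1 + d2)
    else:
        drop_share1 = 0.5
    w1 = (acc_share1 + drop_share1) / 2.0
    w2 = ((1.0 - acc_share1) + (1.0 - drop_share1)) / 2.0
    return EnsembleWeights(a1, a2, d1, d2, w1, w2)


def fit_ensemble(
    train_set: Dataset,
    fcnn_cfg: TrainConfig | None = None,
    dnn_cfg: TrainConfig | None = None,
    dnn_rate: float = 0.5,
    fcnn_rate: float = 0.0,
    threshold: float = 0.5,
) -> EnsembleModel:
    """Train both members on the same training set and derive the weights.

    ``Accuracy1``/``Accuracy2`` are the members' final training-set
    accuracies; ``Dropout1``/``Dropout2`` are their configured rates
    (``fcnn_rate`` defaults to 0 — the fully connected member has no
    dropout mechanism).  Deterministic for fixed config seeds.
    """
    fcnn_cfg = fcnn_cfg or TrainConfig()
    dnn_cfg = dnn_cfg or TrainConfig()
    n_in = train_set.X.shape[1]
    fcnn_fit = train(init_network(n_in, fcnn_cfg, dropout_rate=fcnn_rate), train_set, fcnn_cfg)
    dnn_fit = train(init_network(n_in, dnn_cfg, dropout_rate=dnn_rate), train_set, dnn_cfg)
    weights = compute_weights(
        fcnn_fit.training_accuracy, dnn_fit.training_accuracy, fcnn_rate, dnn_rate
    )
    return EnsembleModel(
        fcnn=fcnn_fit.network,
        dnn=dnn_fit.network,
        weights=weights,
        threshold=threshold,
        fcnn_fit=fcnn_fit,
        dnn_fit=dnn_fit,
    )


def predict(model: EnsembleModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average probability and thresholded labels.

    The ensemble probability w1*p_fcnn + w2*p_dnn is convex, hence never
    leaves the interval spanned by the member probabilities.
    """
    p1 = predict_proba(model.fcnn, X)
    p2 = predict_proba(model.dnn, X)
    proba = model.weights.w1 * p1 + model.weights.w2 * p2
    labels = (proba >= model.threshold).astype(np.int64)
    return proba, labels
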
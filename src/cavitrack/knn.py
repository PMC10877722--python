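"""k-nearest-neighbour classification of cavitation level from temperature.

A deliberately transparent, from-scratch lazy learner on a single scalar
feature: the Euclidean distance between a test temperature x and a labelled
neighbour y is d(x, y) = |x - y|.  The predicted level is the majority label
among the k nearest training points.

Tie rules (stated explicitly because they matter on gridded temperatures):
distance ties are broken by training order; a tied majority vote falls to
the tied label whose nearest member is closest to x, then to the smaller
label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["LabeledPoint", "KnnClassifier", "suggested_k", "knn_fit", "knn_predict"]


@dataclass(frozen=True)
class LabeledPoint:
    """(temperature °C, cavitation level) training pair."""

    x: float
    label: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise ValueError("temperature must be finite")
        if self.label < 1:
            raise ValueError("cavitation level must be >= 1")


@dataclass(frozen=True)
class KnnClassifier:
    """Fitted (i.e. memorised) kNN model."""

    k: int
    xs: np.ndarray  # training temperatures, in supplied order
    labels: np.ndarray  # training levels


def suggested_k(n_train: int) -> int:
    """Rule-of-thumb neighbourhood size: round(sqrt(n_train)), at least 1.

    Advisory only — the evaluation grid sweeps k = 1, 2, 3, 5, 7 anyway.
    """
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    return max(int(math.floor(math.sqrt(n_train) + 0.5)), 1)


def knn_fit(training: Sequence[LabeledPoint], k: int) -> KnnClassifier:
    """Store the training points verbatim (lazy learner)."""
    if len(training) == 0:
        raise ValueError("training set must be nonempty")
    if not (1 <= k <= len(training)):
        raise ValueError(f"k must satisfy 1 <= k <= {len(training)}")
    xs = np.array([p.x for p in training], dtype=float)
    labels = np.array([p.label for p in training], dtype=int)
    return KnnClassifier(k=k, xs=xs, labels=labels)


def knn_predict(model: KnnClassifier, x: float) -> int:
    """Majority label among the k training temperatures nearest to ``x``."""
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    dist = np.abs(model.xs - x)
    order = np.argsort(dist, kind="stable")  # distance ties -> training order
    neigh = order[: model.k]
    votes: dict[int, int] = {}
    nearest: dict[int, float] = {}
    for idx in neigh:
        lab = int(model.labels[idx])
        votes[lab] = votes.get(lab, 0) + 1
        d = float(dist[idx])
        if lab not in nearest or d < nearest[lab]:
            nearest[lab] = d
    best_votes = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == best_votes]
    # vote tie -> label with the closest member, then smaller label
    return min(tied, key=lambda lab: (nearest[lab], lab))
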
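"""Error-correcting output codes: one-vs-one linear SVMs for multiclass levels.

A binary SVM cannot predict one of L cavitation levels directly, so the
multiclass problem is reduced to L(L-1)/2 pairwise binary problems.  The
coding matrix has one row per class and one column per learner; entries are
+1 / -1 for the two classes a learner separates and 0 elsewhere.  Prediction
decodes the vector of learner scores back to a class.

Default decoding is loss-weighted hinge decoding: the predicted class c
minimises

    sum_j |m_cj| * max(0, 1 - m_cj * s_j(x)) / sum_j |m_cj|,

which uses score magnitudes, not just signs.  Hamming decoding (sign
agreement only) is available via ``decoding="hamming"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .knn import LabeledPoint
from .svm import LinearSvm1D, svm_fit_binary

__all__ = ["EcocClassifier", "ecoc_fit", "ecoc_predict"]


@dataclass(frozen=True)
class EcocClassifier:
    """One-vs-one ECOC ensemble of 1-D linear SVMs."""

    classes: tuple[int, ...]  # observed levels, ascending
    coding: np.ndarray  # (n_classes, n_learners) entries in {-1, 0, +1}
    learners: tuple[LinearSvm1D, ...]
    decoding: str = "hinge"  # "hinge" | "hamming"

    def __post_init__(self) -> None:
        if self.decoding not in ("hinge", "hamming"):
            raise ValueError("decoding must be 'hinge' or 'hamming'")
        if self.coding.shape != (len(self.classes), len(self.learners)):
            raise ValueError("coding matrix shape mismatch")


def ecoc_fit(
    training: Sequence[LabeledPoint],
    C: float = 1.0,
    decoding: str = "hinge",
) -> EcocClassifier:
    """Build a one-vs-one coding over the observed classes and train each learner.

    Learner (i, j) (classes ascending, i < j in lexicographic pair order) is
    trained only on the points of those two classes, coded +1 for class i
    and -1 for class j.  Raises if fewer than two classes are observed.
    """
    classes = tuple(sorted({p.label for p in training}))
    if len(classes) < 2:
        raise ValueError("ECOC needs at least 2 distinct labels in training")
    pairs = [
        (ci, cj)
        for a, ci in enumerate(classes)
        for cj in classes[a + 1 :]
    ]
    coding = np.zeros((len(classes), len(pairs)), dtype=int)
    learners: list[LinearSvm1D] = []
    index = {c: i for i, c in enumerate(classes)}
    for col, (ci, cj) in enumerate(pairs):
        coding[index[ci], col] = 1
        coding[index[cj], col] = -1
        pts = [
            (p.x, 1 if p.label == ci else -1)
            for p in training
            if p.label in (ci, cj)
        ]
        learners.append(svm_fit_binary(pts, C=C))
    return EcocClassifier(
        classes=classes, coding=coding, learners=tuple(learners), decoding=decoding
    )


def ecoc_predict(model: EcocClassifier, x: float) -> int:
    """Decode the learner scores at ``x`` to a cavitation level.

    Ties in the decoding loss fall to the smaller level.
    """
    scores = np.array([lrn.score(x) for lrn in model.learners], dtype=float)
    m = model.coding.astype(float)
    weight = np.abs(m)
    if model.decoding == "hinge":
        loss = np.maximum(0.0, 1.0 - m * scores[None, :])
    else:  # hamming: disagreeing sign -> 1, agreeing -> 0, zero score -> 1/2
        sign = np.sign(scores)[None, :]
        loss = np.where(m * sign < 0, 1.0, np.where((m != 0) & (sign == 0), 0.5, 0.0))
    totals = np.sum(weight * np.where(m != 0, loss, 0.0), axis=1) / np.sum(weight, axis=1)
    best = int(np.argmin(totals))  # argmin takes the first, i.e. smaller level
    return int(model.classes[best])
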
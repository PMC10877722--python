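"""Repeated-holdout cross-validation, confusion matrices and bootstrap CIs.

The evaluation design mirrors the study: each model is scored by an adapted
holdout technique — 10 independent random 70/30 train/test splits, with the
test accuracies averaged into the "cross-validation accuracy" — and by a
bootstrap that collects 10 sample means of 10 trained models each (100
trainings per model) whose spread yields a 95% confidence interval.  The
full comparison grid is 6 classifiers (kNN with k = 1, 2, 3, 5, 7 and an
ECOC SVM with C = 1) by 4 cavitation schemes: 24 model configurations,
2,400 trainings with the bootstrap enabled.

RNG policy: a single master seed spawns per-repeat child generators
deterministically, so any individual split can be reproduced in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ecoc import ecoc_fit, ecoc_predict
from .knn import LabeledPoint, knn_fit, knn_predict

__all__ = [
    "ModelSpec",
    "TrainTestSplit",
    "ConfusionMatrix",
    "CrossValidationResult",
    "BootstrapResult",
    "holdout_split",
    "confusion_matrix",
    "cross_validate",
    "bootstrap_ci",
    "run_model_grid",
    "prediction_line",
]


@dataclass(frozen=True)
class ModelSpec:
    """Names a classifier family and its hyperparameters."""

    kind: str  # "knn" | "ecoc_svm"
    k: int | None = None
    C: float = 1.0
    decoding: str = "hinge"

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "ecoc_svm"):
            raise ValueError("kind must be 'knn' or 'ecoc_svm'")
        if self.kind == "knn" and (self.k is None or self.k < 1):
            raise ValueError("knn spec requires k >= 1")

    @property
    def name(self) -> str:
        if self.kind == "knn":
            return f"knn_k{self.k}"
        return f"ecoc_svm_C{self.C:g}"


@dataclass(frozen=True)
class TrainTestSplit:
    """Disjoint train/test index sets covering the dataset exactly once."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


@dataclass(frozen=True)
class ConfusionMatrix:
    """L x L counts; rows are the true class, columns the predicted class."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-split test accuracies and their mean (the CV accuracy)."""

    per_split_accuracy: tuple[float, ...]
    mean_accuracy: float
    unseen_class_splits: int = 0  # splits whose test set held a class absent in training


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap of sample means: grand mean, spread and 95% CI."""

    sample_means: tuple[float, ...]
    grand_mean: float
    sd: float
    ci: tuple[float, float]


def _fit(spec: ModelSpec, train: Sequence[LabeledPoint]):
    if spec.kind == "knn":
        k = min(spec.k, len(train))  # degenerate tiny training sets
        return knn_fit(train, k)
    return ecoc_fit(train, C=spec.C, decoding=spec.decoding)


def _predict(spec: ModelSpec, model, x: float) -> int:
    if spec.kind == "knn":
        return knn_predict(model, x)
    return ecoc_predict(model, x)


def holdout_split(
    n: int, test_fraction: float = 0.3, rng: np.random.Generator | None = None
) -> TrainTestSplit:
    """Uniformly random unstratified split; |test| = floor(test_fraction * n)."""
    if n < 2:
        raise ValueError("need at least 2 points to split")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(math.floor(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate split: {n_test} test points of {n}")
    rng = rng if rng is not None else np.random.default_rng()
    perm = rng.permutation(n)
    return TrainTestSplit(
        train_indices=tuple(int(i) for i in perm[n_test:]),
        test_indices=tuple(int(i) for i in perm[:n_test]),
    )


def confusion_matrix(
    true_labels: Sequence[int], predicted_labels: Sequence[int], n_levels: int
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into an L x L matrix (levels 1..L)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    counts = np.zeros((n_levels, n_levels), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if not (1 <= t <= n_levels and 1 <= p <= n_levels):
            raise ValueError(f"label pair ({t}, {p}) outside 1..{n_levels}")
        counts[t - 1, p - 1] += 1
    return ConfusionMatrix(counts=counts)


def _split_rngs(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Spawn n child generators deterministically from one parent."""
    return [np.random.default_rng(s) for s in rng.bit_generator.seed_seq.spawn(n)]


def cross_validate(
    dataset: Sequence[LabeledPoint],
    model_spec: ModelSpec,
    repeats: int = 10,
    test_fraction: float = 0.3,
    rng: np.random.Generator | None = None,
) -> CrossValidationResult:
    """Adapted holdout: average test accuracy over fresh random splits.

    A test split containing a class never seen in training is not an error;
    predictions simply cannot hit it, and such splits are counted in
    ``unseen_class_splits`` for reporting.
    """
    rng = rng if rng is not None else np.random.default_rng()
    dataset = list(dataset)
    accuracies: list[float] = []
    unseen = 0
    for child in _split_rngs(rng, repeats):
        split = holdout_split(len(dataset), test_fraction, child)
        train = [dataset[i] for i in split.train_indices]
        test = [dataset[i] for i in split.test_indices]
        model = _fit(model_spec, train)
        preds = [_predict(model_spec, model, p.x) for p in test]
        hits = sum(1 for p, q in zip(preds, test) if p == q.label)
        accuracies.append(hits / len(test))
        if {p.label for p in test} - {p.label for p in train}:
            unseen += 1
    return CrossValidationResult(
        per_split_accuracy=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        unseen_class_splits=unseen,
    )


def bootstrap_ci(
    dataset: Sequence[LabeledPoint],
    model_spec: ModelSpec,
    samples: int = 10,
    models_per_sample: int = 10,
    test_fraction: float = 0.3,
    rng: np.random.Generator | None = None,
    z: float = 1.96,
    use_sem: bool = False,
) -> BootstrapResult:
    """Bootstrap the mean accuracy from repeated samples of trained models.

    Each sample trains ``models_per_sample`` models on fresh random splits
    and records their mean test accuracy; over ``samples`` repetitions the
    grand mean and the standard deviation of the sample means give the 95%
    interval grand_mean +/- z*sd.  ``use_sem=True`` divides the sd by
    sqrt(samples) instead (a standard-error variant).
    """
    rng = rng if rng is not None else np.random.default_rng()
    sample_means: list[float] = []
    for child in _split_rngs(rng, samples):
        res = cross_validate(
            dataset, model_spec, repeats=models_per_sample,
            test_fraction=test_fraction, rng=child,
        )
        sample_means.append(res.mean_accuracy)
    grand = float(np.mean(sample_means))
    sd = float(np.std(sample_means, ddof=1)) if len(sample_means) > 1 else 0.0
    half = z * (sd / math.sqrt(len(sample_means)) if use_sem else sd)
    return BootstrapResult(
        sample_means=tuple(sample_means),
        grand_mean=grand,
        sd=sd,
        ci=(grand - half, grand + half),
    )


def default_model_specs(
    k_values: Sequence[int] = (1, 2, 3, 5, 7), C: float = 1.0
) -> list[ModelSpec]:
    """The study's 6-classifier slate: five kNN variants plus one ECOC SVM."""
    specs = [ModelSpec(kind="knn", k=k) for k in k_values]
    specs.append(ModelSpec(kind="ecoc_svm", C=C))
    return specs


def run_model_grid(
    dataset_by_scheme: dict[int, Sequence[LabeledPoint]],
    C: float = 1.0,
    k_values: Sequence[int] = (1, 2, 3, 5, 7),
    repeats: int = 10,
    test_fraction: float = 0.3,
    rng: np.random.Generator | None = None,
    with_bootstrap: bool = False,
    bootstrap_samples: int = 10,
    models_per_sample: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Evaluate every classifier on every scheme's labelling of the trials.

    Returns a (classifier x scheme) table of mean CV accuracies, and, when
    ``with_bootstrap`` is set, a long-format bootstrap summary table
    (model, scheme, grand_mean, sd, ci_low, ci_high).
    """
    rng = rng if rng is not None else np.random.default_rng()
    specs = default_model_specs(k_values, C)
    scheme_ids = sorted(dataset_by_scheme)
    children = _split_rngs(rng, len(specs) * len(scheme_ids) * (2 if with_bootstrap else 1))
    it = iter(children)
    table = pd.DataFrame(
        index=[s.name for s in specs],
        columns=[f"scheme_{sid}" for sid in scheme_ids],
        dtype=float,
    )
    boot_rows: list[dict] = []
    for spec in specs:
        for sid in scheme_ids:
            data = dataset_by_scheme[sid]
            res = cross_validate(data, spec, repeats, test_fraction, next(it))
            table.loc[spec.name, f"scheme_{sid}"] = res.mean_accuracy
            if with_bootstrap:
                boot = bootstrap_ci(
                    data, spec, bootstrap_samples, models_per_sample,
                    test_fraction, next(it),
                )
                boot_rows.append(
                    {
                        "model": spec.name,
                        "scheme": sid,
                        "grand_mean": boot.grand_mean,
                        "sd": boot.sd,
                        "ci_low": boot.ci[0],
                        "ci_high": boot.ci[1],
                    }
                )
    boot_table = pd.DataFrame(boot_rows) if with_bootstrap else None
    return table, boot_table


def prediction_line(
    dataset: Sequence[LabeledPoint],
    model_spec: ModelSpec,
    temperatures: Sequence[float],
) -> pd.DataFrame:
    """Predicted level over a temperature sweep, for plotting."""
    model = _fit(model_spec, list(dataset))
    rows = [
        {"temperature_C": float(t), "predicted_level": _predict(model_spec, model, float(t))}
        for t in temperatures
    ]
    return pd.DataFrame(rows)
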
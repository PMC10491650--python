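"""10-fold cross-validation with Brier-style per-fold errors.

Each fold q holds out one tenth of the segments; a fresh seeded model is
trained on the other nine tenths and evaluated on the held-out tenth.  The
fold error is

    e_q = (1/m) * sum_n || yhat_n - onehot(y_n) ||^2

i.e. the multiclass Brier score of the predicted probability vectors (for a
scalar 0/1 prediction this reduces to the plain mean squared error), and the
aggregate is their mean, CVe = (1/10) * sum_q e_q.  Mean test accuracy across
folds is reported alongside as the headline figure.

Splitting is stratified by default: the ictal group has half the segment
count of the other ternary groups, and unstratified folds can end up missing
a class entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .bonn import TaskSpec
from .metrics import EvalReport, evaluation_report
from .network import CNNLSTMClassifier, ModelConfig
from .preprocess import SegmentSet

__all__ = ["FoldSplit", "CVResult", "tenfold_split", "fold_error", "cross_validate"]


@dataclass(frozen=True)
class FoldSplit:
    """Fold q (1-based) with its train/test index arrays."""

    q: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVResult:
    """Per-fold errors and reports plus their aggregates."""

    fold_errors: list[float]
    cve: float
    fold_sizes: list[int]
    fold_reports: list[EvalReport]
    fold_predictions: list[np.ndarray] = field(repr=False, default_factory=list)
    fold_truths: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def accuracies(self) -> list[float]:
        return [r.accuracy for r in self.fold_reports]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_errors": self.fold_errors,
            "cve": self.cve,
            "fold_sizes": self.fold_sizes,
            "accuracies": self.accuracies,
            "mean_accuracy": self.mean_accuracy,
            "fold_reports": [r.to_dict() for r in self.fold_reports],
        }


def tenfold_split(
    labels: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> list[FoldSplit]:
    """Seeded shuffled k-fold partition of ``range(len(labels))``.

    Every index lands in exactly one test fold; fold sizes differ by at most
    one, and under stratification per-class counts across folds differ by at
    most one.  If some class has fewer members than ``n_folds``, stratification
    is impossible; a warning is emitted and a plain shuffled split is used.
    """
    y = np.asarray(labels, dtype=int)
    if y.size < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {y.size}")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            warnings.warn(
                f"smallest class has {counts.min()} < {n_folds} members; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            stratified = False
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        FoldSplit(q=q, train_idx=np.asarray(tr), test_idx=np.asarray(te))
        for q, (tr, te) in enumerate(splitter.split(np.zeros_like(y), y), start=1)
    ]


def fold_error(probabilities: np.ndarray, truths: Sequence[int]) -> float:
    """Brier-style fold error: mean squared distance to the one-hot truth."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truths, dtype=int)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (m, k) aligned with truths")
    if p.shape[0] < 1:
        raise ValueError("fold_error requires at least one sample")
    onehot = np.zeros_like(p)
    onehot[np.arange(y.size), y] = 1.0
    return float(np.mean(np.sum((p - onehot) ** 2, axis=1)))


def _fold_seed(seed: int, q: int) -> int:
    return int(np.random.SeedSequence([seed, q]).generate_state(1)[0] % (2**31))


def cross_validate(
    dataset: SegmentSet,
    cfg: ModelConfig,
    task: TaskSpec,
    seed: int = 0,
    n_folds: int = 10,
    stratified: bool = True,
) -> CVResult:
    """Train/evaluate one fresh seeded model per fold and aggregate errors.

    Per-fold model seeds are derived from ``seed`` and the fold index, so the
    whole procedure is reproducible; no information flows from a test fold
    into its training run (normalization is per segment).
    """
    if len(dataset) == 0:
        raise ValueError("cross_validate requires a non-empty dataset")
    splits = tenfold_split(dataset.labels, n_folds=n_folds, seed=seed, stratified=stratified)
    errors: list[float] = []
    sizes: list[int] = []
    reports: list[EvalReport] = []
    predictions: list[np.ndarray] = []
    truths: list[np.ndarray] = []
    for split in splits:
        model = CNNLSTMClassifier(replace(cfg, seed=_fold_seed(seed, split.q)), task.n_classes)
        try:
            model.fit(dataset.segments[split.train_idx], dataset.labels[split.train_idx])
        except RuntimeError as exc:
            raise RuntimeError(f"fold {split.q}: {exc}") from exc
        probs = model.predict_proba(dataset.segments[split.test_idx])
        y_test = dataset.labels[split.test_idx]
        errors.append(fold_error(probs, y_test))
        sizes.append(int(split.test_idx.size))
        reports.append(evaluation_report(probs, y_test, task))
        predictions.append(probs)
        truths.append(y_test)
    return CVResult(
        fold_errors=errors,
        cve=float(np.mean(errors)),
        fold_sizes=sizes,
        fold_reports=reports,
        fold_predictions=predictions,
        fold_truths=truths,
    )
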
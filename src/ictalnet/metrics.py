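"""Multi-index evaluation: confusion table, group SPE/SEN, ACC, ROC/AUC, PRC.

The confusion table ``A`` is indexed rows = real class, columns = predicted
class: ``A[i, j]`` counts samples of real group i assigned to group j, and
``A_i`` is the row total.  Group sensitivity and specificity follow the
three-group formulas

    SEN_g = A_gg / A_g
    SPE_g = (sum of A_ij over i != g, j != g) / (sum of A_i over i != g)

which for two classes reduce to the familiar TP/(TP+FN) and TN/(TN+FP), and
for any k equal the one-vs-rest recall and true-negative rate of group g.

ROC curves are one-vs-rest threshold sweeps on a class's predicted
probability; AUC uses the trapezoid rule over tie-grouped points, which
equals the Mann-Whitney probability-of-correct-ranking statistic with ties
credited 1/2.  Implemented directly (scikit-learn serves only as an
independent cross-check in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bonn import TaskSpec

__all__ = [
    "ConfusionTable",
    "EvalReport",
    "confusion_table",
    "group_sensitivity",
    "group_specificity",
    "accuracy",
    "ovr_roc_auc",
    "macro_ovr_auc",
    "pr_curve",
    "evaluation_report",
]


@dataclass
class ConfusionTable:
    """k x k count table, rows = real class, columns = predicted class."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        if self.table.ndim != 2 or self.table.shape[0] != self.table.shape[1]:
            raise ValueError("confusion table must be square")
        if (self.table < 0).any():
            raise ValueError("confusion table entries must be non-negative")

    @property
    def k(self) -> int:
        return int(self.table.shape[0])

    @property
    def row_totals(self) -> np.ndarray:
        """A_i: total number of samples of each real class."""
        return self.table.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.table.sum())


def confusion_table(truths: Sequence[int], predictions: Sequence[int], k: int) -> ConfusionTable:
    """Tally an (k x k) confusion table from aligned label vectors."""
    t = np.asarray(truths, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truths and predictions must have equal length")
    for name, arr in (("truth", t), ("prediction", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} label out of range 0..{k - 1}")
    A = np.zeros((k, k), dtype=int)
    np.add.at(A, (t, p), 1)
    return ConfusionTable(A)


def group_sensitivity(A: ConfusionTable, g: int) -> float:
    """SEN_g = A_gg / A_g (fraction of group g's samples correctly recognized)."""
    totals = A.row_totals
    if totals[g] == 0:
        raise ValueError(f"sensitivity of group {g} undefined: no samples of that group")
    return float(A.table[g, g] / totals[g])


def group_specificity(A: ConfusionTable, g: int) -> float:
    """SPE_g: fraction of all other groups' samples assigned to other groups."""
    others = [i for i in range(A.k) if i != g]
    denom = A.row_totals[others].sum()
    if denom == 0:
        raise ValueError(f"specificity of group {g} undefined: complementary groups are empty")
    num = A.table[np.ix_(others, others)].sum()
    return float(num / denom)


def accuracy(A: ConfusionTable) -> float:
    """trace(A) / sum(A)."""
    if A.total == 0:
        raise ValueError("accuracy undefined on an empty confusion table")
    return float(np.trace(A.table) / A.total)


def _ovr_scores(probabilities: np.ndarray, truths: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    probabilities = np.asarray(probabilities, dtype=float)
    truths = np.asarray(truths, dtype=int)
    scores = probabilities[:, c] if probabilities.ndim == 2 else probabilities
    if scores.shape[0] != truths.shape[0]:
        raise ValueError("probabilities and truths must align")
    pos = truths == c
    if pos.all() or not pos.any():
        raise ValueError(f"ROC for class {c} needs at least one positive and one negative")
    return scores, pos


def ovr_roc_auc(
    probabilities: np.ndarray, truths: Sequence[int], c: int
) -> tuple[np.ndarray, float]:
    """One-vs-rest ROC points ``(fpr, tpr)`` and trapezoid AUC for class *c*.

    Thresholds sweep every distinct score from high to low; tied scores are
    grouped into a single ROC vertex, so the trapezoid area equals the
    Mann-Whitney ranking probability with ties counted half.
    """
    scores, pos = _ovr_scores(np.asarray(probabilities), np.asarray(truths, dtype=int), c)
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # keep only the last index of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def macro_ovr_auc(probabilities: np.ndarray, truths: Sequence[int], k: int) -> float:
    """Unweighted mean of the k one-vs-rest AUCs; every class must be present."""
    truths = np.asarray(truths, dtype=int)
    missing = [c for c in range(k) if not (truths == c).any()]
    if missing:
        raise ValueError(f"macro AUC undefined: class(es) {missing} absent from truths")
    return float(np.mean([ovr_roc_auc(probabilities, truths, c)[1] for c in range(k)]))


def pr_curve(probabilities: np.ndarray, truths: Sequence[int], c: int) -> np.ndarray:
    """Precision-recall points ``(threshold, precision, recall)`` for class *c*.

    One point per distinct score, sweeping thresholds from high to low, so
    recall is non-decreasing along the returned rows; the final row has
    recall 1 and precision equal to the class prevalence.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    truths = np.asarray(truths, dtype=int)
    scores = probabilities[:, c] if probabilities.ndim == 2 else probabilities
    pos = truths == c
    if not pos.any():
        raise ValueError(f"PR curve for class {c} needs at least one positive")
    n_pos = int(pos.sum())
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    return np.column_stack([sorted_scores[distinct], precision, recall])


@dataclass
class EvalReport:
    """All assessment indices for one evaluated prediction set.

    Per-group values are keyed by the task's group labels (e.g. ``"{F/N}"``);
    ``mean_sensitivity`` / ``mean_specificity`` are their unweighted means.
    """

    task_name: str
    group_names: list[str]
    confusion: ConfusionTable
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    auc: dict[str, float]
    macro_auc: float
    roc: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    prc: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(list(self.sensitivity.values())))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(list(self.specificity.values())))

    def to_dict(self) -> dict:
        """JSON-serializable summary (curves as plain lists)."""
        return {
            "task": self.task_name,
            "groups": self.group_names,
            "confusion": self.confusion.table.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "roc": {g: r.tolist() for g, r in self.roc.items()},
            "prc": {g: r.tolist() for g, r in self.prc.items()},
        }


def evaluation_report(
    probabilities: np.ndarray, truths: Sequence[int], task: TaskSpec
) -> EvalReport:
    """Assemble every index for predicted probabilities against true labels."""
    probabilities = np.asarray(probabilities, dtype=float)
    truths = np.asarray(truths, dtype=int)
    k = task.n_classes
    if probabilities.ndim != 2 or probabilities.shape[1] != k:
        raise ValueError(f"probabilities must be (n, {k}) for task {task.name!r}")
    if probabilities.shape[0] != truths.shape[0]:
        raise ValueError("probabilities and truths must align")
    preds = probabilities.argmax(axis=1)
    A = confusion_table(truths, preds, k)
    names = [task.group_label(g) for g in range(k)]
    sen = {names[g]: group_sensitivity(A, g) for g in range(k)}
    spe = {names[g]: group_specificity(A, g) for g in range(k)}
    roc: dict[str, np.ndarray] = {}
    auc: dict[str, float] = {}
    prc: dict[str, np.ndarray] = {}
    for g in range(k):
        points, a = ovr_roc_auc(probabilities, truths, g)
        roc[names[g]] = points
        auc[names[g]] = a
        prc[names[g]] = pr_curve(probabilities, truths, g)
    return EvalReport(
        task_name=task.name,
        group_names=names,
        confusion=A,
        accuracy=accuracy(A),
        sensitivity=sen,
        specificity=spe,
        auc=auc,
        macro_auc=float(np.mean(list(auc.values()))),
        roc=roc,
        prc=prc,
    )
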
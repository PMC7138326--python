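"""Hold-out evaluation: k-fold partitioning, AUC and confusion matrices.

Sites are randomly divided into five near-equal folds; models train on four
(80 %) and are tested on the fifth (20 %). Test-fold diagnostics are the
area under the ROC curve (Mann-Whitney formulation, ties counted half) and
the 2x2 confusion matrix at a 0.5 probability threshold — meaningful here
because balanced case weights re-center prevalence at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class EvaluationError(ValueError):
    pass


@dataclass
class PartitionPlan:
    fold: np.ndarray  # fold id per site, 1..n_folds
    n_folds: int
    seed: int

    def train_mask(self, test_fold: int) -> np.ndarray:
        return self.fold != test_fold

    def test_mask(self, test_fold: int) -> np.ndarray:
        return self.fold == test_fold


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def make_partition(n_sites: int, seed: int, n_folds: int = 5) -> PartitionPlan:
    """Seeded random assignment of sites to near-equal folds.

    Fold sizes differ by at most one; every site lands in exactly one fold.
    """
    if n_sites < n_folds:
        raise EvaluationError("fewer sites than folds")
    base = np.concatenate([
        np.full(n_sites // n_folds + (1 if k < n_sites % n_folds else 0),
                k + 1, dtype=int)
        for k in range(n_folds)
    ])
    rng = np.random.default_rng(seed)
    rng.shuffle(base)
    return PartitionPlan(fold=base, n_folds=n_folds, seed=seed)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """P(random presence outscores random absence), ties counted 1/2.

    Computed via the rank-sum identity, so it is invariant under any
    strictly monotone transform of the scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
) -> ConfusionSummary:
    """2x2 confusion counts; scores equal to the threshold classify positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise EvaluationError("confusion matrix needs both classes")
    pred = scores >= threshold
    return ConfusionSummary(
        tp=int(((labels == 1) & pred).sum()),
        fp=int(((labels == 0) & pred).sum()),
        tn=int(((labels == 0) & ~pred).sum()),
        fn=int(((labels == 1) & ~pred).sum()),
        threshold=threshold,
    )


def evaluate_holdout(labels, scores, threshold: float = 0.5) -> dict:
    """AUC + confusion-matrix diagnostics in one tidy record."""
    cm = confusion(labels, scores, threshold)
    return {
        "auc": auc(labels, scores),
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
        "n_test": cm.n,
    }
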
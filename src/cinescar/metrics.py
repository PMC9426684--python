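"""Segmentation and classification metrics and the weighted loss functions.

Covers the Dice similarity coefficient and its channel-weighted loss (the
four channels are background, myocardium, LV cavity and scar), inverse-
frequency class weights for imbalanced binary classification, the weighted
cross-entropy built on them, the standard confusion-matrix metrics and
cross-validated ROC/AUC.

A small epsilon smooths the Dice ratio so that an empty ground-truth channel
matched by an empty prediction counts as a perfect overlap (0/0 -> 1) rather
than NaN; empty scar channels are common.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

_CLIP_DELTA = 1e-7  # probability clipping so log stays finite


@dataclass(frozen=True)
class DiceWeights:
    """Channel weights (background, myocardium, cavity, scar) for the Dice loss."""

    beta: tuple[float, float, float, float] = (0.15, 0.25, 0.25, 0.35)
    epsilon: float = 1e-6

    def __post_init__(self):
        if min(self.beta) < 0:
            raise ValueError("channel weights must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights lambda_i = (1/k_i) * (N/C)."""

    lambda_: tuple[float, ...]
    class_counts: tuple[int, ...]
    total: int
    n_classes: int

    def rounded(self, ndigits: int = 3) -> tuple[float, ...]:
        """Display rounding only; the stored weights keep full precision."""
        return tuple(round(l, ndigits) for l in self.lambda_)


def dice_per_channel(y, y_hat, epsilon: float = 1e-6) -> float:
    """Dice similarity of one channel: (2*sum(y*yhat)+eps) / (sum(y)+sum(yhat)+eps).

    On hard binary masks this equals the set-overlap form 2|A∩B|/(|A|+|B|)
    as epsilon -> 0.  ``y_hat`` may be a soft (posterior probability) map.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("mask shapes differ")
    num = 2.0 * float(np.sum(y * y_hat)) + epsilon
    den = float(np.sum(y)) + float(np.sum(y_hat)) + epsilon
    return num / den


def weighted_dice_loss(y, y_hat, weights: DiceWeights | None = None) -> float:
    """Channel-weighted Dice loss L = sum_i beta_i * (1 - DSC_i) over 4 channels.

    ``y`` and ``y_hat`` are (4, ...) arrays: one-hot ground truth and
    predicted per-channel posteriors.
    """
    weights = weights or DiceWeights()
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape[0] != 4 or y_hat.shape[0] != 4:
        raise ValueError("expected 4 channels")
    return float(
        sum(
            b * (1.0 - dice_per_channel(y[i], y_hat[i], weights.epsilon))
            for i, b in enumerate(weights.beta)
        )
    )


def compute_class_weights(class_counts, n_classes: int | None = None) -> ClassWeights:
    """Per-class weights lambda_i = (1/k_i) * (N/C) with N = sum(k_i).

    Example: counts (336, 170) with C=2 give (0.753, 1.488) to 3 decimals.
    """
    counts = tuple(int(k) for k in class_counts)
    if any(k <= 0 for k in counts):
        raise ValueError("all class counts must be > 0")
    c = n_classes if n_classes is not None else len(counts)
    n = sum(counts)
    lam = tuple((1.0 / k) * (n / c) for k in counts)
    return ClassWeights(lambda_=lam, class_counts=counts, total=n, n_classes=c)


def weighted_cross_entropy(y, y_hat, weights: ClassWeights | None = None) -> float:
    """Class-weighted cross-entropy over a batch of binary one-hot labels.

    ``y`` is (N, 2) one-hot; ``y_hat`` is (N, 2) predicted class
    probabilities (a scalar sigmoid output p expands to (1-p, p)).  Each
    sample contributes ``-lambda_c * log(y_hat[c])`` with ``c`` its true
    class; the batch loss is the mean.  With unit weights this reduces to
    plain mean cross-entropy.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_hat.ndim == 1:  # sigmoid head: expand to the probability pair
        y_hat = np.stack([1.0 - y_hat, y_hat], axis=1)
    if y.ndim == 1:
        y = np.stack([1.0 - y, y], axis=1)
    if y.shape != y_hat.shape or y.shape[1] != 2:
        raise ValueError("expected matching (N, 2) label and probability arrays")
    if np.any(y_hat < 0) or np.any(y_hat > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    lam = np.asarray(weights.lambda_ if weights is not None else (1.0, 1.0))
    p = np.clip(y_hat, _CLIP_DELTA, 1.0 - _CLIP_DELTA)
    true_class = np.argmax(y, axis=1)
    p_true = p[np.arange(len(p)), true_class]
    return float(-np.mean(lam[true_class] * np.log(p_true)))


@dataclass
class ClassificationReport:
    """Binary confusion-matrix summary with zero-division flags."""

    tn: int
    fp: int
    fn: int
    tp: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    zero_division_flags: list = field(default_factory=list)

    @property
    def confusion_matrix(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "zero_division_flags": self.zero_division_flags,
        }


def classification_report(y_true, y_pred) -> ClassificationReport:
    """Confusion matrix plus precision, recall, F1 and accuracy for binary labels.

    Zero denominators yield 0 for the affected metric with a flag recorded.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))).issubset({0, 1}):
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    flags = []

    def _safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "f1")
    accuracy = _safe(tp + tn, len(y_true), "accuracy")
    return ClassificationReport(tn, fp, fn, tp, precision, recall, f1, accuracy, flags)


@dataclass
class CvRocResult:
    """Per-fold ROC curves on a common FPR grid with mean AUC +/- SD."""

    fpr_grid: np.ndarray
    tpr_per_fold: np.ndarray  # (n_folds, len(grid))
    auc_per_fold: np.ndarray
    mean_auc: float
    sd_auc: float

    @property
    def mean_tpr(self) -> np.ndarray:
        return self.tpr_per_fold.mean(axis=0)

    def to_csv(self, path) -> None:
        """Write per-fold ROC curves as columns (fpr, tpr_fold0, ...)."""
        import pandas as pd

        data = {"fpr": self.fpr_grid}
        for i, tpr in enumerate(self.tpr_per_fold):
            data[f"tpr_fold{i}"] = tpr
        pd.DataFrame(data).to_csv(path, index=False)

    def plot(self, path) -> None:
        """Mean ROC curve with a ±1 SD band, saved as an image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mean = self.mean_tpr
        sd = self.tpr_per_fold.std(axis=0)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.fpr_grid, mean, color="C0", label=f"AUC {self.mean_auc:.2f}±{self.sd_auc:.2f}")
        ax.fill_between(
            self.fpr_grid, np.clip(mean - sd, 0, 1), np.clip(mean + sd, 0, 1),
            color="gray", alpha=0.35, label="±1 SD",
        )
        ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def cv_roc_auc(features, labels, model, n_folds: int = 10, seed: int = 0) -> CvRocResult:
    """Stratified k-fold cross-validated ROC curves and AUC for a classifier.

    ``model`` is an (unfitted) sklearn estimator exposing either
    ``decision_function`` or ``predict_proba``; it is cloned per fold.  Folds
    are reduced with a warning when a class has fewer members than
    ``n_folds``.  Per-fold curves are interpolated onto a common FPR grid.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    folds = int(min(n_folds, counts.min()))
    if folds < n_folds:
        import warnings

        warnings.warn(f"reducing folds from {n_folds} to {folds} (small class)", stacklevel=2)
    grid = np.linspace(0.0, 1.0, 101)
    tprs, aucs = [], []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(x, y):
        est = clone(model)
        if hasattr(est, "random_state"):
            est.random_state = seed
        est.fit(x[train_idx], y[train_idx])
        if hasattr(est, "decision_function"):
            scores = est.decision_function(x[test_idx])
        else:
            scores = est.predict_proba(x[test_idx])[:, 1]
        fpr, tpr, _ = roc_curve(y[test_idx], scores)
        aucs.append(auc(fpr, tpr))
        interp = np.interp(grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    aucs = np.asarray(aucs)
    return CvRocResult(
        fpr_grid=grid,
        tpr_per_fold=np.asarray(tprs),
        auc_per_fold=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std()),
    )
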
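"""Classical classifiers over the engineered feature table: dataset
splitting, z-score standardisation, SVM (RBF) and decision-tree training,
and permutation feature importance.

The learners themselves are scikit-learn estimators; this module fixes the
conventions used throughout the pipeline (floor-remainder split sizes,
train-only standardisation statistics, seeded determinism) and returns
structured reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class SplitSpec:
    """Partition fractions with the floor-remainder rounding rule.

    Non-training partition sizes are ``floor(fraction * N)``; the training
    partition receives the remainder.  Fractions are ordered (train, test)
    or (train, val, test) and must sum to 1.
    """

    fractions: tuple[float, ...] = (0.8, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.fractions) not in (2, 3):
            raise ValueError("expected (train, test) or (train, val, test) fractions")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class DatasetSplit:
    train: np.ndarray
    test: np.ndarray
    val: np.ndarray | None = None

    @property
    def counts(self) -> tuple[int, ...]:
        if self.val is None:
            return (len(self.train), len(self.test))
        return (len(self.train), len(self.val), len(self.test))


def _floor_sizes(n: int, fractions) -> list[int]:
    others = [int(np.floor(f * n)) for f in fractions[1:]]
    return [n - sum(others)] + others


def split_dataset(n_samples: int, spec: SplitSpec, labels=None) -> DatasetSplit:
    """Split sample indices into partitions with a seeded shuffle.

    With ``spec.stratified`` and ``labels`` given, the floor rule is applied
    per class so class balance carries into every partition.  For 722
    samples at (0.70, 0.15, 0.15) the unstratified sizes are 506/108/108.
    """
    n_parts = len(spec.fractions)
    if n_samples < n_parts:
        raise ValueError("fewer samples than partitions")
    rng = np.random.default_rng(spec.seed)

    def assign(indices) -> list[np.ndarray]:
        idx = rng.permutation(indices)
        sizes = _floor_sizes(len(idx), spec.fractions)
        out, start = [], 0
        for s in sizes:
            out.append(np.sort(idx[start : start + s]))
            start += s
        return out

    if spec.stratified and labels is not None:
        labels = np.asarray(labels)
        parts = [[] for _ in range(n_parts)]
        for cls in np.unique(labels):
            for i, chunk in enumerate(assign(np.flatnonzero(labels == cls))):
                parts[i].append(chunk)
        parts = [np.sort(np.concatenate(p)) if p else np.array([], dtype=int) for p in parts]
    else:
        parts = assign(np.arange(n_samples))
    if any(len(p) == 0 for p in parts):
        import warnings

        warnings.warn("a partition is empty at this sample size", stacklevel=2)
    if n_parts == 2:
        return DatasetSplit(train=parts[0], test=parts[1])
    return DatasetSplit(train=parts[0], val=parts[1], test=parts[2])


class Standardizer:
    """Z-score standardisation with statistics estimated on the training set.

    Thin sklearn-style wrapper over ``StandardScaler`` that additionally
    flags constant features (they map to 0).
    """

    def __init__(self):
        self._scaler = StandardScaler()

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "Standardizer":
        return self

    def fit(self, x, y=None) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        self._scaler.fit(x)
        self.mean_ = self._scaler.mean_
        self.scale_ = self._scaler.scale_
        self.constant_flags_ = self._scaler.var_ == 0
        return self

    def transform(self, x) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise RuntimeError("Standardizer must be fitted before transform")
        return self._scaler.transform(np.asarray(x, dtype=float))

    def fit_transform(self, x, y=None) -> np.ndarray:
        return self.fit(x).transform(x)


def train_svm_rbf(x, y, hyperparams: dict | None = None, seed: int = 0) -> SVC:
    """Fit an RBF-kernel SVM on standardised features.

    Defaults C=1 and gamma='scale' (1/(d*Var)); the fitted model exposes
    ``decision_function`` scores for ROC analysis.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = {"C": 1.0, "kernel": "rbf", "gamma": "scale"}
    params.update(hyperparams or {})
    model = SVC(random_state=seed, **params)
    model.fit(np.asarray(x, dtype=float), y)
    return model


def train_decision_tree(x, y, hyperparams: dict | None = None, seed: int = 0) -> DecisionTreeClassifier:
    """Fit a decision tree (Gini, unlimited depth by default).

    The learned split structure is inspectable via the sklearn ``tree_``
    attribute.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = {"criterion": "gini"}
    params.update(hyperparams or {})
    model = DecisionTreeClassifier(random_state=seed, **params)
    model.fit(np.asarray(x, dtype=float), y)
    return model


@dataclass
class ImportanceReport:
    """Permutation importances: accuracy drop per feature over n_repeats shuffles."""

    feature_names: list
    importances: np.ndarray  # (n_features, n_repeats)
    partition: str = "test"

    @property
    def mean(self) -> np.ndarray:
        return self.importances.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.importances.std(axis=1)

    def ranking(self) -> list:
        order = np.argsort(self.mean)[::-1]
        return [self.feature_names[i] for i in order]

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "features": [
                {"name": n, "mean": float(m), "sd": float(s)}
                for n, m, s in zip(self.feature_names, self.mean, self.sd)
            ],
        }


def permutation_importance(
    model,
    x_eval,
    y_eval,
    feature_names=None,
    n_repeats: int = 10,
    seed: int = 0,
    partition: str = "test",
) -> ImportanceReport:
    """Importance of each feature as the mean decrease in accuracy when the
    feature is shuffled, over ``n_repeats`` seeded shuffles on the
    evaluation partition.
    """
    x_eval = np.asarray(x_eval, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x_eval.shape[1])]
    if len(feature_names) != x_eval.shape[1]:
        raise ValueError("feature name count does not match the feature matrix")
    result = _sk_permutation_importance(
        model, x_eval, np.asarray(y_eval), scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    return ImportanceReport(
        feature_names=list(feature_names), importances=result.importances, partition=partition
    )
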
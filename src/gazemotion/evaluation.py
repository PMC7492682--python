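"""Leave-one-subject-out emotion classification and feature screening.

The labelled dataset holds one example per participant x class movie
(standardized 18-feature vectors).  Cross-validation is leave-one-subject-out
(LOSO): each fold trains on all but one participant and tests on the
held-out participant's examples, so train and test never share a subject.
Fold predictions are pooled into a single confusion matrix (rows predicted,
columns true) from which accuracy and per-class precision, recall,
specificity and F1 are computed; per-fold accuracies are kept for
dispersion reporting.

Three classifiers mirror the study design: a quadratic-kernel SVM
(polynomial degree 2), linear discriminant analysis, and an 11-nearest-
neighbour vote with ties broken by summed distance to the tied classes'
neighbours.

The feature screen tests, per feature: per-class normality
(Kolmogorov-Smirnov against a normal with moments estimated from the
sample), a one-way ANOVA across the three classes, and pairwise Welch
comparisons with Bonferroni correction (x3, capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = [
    "CLASSES",
    "LabelledDataset",
    "ConfusionMatrix",
    "ClassMetrics",
    "LosoResult",
    "assemble_dataset",
    "loso_splits",
    "run_classifier",
    "metrics_from_confusion",
    "evaluate_loso",
    "feature_screen",
    "MODELS",
]

CLASSES = ("C1", "C2", "C3")
MODELS = ("qsvm", "lda", "knn11")


@dataclass
class LabelledDataset:
    X: np.ndarray  # (n_examples, n_features)
    y: np.ndarray  # class labels
    participants: np.ndarray  # participant id per example
    feature_names: tuple = FEATURE_NAMES
    classes: tuple = CLASSES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.participants = np.asarray(self.participants)
        if not (len(self.X) == len(self.y) == len(self.participants)):
            raise ValueError("X, y and participants must have equal length")

    @property
    def n_examples(self) -> int:
        return len(self.y)

    def subset(self, classes: Sequence[str]) -> "LabelledDataset":
        """Restrict to a class subset, e.g. one pairwise task."""
        mask = np.isin(self.y, list(classes))
        return LabelledDataset(
            self.X[mask], self.y[mask], self.participants[mask],
            self.feature_names, tuple(classes),
        )


def assemble_dataset(
    features: pd.DataFrame, classes: Sequence[str] = CLASSES
) -> LabelledDataset:
    """Build the labelled example matrix from a (standardized) feature table.

    Each participant must contribute every class movie; a gap is reported
    explicitly.  With 25 participants and 2 movies per class this yields
    150 three-class examples, and each pairwise subset has 100.
    """
    sub = features[features["class_label"].isin(list(classes))]
    if sub.duplicated(["participant_id", "movie_id"]).any():
        raise ValueError("duplicate (participant, movie) pairs in feature table")
    movies_per_class = sub.groupby("class_label")["movie_id"].nunique()
    gaps = []
    expected = sub.groupby("class_label")["movie_id"].unique()
    for pid, group in sub.groupby("participant_id"):
        for cls in classes:
            have = set(group.loc[group["class_label"] == cls, "movie_id"])
            missing = set(expected.get(cls, [])) - have
            if missing:
                gaps.append((pid, cls, sorted(missing)))
    if gaps:
        raise ValueError(f"participants missing class movies: {gaps}")
    del movies_per_class
    sub = sub.sort_values(["participant_id", "movie_id"]).reset_index(drop=True)
    return LabelledDataset(
        X=sub[list(FEATURE_NAMES)].to_numpy(dtype=float),
        y=sub["class_label"].to_numpy(),
        participants=sub["participant_id"].to_numpy(),
        classes=tuple(classes),
    )


def loso_splits(dataset: LabelledDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train, test) index pair per participant; folds partition the data."""
    pids = np.unique(dataset.participants)
    if len(pids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 participants")
    splits = []
    for pid in pids:
        test = np.flatnonzero(dataset.participants == pid)
        train = np.flatnonzero(dataset.participants != pid)
        splits.append((train, test))
    return splits


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    """Majority vote over the k Euclidean nearest neighbours.

    Vote ties (possible with 3 classes even at k = 11) are broken in favour
    of the tied class with the smallest summed neighbour distance.
    """
    if k > len(X_train):
        raise ValueError(f"k={k} exceeds the training-set size {len(X_train)}")
    dist = euclidean_distances(X_test, X_train)
    nn = np.argpartition(dist, k - 1, axis=1)[:, :k]
    preds = []
    for row, idx in zip(dist, nn):
        labels = y_train[idx]
        classes, counts = np.unique(labels, return_counts=True)
        best = classes[counts == counts.max()]
        if len(best) == 1:
            preds.append(best[0])
        else:
            sums = {c: row[idx[labels == c]].sum() for c in best}
            preds.append(min(sums, key=sums.get))
    return np.asarray(preds)


def run_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    model: str = "qsvm",
    **params,
) -> np.ndarray:
    """Fit one classifier on the training fold and predict the test fold.

    Models: ``qsvm`` (SVC with degree-2 polynomial kernel, C=1, gamma=1,
    coef0=1, one-vs-one for three classes), ``lda`` (pooled-covariance
    linear discriminant) and ``knn11`` (11-nearest-neighbour vote).
    Keyword arguments override the model defaults.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold must contain at least 2 classes")
    if model == "qsvm":
        defaults = dict(C=1.0, kernel="poly", degree=2, gamma=1.0, coef0=1.0)
        defaults.update(params)
        clf = SVC(**defaults)
    elif model == "lda":
        clf = LinearDiscriminantAnalysis(**params)
    elif model == "knn11":
        return _knn_predict(X_train, y_train, X_test, k=int(params.get("k", 11)))
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


@dataclass
class ConfusionMatrix:
    """Counts with rows = predicted class, columns = true class."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the label set")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels: Sequence[str]) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[p], index[t]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class ClassMetrics:
    """Per-class precision/recall/specificity/F1 plus macro means and accuracy."""

    per_class: pd.DataFrame  # rows classes, columns P/R/S/F1
    accuracy: float

    @property
    def macro(self) -> pd.Series:
        return self.per_class.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.loc["mean"] = self.macro
        return out


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """Accuracy and per-class P, R, S, F1 from a pooled confusion matrix.

    An empty predicted row makes precision undefined; it is reported as 0
    with a warning, and F1 follows as 0.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    rows = {}
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        row_sum = counts[i, :].sum()  # predicted as this class
        col_sum = counts[:, i].sum()  # truly this class
        fp = row_sum - tp
        tn = total - col_sum - fp
        if row_sum == 0:
            warnings.warn(f"no predictions for class {label}; precision set to 0", stacklevel=2)
            precision = 0.0
        else:
            precision = tp / row_sum
        recall = tp / col_sum if col_sum > 0 else 0.0
        specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
        rows[label] = {"precision": precision, "recall": recall,
                       "specificity": specificity, "f1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return ClassMetrics(per_class=per_class, accuracy=float(np.trace(counts) / total))


@dataclass
class LosoResult:
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    fold_accuracies: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        """Pooled-matrix accuracy (the mean of per-fold accuracies is also
        available via ``fold_accuracies``)."""
        return self.metrics.accuracy

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(list(self.fold_accuracies.values())))


def evaluate_loso(dataset: LabelledDataset, model: str = "qsvm", **params) -> LosoResult:
    """Run LOSO cross-validation and pool fold predictions."""
    y_true_all, y_pred_all = [], []
    fold_acc = {}
    for train, test in loso_splits(dataset):
        pred = run_classifier(dataset.X[train], dataset.y[train], dataset.X[test],
                              model=model, **params)
        truth = dataset.y[test]
        fold_acc[str(dataset.participants[test][0])] = float(np.mean(pred == truth))
        y_true_all.extend(truth)
        y_pred_all.extend(pred)
    cm = ConfusionMatrix.from_predictions(y_true_all, y_pred_all, dataset.classes)
    return LosoResult(cm, metrics_from_confusion(cm), fold_acc)


def feature_screen(
    dataset: LabelledDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature normality, ANOVA and Bonferroni pairwise comparisons.

    Returns one row per feature with: the minimum per-class KS normality
    p-value, the one-way ANOVA F and p across the three classes, a
    significance flag at ``alpha``, and Bonferroni-adjusted (x3, capped at
    1) Welch p-values for each class pair.  Features with zero variance in
    every class are skipped with a warning.
    """
    classes = list(dataset.classes)
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    records = []
    for j, name in enumerate(dataset.feature_names):
        groups = [dataset.X[dataset.y == c, j] for c in classes]
        if all(len(g) < 2 or np.std(g) == 0 for g in groups):
            warnings.warn(f"feature {name} has no within-class variance; skipped", stacklevel=2)
            continue
        ks_ps = []
        for g in groups:
            s = np.std(g, ddof=1)
            if len(g) >= 3 and s > 0:
                ks_ps.append(stats.kstest(g, "norm", args=(np.mean(g), s)).pvalue)
        anova = stats.f_oneway(*groups)
        rec = {
            "feature": name,
            "ks_p_min": float(min(ks_ps)) if ks_ps else np.nan,
            "anova_F": float(anova.statistic),
            "anova_p": float(anova.pvalue),
            "significant": bool(anova.pvalue < alpha),
        }
        for a, b in pairs:
            ga, gb = dataset.X[dataset.y == a, j], dataset.X[dataset.y == b, j]
            p = stats.ttest_ind(ga, gb, equal_var=False).pvalue
            rec[f"p_{a}_vs_{b}"] = float(min(len(pairs) * p, 1.0))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("feature")
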
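"""Subject-aware classification of fluid-accumulation status.

Five classifier families — cubic, quadratic and Gaussian-kernel SVMs
(C = 1; Gaussian kernel width gamma = 2.6), 1-nearest-neighbour and a
decision tree — are evaluated with leave-one-subject-out (LOSO)
cross-validation: every recording of a subject is held out together, so
a subject with recordings in two groups never straddles a fold.  Class
imbalance is compensated by uniform priors, implemented as class weights
inversely proportional to training-class frequency.  Features are
z-scored on each training fold.  ``subset_search`` evaluates every
non-empty subset of the 15 features (2^15 - 1 = 32767 evaluations) and
returns the most accurate, preferring smaller subsets on ties.
"""
from __future__ import annotations

import warnings
from itertools import combinations
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import (
    FEATURE_NAMES,
    CohortDataset,
    ConfusionMatrix,
    CVResult,
    InvalidInputError,
)

__all__ = [
    "CLASSIFIER_FAMILIES",
    "make_classifier",
    "loso_folds",
    "train_eval",
    "iter_feature_subsets",
    "subset_search",
    "confusion",
    "accuracy_from_confusion",
]

CLASSIFIER_FAMILIES = ("svm_cubic", "svm_quadratic", "svm_gaussian", "knn1", "tree")


def make_classifier(
    family: str,
    *,
    c: float = 1.0,
    gamma: float = 2.6,
    uniform_priors: bool = True,
    random_state: int = 0,
):
    """Instantiate one of the study's classifier families."""
    weight = "balanced" if uniform_priors else None
    if family == "svm_cubic":
        return SVC(kernel="poly", degree=3, C=c, gamma="scale", coef0=1.0,
                   class_weight=weight)
    if family == "svm_quadratic":
        return SVC(kernel="poly", degree=2, C=c, gamma="scale", coef0=1.0,
                   class_weight=weight)
    if family == "svm_gaussian":
        return SVC(kernel="rbf", C=c, gamma=gamma, class_weight=weight)
    if family == "knn1":
        return KNeighborsClassifier(n_neighbors=1)
    if family == "tree":
        return DecisionTreeClassifier(class_weight=weight, random_state=random_state)
    raise InvalidInputError(f"unknown classifier family {family!r}")


def loso_folds(dataset: CohortDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per distinct subject; returns (train_idx, test_idx) pairs.

    All recordings of the held-out subject are in the test side together;
    the test sides partition the dataset.
    """
    subjects = dataset.table["subject_id"].to_numpy()
    unique = pd.unique(subjects)
    if unique.size < 2:
        raise InvalidInputError("leave-one-subject-out requires >= 2 subjects")
    folds = []
    idx = np.arange(subjects.size)
    for s in unique:
        mask = subjects == s
        folds.append((idx[~mask], idx[mask]))
    return folds


def _eval_arrays(
    family: str,
    x_all: np.ndarray,
    y_all: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_classes: int,
    **clf_kwargs,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Core fold loop on raw arrays: per-fold z-scoring, fit, predict."""
    y_true_parts, y_pred_parts = [], []
    n_skipped = 0
    for train_idx, test_idx in folds:
        y_train = y_all[train_idx]
        if np.unique(y_train).size < n_classes:
            warnings.warn(
                "training fold missing a class; fold skipped", stacklevel=3
            )
            n_skipped += 1
            continue
        mu = x_all[train_idx].mean(axis=0)
        sd = x_all[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        clf = make_classifier(family, **clf_kwargs)
        clf.fit((x_all[train_idx] - mu) / sd, y_train)
        y_pred_parts.append(clf.predict((x_all[test_idx] - mu) / sd))
        y_true_parts.append(y_all[test_idx])
    if not y_true_parts:
        raise InvalidInputError("every fold was skipped; cannot evaluate")
    return np.concatenate(y_true_parts), np.concatenate(y_pred_parts), n_skipped


def train_eval(
    family: str,
    dataset: CohortDataset,
    features: Sequence[str],
    *,
    task: str = "two_class",
    c: float = 1.0,
    gamma: float = 2.6,
    uniform_priors: bool = True,
    random_state: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """LOSO-evaluate one classifier family on a feature subset.

    Per fold, features are standardized on the training recordings only;
    a fold whose training side is missing a class is skipped with a
    warning and excluded from the accuracy denominator.
    """
    features = tuple(features)
    if not features:
        raise InvalidInputError("feature subset must be non-empty")
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise InvalidInputError(f"unknown features: {sorted(unknown)}")
    x_all = dataset.table[list(features)].to_numpy(dtype=float)
    y_all = dataset.labels(task).to_numpy()
    classes = np.unique(y_all)
    if folds is None:
        folds = loso_folds(dataset)
    y_true, y_pred, n_skipped = _eval_arrays(
        family, x_all, y_all, folds, classes.size,
        c=c, gamma=gamma, uniform_priors=uniform_priors, random_state=random_state,
    )
    return CVResult(
        family=family,
        features=features,
        y_true=y_true,
        y_pred=y_pred,
        accuracy=float(np.mean(y_true == y_pred)),
        labels=tuple(classes),
        n_folds=len(folds),
        n_skipped_folds=n_skipped,
    )


def iter_feature_subsets(
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> Iterator[tuple[str, ...]]:
    """All non-empty feature subsets, smallest first, lexicographic within size."""
    names = list(feature_names)
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            yield combo


def subset_search(
    dataset: CohortDataset,
    family: str,
    *,
    task: str = "two_class",
    feature_names: Sequence[str] = FEATURE_NAMES,
    progress: Callable[[tuple[str, ...], float], None] | None = None,
    **eval_kwargs,
) -> CVResult:
    """Exhaustive feature-subset search maximizing LOSO accuracy.

    Ties are broken toward fewer features, then lexicographic feature
    order (the enumeration order of :func:`iter_feature_subsets`, which
    visits smaller subsets first).  ``progress`` is called with each
    (subset, accuracy) evaluated.
    """
    import sklearn

    folds = loso_folds(dataset)
    names = list(feature_names)
    col = {name: i for i, name in enumerate(names)}
    x_full = dataset.table[names].to_numpy(dtype=float)
    y_all = dataset.labels(task).to_numpy()
    classes = np.unique(y_all)
    clf_kwargs = {
        "c": eval_kwargs.pop("c", 1.0),
        "gamma": eval_kwargs.pop("gamma", 2.6),
        "uniform_priors": eval_kwargs.pop("uniform_priors", True),
        "random_state": eval_kwargs.pop("random_state", 0),
    }
    if eval_kwargs:
        raise TypeError(f"unexpected arguments: {sorted(eval_kwargs)}")

    best: CVResult | None = None
    with sklearn.config_context(assume_finite=True):
        for subset in iter_feature_subsets(names):
            cols = [col[f] for f in subset]
            y_true, y_pred, n_skipped = _eval_arrays(
                family, x_full[:, cols], y_all, folds, classes.size, **clf_kwargs
            )
            acc = float(np.mean(y_true == y_pred))
            if progress is not None:
                progress(subset, acc)
            if best is None or acc > best.accuracy:
                best = CVResult(
                    family=family,
                    features=subset,
                    y_true=y_true,
                    y_pred=y_pred,
                    accuracy=acc,
                    labels=tuple(classes),
                    n_folds=len(folds),
                    n_skipped_folds=n_skipped,
                )
    return best


def confusion(result: CVResult) -> ConfusionMatrix:
    """Row-percentage confusion matrix of a CV result (one decimal scale).

    Rows are actual classes, columns predicted; each non-empty row sums
    to 100.  A class with no recordings yields a NaN row (undefined, not
    zero).
    """
    labels = result.labels
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(result.y_true, result.y_pred):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    return ConfusionMatrix(labels=labels, row_counts=counts, row_percent=percent)


def accuracy_from_confusion(row_percent, class_sizes) -> float:
    """Overall accuracy implied by a row-percentage diagonal and class sizes.

    Per-class correct counts are recovered as round(diagonal% * n / 100)
    to the nearest integer; the result is total correct over total size.
    Accepts a full matrix or just its diagonal.
    """
    rp = np.asarray(row_percent, dtype=float)
    diag = np.diagonal(rp) if rp.ndim == 2 else rp
    sizes = np.asarray(class_sizes, dtype=float)
    if diag.shape != sizes.shape:
        raise InvalidInputError("diagonal and class_sizes must have equal length")
    if np.any((diag < 0) | (diag > 100)):
        raise InvalidInputError("percentages must lie in [0, 100]")
    if np.any(sizes <= 0):
        raise InvalidInputError("class sizes must be positive")
    correct = np.rint(diag * sizes / 100.0)
    if np.any(correct > sizes):
        raise InvalidInputError("rounded correct counts exceed class sizes")
    return float(correct.sum() / sizes.sum())
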
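"""Traditional-ML evaluation protocol: mid-scale label binarization, five fully
balanced subsets, grid-searched SVM/random-forest/KNN with leakage-free
standardization, analytic dummy classifiers, and paired t-tests over
subset-level results.

Protocol: the raw label distribution is unbalanced (mid-scale threshold on a
1-9 scale), so five balanced subsets are drawn, each keeping every
minority-class row plus an equal-size random sample of majority rows.  Within
each subset a stratified 5-fold cross-validation realises the 80/20
train/test split; hyperparameters are chosen by an inner grid search on the
80% only.  The reported value is the mean over the five subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InvalidParameterError
from .features import ECG_FEATURES, EDA_FEATURES, RSP_FEATURES, ALL_FEATURES

__all__ = [
    "MODALITY_COLUMNS", "BalancedSubset", "EvalResult",
    "binarize", "make_balanced_subsets", "run_ml",
    "dummy_classifiers", "paired_t_test",
]

MODALITY_COLUMNS = {
    "ecg": list(ECG_FEATURES),
    "eda": list(EDA_FEATURES),
    "rsp": list(RSP_FEATURES),
    "fusion": list(ALL_FEATURES),
}


@dataclass
class BalancedSubset:
    subset_id: int
    indices: np.ndarray
    class_counts: tuple

    def __post_init__(self) -> None:
        if self.class_counts[0] != self.class_counts[1]:
            raise InvalidParameterError("balanced subset must have equal class counts")


@dataclass
class EvalResult:
    """Accuracy / macro-F1 summary with the per-subset and per-fold raw values."""

    classifier: str
    modality: str
    accuracy_mean: float
    accuracy_sd: float
    f1_mean: float
    f1_sd: float
    subset_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))
    subset_f1s: np.ndarray = field(default_factory=lambda: np.array([]))
    fold_accuracies: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy_mean <= 1.0 and 0.0 <= self.f1_mean <= 1.0):
            raise InvalidParameterError("accuracy and F1 must lie in [0, 1]")
        if self.accuracy_sd < 0 or self.f1_sd < 0:
            raise InvalidParameterError("standard deviations must be >= 0")


def binarize(scores, threshold: int = 5) -> np.ndarray:
    """Two-class labels from 1-9 self-report scores: score <= threshold -> 0 (low).

    The mid-scale convention (<= 5 is "low") is a documented choice; pass a
    different threshold to move the split.
    """
    s = np.asarray(scores)
    if np.any((s < 1) | (s > 9)):
        raise InvalidParameterError("scores must lie in 1-9")
    return (s > threshold).astype(int)


def make_balanced_subsets(labels, n_subsets: int = 5, seed: int = 0) -> list[BalancedSubset]:
    """Five fully balanced subsets sized by the minority class.

    Each subset contains all minority rows plus an independent random sample
    (without replacement) of the same number of majority rows; subsets differ
    only in the majority sample.  If the classes are already balanced, every
    subset is the full dataset.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateDataError("both classes must be present to balance")
    minority = classes[np.argmin(counts)]
    n_min = int(counts.min())
    if n_min < 2:
        raise DegenerateDataError(f"minority class has {n_min} rows; need >= 2")
    if n_min < 10:
        warnings.warn(f"minority class has only {n_min} rows; results will be unstable")
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    rng = np.random.default_rng(seed)
    subsets = []
    for sid in range(1, n_subsets + 1):
        sample = rng.choice(maj_idx, size=n_min, replace=False)
        idx = np.sort(np.concatenate([min_idx, sample]))
        subsets.append(BalancedSubset(sid, idx, (n_min, n_min)))
    return subsets


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def _make_search(classifier: str, seed: int):
    from sklearn.model_selection import GridSearchCV
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.ensemble import RandomForestClassifier

    if classifier == "svm":
        est = SVC(kernel="rbf", random_state=seed)
        grid = {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.01]}
    elif classifier == "rfc":
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
        grid = {"clf__n_estimators": [100], "clf__max_depth": [None, 5]}
    elif classifier == "knn":
        est = KNeighborsClassifier()
        grid = {"clf__n_neighbors": [3, 5, 9]}
    else:
        raise InvalidParameterError(f"unknown classifier {classifier!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return GridSearchCV(pipe, grid, cv=3, scoring="accuracy", n_jobs=1)


def modality_matrix(features_table: pd.DataFrame, modality: str) -> np.ndarray:
    cols = MODALITY_COLUMNS[modality]
    return features_table[cols].to_numpy(dtype=float)


def run_ml(features_table: pd.DataFrame, labels, classifier: str = "svm",
           modality: str = "fusion", seed: int = 0, n_subsets: int = 5,
           n_folds: int = 5, groups=None) -> EvalResult:
    """Balanced-subset cross-validated evaluation of one classifier x modality.

    Standardization and the hyperparameter grid search are fitted on each
    fold's training 80% only.  Rows with non-finite features are dropped (the
    count is reported in a warning).

    ``groups`` (e.g. subject ids) switches to group-disjoint folds: the same
    subject never appears in both train and test.  Trial-level folds let a
    model score above chance on permuted labels by memorising subjects, so
    permutation nulls should always pass ``groups``.
    """
    from sklearn.metrics import accuracy_score, f1_score
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    X = modality_matrix(features_table, modality)
    y = np.asarray(labels)
    groups = None if groups is None else np.asarray(groups)
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} rows with non-finite features")
        X, y = X[finite], y[finite]
        if groups is not None:
            groups = groups[finite]

    subsets = make_balanced_subsets(y, n_subsets=n_subsets, seed=seed)
    subset_accs, subset_f1s, fold_accs = [], [], []
    for sub in subsets:
        Xs, ys = X[sub.indices], y[sub.indices]
        if groups is None:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed + sub.subset_id)
            splits = skf.split(Xs, ys)
        else:
            skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                       random_state=seed + sub.subset_id)
            splits = skf.split(Xs, ys, groups[sub.indices])
        accs, f1s = [], []
        for train, test in splits:
            search = _make_search(classifier, seed)
            search.fit(Xs[train], ys[train])
            pred = search.predict(Xs[test])
            accs.append(accuracy_score(ys[test], pred))
            f1s.append(f1_score(ys[test], pred, average="macro"))
        subset_accs.append(float(np.mean(accs)))
        subset_f1s.append(float(np.mean(f1s)))
        fold_accs.append(accs)
    subset_accs = np.asarray(subset_accs)
    subset_f1s = np.asarray(subset_f1s)
    return EvalResult(
        classifier=classifier, modality=modality,
        accuracy_mean=float(np.mean(subset_accs)), accuracy_sd=float(np.std(subset_accs)),
        f1_mean=float(np.mean(subset_f1s)), f1_sd=float(np.std(subset_f1s)),
        subset_accuracies=subset_accs, subset_f1s=subset_f1s, fold_accuracies=fold_accs,
    )


def dummy_classifiers(labels_train, labels_test, seed: int = 0) -> tuple[EvalResult, EvalResult]:
    """Random and majority reference classifiers.

    On any balanced binary test set the majority classifier scores exactly 0.5
    accuracy and 1/3 macro F1 (one class gets precision 0.5 / recall 1 ->
    F1 = 2/3; the other 0; the macro mean is 1/3).
    """
    from sklearn.metrics import accuracy_score, f1_score

    y_tr = np.asarray(labels_train)
    y_te = np.asarray(labels_test)
    rng = np.random.default_rng(seed)

    pred_rand = rng.integers(0, 2, size=len(y_te))
    classes, counts = np.unique(y_tr, return_counts=True)
    maj = int(classes[np.argmax(counts)])
    pred_maj = np.full(len(y_te), maj)

    def build(name, pred):
        return EvalResult(
            classifier=name, modality="none",
            accuracy_mean=float(accuracy_score(y_te, pred)), accuracy_sd=0.0,
            f1_mean=float(f1_score(y_te, pred, average="macro", zero_division=0)),
            f1_sd=0.0,
        )

    return build("random", pred_rand), build("majority", pred_maj)


def paired_t_test(fold_values_a, fold_values_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched fold/subset result vectors.

    Zero-variance differences are handled explicitly: all-zero differences
    give (0.0, 1.0); a constant nonzero shift gives (signed inf, 0.0).
    """
    a = np.asarray(fold_values_a, dtype=float)
    b = np.asarray(fold_values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidParameterError("need two equal-length 1-D vectors with n >= 2")
    diff = a - b
    if np.std(diff) == 0.0:
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
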
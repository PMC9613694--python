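"""Evaluation harness: stratified splits, baseline features, classifier search.

The default protocol mirrors the transform's intended use: fit the law bank on
the training instances, transform the *test* instances, then score classifiers
by stratified fivefold cross-validation on the transformed test features (the
training set never enters the classifier).  A conventional
``protocol="holdout"`` mode — fit classifiers on transformed training-like
features and score on a holdout — is available but is not the reference
protocol of this package.

Each classifier family (ensemble of trees, k-nearest neighbours, decision
tree, support-vector machine) is tuned by a randomized hyperparameter search
with a budget of exactly 30 candidate evaluations, each scored by stratified
fivefold CV accuracy.  The ensemble family splits its budget 15/15 between
bagged (random-forest) and boosted (gradient-boosting) trees and keeps the
better of the two searches.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DataError, ParameterError
from .panel import LabeledPanel

__all__ = [
    "SplitSpec",
    "BenchmarkResult",
    "stratified_split",
    "arem_paper_split",
    "AREM_TEST_LISTS",
    "baseline_features",
    "run_classifiers",
    "CLASSIFIER_FAMILIES",
]

#: the printed per-activity test-session lists of the 88-instance activity
#: recognition dataset (1-based within-class session numbers)
AREM_TEST_LISTS = {
    "bending1": (2, 3, 4, 6),
    "bending2": (2, 3, 5),
    "cycling": (1, 2, 5, 7, 9, 10, 14, 15),
    "lying": (1, 2, 6, 9, 11, 12, 14, 15),
    "sitting": (4, 7, 8, 9, 10, 11, 12, 15),
    "standing": (2, 3, 6, 7, 8, 12, 13, 14),
    "walking": (1, 3, 4, 7, 8, 9, 11, 13),
}

#: class order used by the mimic preset: the five 15-session activities first,
#: then the 7- and 6-session bending activities
AREM_CLASS_ORDER = (
    "cycling",
    "lying",
    "sitting",
    "standing",
    "walking",
    "bending1",
    "bending2",
)

CLASSIFIER_FAMILIES = ("ensemble", "knn", "dt", "svm")


@dataclass(frozen=True)
class SplitSpec:
    """A train/test partition of instance indices (0-based, disjoint, covering)."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int | None = None
    test_fraction: float | None = None

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)


@dataclass
class BenchmarkResult:
    """Per-classifier outcome on one feature table.

    ``accuracy`` is the best CV accuracy in percent; ``confusion`` the
    ``c x c`` count matrix aggregated over the CV folds of the best model
    (rows = true class); timing is wall-clock seconds and is reported for
    information only.
    """

    classifier: str
    accuracy: float
    confusion: np.ndarray
    elapsed_seconds: float
    best_params: dict = field(default_factory=dict)


def stratified_split(panel: LabeledPanel, test_fraction: float, seed: int = 0) -> SplitSpec:
    """Class-stratified random split; per-class test counts round to nearest.

    Every class keeps at least one instance on each side, so classes are
    present in both sets.
    """
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must lie strictly between 0 and 1")
    labels = panel.labels
    for cls, count in panel.class_counts().items():
        if count < 2:
            raise DataError(f"class {cls} has fewer than 2 instances; cannot split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5BA7]))
    test: list[int] = []
    for cls in sorted(panel.class_counts()):
        members = np.flatnonzero(labels == cls)
        n_test = int(round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        test.extend(rng.choice(members, size=n_test, replace=False).tolist())
    test_sorted = tuple(sorted(test))
    train_sorted = tuple(i for i in range(panel.n_instances) if i not in set(test_sorted))
    return SplitSpec(
        train_indices=train_sorted,
        test_indices=test_sorted,
        seed=seed,
        test_fraction=test_fraction,
    )


def arem_paper_split(panel: LabeledPanel) -> SplitSpec:
    """The printed test-session lists as a fixed split of an 88-instance panel.

    Assumes instances are grouped by class in label order (as the mimic preset
    generates them) with 1-based session numbering inside each class; class
    ``q`` maps to ``AREM_CLASS_ORDER[q - 1]``.  Yields 47 test instances
    (8 + 8 + 8 + 8 + 8 + 4 + 3), a 53.4% test fraction.
    """
    counts = panel.class_counts()
    c = panel.n_classes
    if c != len(AREM_CLASS_ORDER):
        raise DataError(
            f"the fixed split needs {len(AREM_CLASS_ORDER)} classes, panel has {c}"
        )
    test: list[int] = []
    offset = 0
    for cls in range(1, c + 1):
        members = np.flatnonzero(panel.labels == cls)
        if not np.array_equal(members, np.arange(offset, offset + counts[cls])):
            raise DataError(
                "the fixed split requires instances grouped contiguously by class"
            )
        sessions = AREM_TEST_LISTS[AREM_CLASS_ORDER[cls - 1]]
        if max(sessions) > counts[cls]:
            raise DataError(
                f"class {cls} has {counts[cls]} instances but the printed list "
                f"references session {max(sessions)}"
            )
        test.extend(offset + s - 1 for s in sessions)
        offset += counts[cls]
    test_sorted = tuple(sorted(test))
    train_sorted = tuple(i for i in range(panel.n_instances) if i not in set(test_sorted))
    return SplitSpec(
        train_indices=train_sorted,
        test_indices=test_sorted,
        test_fraction=len(test_sorted) / panel.n_instances,
    )


def baseline_features(panel: LabeledPanel, indices=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw-feature baseline: per-channel mean and sample variance tables.

    Mirrors the LLT mean/variance pairing so the same classifier harness runs
    on both feature spaces.
    """
    if indices is None:
        indices = range(panel.n_instances)
    indices = list(indices)
    m = panel.n_channels
    rows_mean, rows_var, ids = [], [], []
    for i in indices:
        chans = panel.series[i]
        rows_mean.append([float(s.mean()) for s in chans])
        rows_var.append([float(s.var(ddof=1)) for s in chans])
        ids.append(panel.instance_ids[i])
    idx = pd.Index(ids, name="instance")
    cols_m = [f"mean_ch{j}" for j in range(1, m + 1)]
    cols_v = [f"var_ch{j}" for j in range(1, m + 1)]
    means = pd.DataFrame(rows_mean, index=idx, columns=cols_m)
    variances = pd.DataFrame(rows_var, index=idx, columns=cols_v)
    means["label"] = panel.labels[indices]
    variances["label"] = panel.labels[indices]
    return means, variances


def _search_spaces(seed: int, n_rows: int, n_folds: int):
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("clf", est)])
    # largest k that fits in a training fold
    k_max = max(2, min(21, (n_rows * (n_folds - 1)) // n_folds))
    return {
        "knn": [
            (
                scaled(KNeighborsClassifier()),
                {
                    "clf__n_neighbors": randint(1, k_max),
                    "clf__weights": ["uniform", "distance"],
                    "clf__p": [1, 2],
                },
                30,
            )
        ],
        "dt": [
            (
                DecisionTreeClassifier(random_state=seed),
                {
                    "max_depth": randint(1, 21),
                    "min_samples_leaf": randint(1, 11),
                    "criterion": ["gini", "entropy"],
                },
                30,
            )
        ],
        "svm": [
            (
                scaled(SVC(random_state=seed)),
                {
                    "clf__C": loguniform(1e-2, 1e3),
                    "clf__gamma": loguniform(1e-4, 1e1),
                    "clf__kernel": ["rbf", "linear"],
                },
                30,
            )
        ],
        "ensemble": [
            (
                RandomForestClassifier(random_state=seed),
                {
                    "n_estimators": randint(20, 201),
                    "max_depth": randint(2, 21),
                    "min_samples_leaf": randint(1, 6),
                },
                15,
            ),
            (
                GradientBoostingClassifier(random_state=seed),
                {
                    "n_estimators": randint(20, 201),
                    "learning_rate": loguniform(1e-2, 1.0),
                    "max_depth": randint(1, 6),
                },
                15,
            ),
        ],
    }


def _feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "label" not in features.columns:
        raise DataError("feature table must carry a 'label' column")
    y = features["label"].to_numpy()
    X = features.drop(columns="label").to_numpy(dtype=float)
    return X, y


def run_classifiers(
    features: pd.DataFrame,
    families=CLASSIFIER_FAMILIES,
    seed: int = 0,
    n_folds: int = 5,
) -> list[BenchmarkResult]:
    """Tune and score classifier families on one feature table.

    Each family gets a 30-candidate randomized hyperparameter search, every
    candidate scored by stratified ``n_folds``-fold CV accuracy on the given
    table.  Reports best CV accuracy (%), the fold-aggregated confusion
    matrix of the best model, elapsed seconds, and the chosen
    hyperparameters.  Fixed ``seed`` makes runs reproducible.
    """
    X, y = _feature_matrix(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("need at least 2 classes to classify")
    if X.shape[0] < 10:
        raise DataError("need at least 10 instances to cross-validate")
    spaces = _search_spaces(seed, X.shape[0], n_folds)
    results: list[BenchmarkResult] = []
    for family in families:
        if family not in spaces:
            raise ParameterError(
                f"unknown classifier family {family!r}; choose from {CLASSIFIER_FAMILIES}"
            )
        start = time.perf_counter()
        best_score, best_est, best_params = -np.inf, None, {}
        for sub, (estimator, space, n_iter) in enumerate(spaces[family]):
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            search = RandomizedSearchCV(
                estimator,
                space,
                n_iter=n_iter,
                cv=cv,
                scoring="accuracy",
                random_state=seed + sub,
                n_jobs=1,
                refit=False,
            )
            search.fit(X, y)
            if search.best_score_ > best_score:
                best_score = search.best_score_
                best_params = dict(search.best_params_)
                best_est = clone(estimator).set_params(**search.best_params_)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        y_pred = cross_val_predict(best_est, X, y, cv=cv, n_jobs=1)
        conf = confusion_matrix(y, y_pred, labels=classes)
        elapsed = time.perf_counter() - start
        # accuracy reported from the pooled confusion matrix so that
        # accuracy == 100 * trace / total holds exactly
        results.append(
            BenchmarkResult(
                classifier=family,
                accuracy=100.0 * float(np.trace(conf)) / float(conf.sum()),
                confusion=conf,
                elapsed_seconds=elapsed,
                best_params=best_params,
            )
        )
    return results
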
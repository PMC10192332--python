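"""External validation by supervised label transfer.

Meta-cluster assignments become class labels: four classifiers (naive
Bayes, gradient boosting, random forest, logistic regression) are trained
on a stratified 80:20 split of the original cohort's clustering features,
scored on the held-out test set (macro one-vs-rest AUROC, macro precision /
recall / F1), and the AUROC-best model — refit on the full original cohort —
assigns clusters to an external cohort.

The external cohort is preprocessed with the ORIGINAL cohort's fitted
parameters (sparse-filter decisions, one-hot vocabulary, imputation
medians, z-score scaling); when it lacks some features, the model is refit
on the feature intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB

from .cohort import Cohort
from .preprocess import ClusteringMatrix, Preprocessor

logger = logging.getLogger(__name__)

TRAIN_FRACTION = 0.8
CLASSIFIER_ORDER = ("naive_bayes", "gradient_boosting", "random_forest", "logistic_regression")


def _make_classifier(name: str, seed: int):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_estimators=200)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise KeyError(f"unknown classifier {name!r}")


@dataclass
class ClassifierMetrics:
    auroc: float
    precision: float
    recall: float
    f1: float


@dataclass
class TransferReport:
    metrics: dict[str, ClassifierMetrics]
    selected_model: str
    feature_set: list[str] = field(default_factory=list)
    external_labels: np.ndarray | None = None


def train_and_evaluate(
    matrix: ClusteringMatrix | np.ndarray,
    meta_labels: np.ndarray,
    split: float = TRAIN_FRACTION,
    seed: int = 0,
    classifiers: tuple[str, ...] = CLASSIFIER_ORDER,
) -> TransferReport:
    """Fit the classifier panel on a stratified train split, score on test.

    AUROC is macro-averaged one-vs-rest; precision/recall/F1 are macro.
    Deterministic given ``seed``.
    """
    X = matrix.matrix if isinstance(matrix, ClusteringMatrix) else np.asarray(matrix)
    y = np.asarray(meta_labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two meta-clusters to learn labels")
    counts = np.bincount(np.searchsorted(classes, y))
    if counts.min() < 2:
        raise ValueError("a cluster is too small for a stratified split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y
    )
    metrics: dict[str, ClassifierMetrics] = {}
    for name in classifiers:
        clf = _make_classifier(name, seed)
        clf.fit(X_tr, y_tr)
        proba = clf.predict_proba(X_te)
        pred = clf.predict(X_te)
        if len(classes) == 2:
            auroc = roc_auc_score(y_te, proba[:, 1])
        else:
            auroc = roc_auc_score(y_te, proba, multi_class="ovr", average="macro")
        metrics[name] = ClassifierMetrics(
            auroc=float(auroc),
            precision=float(precision_score(y_te, pred, average="macro", zero_division=0)),
            recall=float(recall_score(y_te, pred, average="macro", zero_division=0)),
            f1=float(f1_score(y_te, pred, average="macro", zero_division=0)),
        )
    report = TransferReport(
        metrics=metrics,
        selected_model=select_best(metrics, order=classifiers),
        feature_set=list(matrix.feature_names)
        if isinstance(matrix, ClusteringMatrix)
        else [],
    )
    return report


def select_best(
    metrics: dict[str, ClassifierMetrics], order: tuple[str, ...] = CLASSIFIER_ORDER
) -> str:
    """AUROC argmax; exact ties broken by panel order."""
    if not metrics:
        raise ValueError("no classifier metrics to select from")
    names = [n for n in order if n in metrics]
    best = names[0]
    for n in names[1:]:
        if metrics[n].auroc > metrics[best].auroc:
            best = n
    return best


def assign_external(
    preprocessor: Preprocessor,
    original_cohort: Cohort,
    meta_labels: np.ndarray,
    external_cohort: Cohort,
    model_name: str,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Assign meta-cluster labels to an external cohort.

    Both cohorts are transformed with parameters fitted on the original
    cohort only. The selected model is refit on 100% of the original cohort
    restricted to the expanded-feature intersection, then predicts the
    external patients. Returns (labels, features used).
    """
    Xo = preprocessor.transform(original_cohort)
    Xe = preprocessor.transform(external_cohort)
    common = [f for f in Xo.feature_names if f in set(Xe.feature_names)]
    if not common:
        raise ValueError("no shared features between cohorts after preprocessing")
    if len(common) < len(Xo.feature_names):
        logger.info(
            "external cohort lacks %d expanded features; refitting on intersection",
            len(Xo.feature_names) - len(common),
        )
    io = [Xo.feature_names.index(f) for f in common]
    ie = [Xe.feature_names.index(f) for f in common]
    clf = _make_classifier(model_name, seed)
    clf.fit(Xo.matrix[:, io], np.asarray(meta_labels))
    return clf.predict(Xe.matrix[:, ie]), common
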
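"""Classifier benchmarking: repeated CV, ROC/AUC, nested-subset curves and
the fixed-split repeatability protocol.

Four classifier families are compared, mirroring common EEG practice:
RBF-kernel SVM, a C4.5-style entropy decision tree, a single-hidden-layer
MLP ("BP" network, hidden size 2*d+1) and LDA.  Every evaluation
standardizes features inside the training fold only (sklearn Pipeline), so
no test-fold statistics leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIERS = ("svm", "c45", "mlp", "lda")


class EvalError(ValueError):
    pass


@dataclass
class EvalProtocol:
    """Evaluation scheme settings.

    scheme="kfold": stratified k-fold repeated until ``total_folds`` fold
    evaluations (default 10-fold x 10 repeats = 100).
    scheme="fixed-split": ``repeats`` random draws of ``test_per_emotion``
    test trials per emotion, rest train (the repeatability protocol).
    """

    scheme: str = "kfold"
    k: int = 10
    total_folds: int = 100
    repeats: int = 10
    test_per_emotion: int = 8
    seed: int = 0
    train_fraction: float | None = None  # literal 10%-train reading, optional


@dataclass
class EvalReport:
    """Accumulated per-condition results."""

    entries: list = field(default_factory=list)

    def add(self, **kwargs):
        self.entries.append(kwargs)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def make_classifier(name: str, n_features: int, seed: int = 0) -> Pipeline:
    """Classifier wrapped with a train-fold-only standardizer."""
    if name == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif name == "c45":
        clf = DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, ccp_alpha=0.002,
            random_state=seed,
        )
    elif name == "mlp":
        # no early stopping: with ~70 training trials a held-out validation
        # slice starves the fit
        clf = MLPClassifier(
            hidden_layer_sizes=(2 * n_features + 1,), max_iter=800,
            random_state=seed,
        )
    elif name == "lda":
        clf = LinearDiscriminantAnalysis()
    else:
        raise EvalError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def crossval_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "c45",
    protocol: EvalProtocol | None = None,
) -> dict:
    """Mean accuracy (%) over repeated stratified fold evaluations.

    Returns {"mean_accuracy": %, "per_fold": array of %}.
    """
    protocol = protocol or EvalProtocol()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise EvalError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise EvalError("need at least 2 classes")
    accs = []
    if protocol.train_fraction is not None:
        splitter = StratifiedShuffleSplit(
            n_splits=protocol.total_folds,
            train_size=protocol.train_fraction,
            random_state=protocol.seed,
        )
        split_iter = splitter.split(X, y)
    else:
        n_repeats = int(np.ceil(protocol.total_folds / protocol.k))
        splitter = RepeatedStratifiedKFold(
            n_splits=protocol.k, n_repeats=n_repeats, random_state=protocol.seed
        )
        split_iter = splitter.split(X, y)
    for fold, (tr, te) in enumerate(split_iter):
        if fold >= protocol.total_folds:
            break
        model = make_classifier(classifier, X.shape[1], seed=protocol.seed + fold)
        model.fit(X[tr], y[tr])
        accs.append(100.0 * float(np.mean(model.predict(X[te]) == y[te])))
    accs = np.array(accs)
    return {"mean_accuracy": float(accs.mean()), "per_fold": accs}


def nested_subset_curve(
    ranking,
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "c45",
    protocol: EvalProtocol | None = None,
    sizes=(2, 5, 10, 15, 20, 25, 27),
    plateau_points: float = 3.0,
) -> dict:
    """Accuracy against nested CFS-prefix subset size.

    ``ranking`` is a FeatureRanking over 1-based feature ids matching the
    columns of ``features``.  The plateau size is the smallest evaluated
    size whose accuracy is within ``plateau_points`` of the maximum.
    """
    X = np.asarray(features, dtype=float)
    p = X.shape[1]
    sizes = [s for s in sizes if s <= p]
    curve = {}
    for s in sizes:
        cols = sorted(fid - 1 for fid in ranking.top(s))  # order-free subsets
        res = crossval_accuracy(X[:, cols], labels, classifier, protocol)
        curve[s] = res["mean_accuracy"]
    best = max(curve.values())
    plateau = next(s for s in sizes if curve[s] >= best - plateau_points)
    return {"sizes": sizes, "accuracy": curve, "plateau_size": plateau}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """One-vs-rest ROC points per class and macro AUC.

    ``scores``: (n, n_classes) continuous scores (probabilities or decision
    values), columns ordered by sorted class value.
    """
    y = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise EvalError("ROC needs at least 2 classes")
    per_class = {}
    aucs = []
    for i, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), scores[:, i])
        a = auc(fpr, tpr)
        per_class[c] = {"fpr": fpr, "tpr": tpr, "auc": float(a)}
        aucs.append(a)
    return {"per_class": per_class, "macro_auc": float(np.mean(aucs))}


def classifier_scores(
    features: np.ndarray, labels: np.ndarray, classifier: str = "lda",
    protocol: EvalProtocol | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out per-class scores via one stratified shuffle split (for ROC)."""
    protocol = protocol or EvalProtocol()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.3, random_state=protocol.seed)
    tr, te = next(splitter.split(X, y))
    model = make_classifier(classifier, X.shape[1], seed=protocol.seed)
    if classifier == "svm":
        model.set_params(clf__probability=True)
    model.fit(X[tr], y[tr])
    clf = model
    if hasattr(clf, "predict_proba"):
        s = clf.predict_proba(X[te])
    else:
        s = clf.decision_function(X[te])
    return s, y[te]


def repeatability_run(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "c45",
    repeats: int = 10,
    test_per_emotion: int = 8,
    seed: int = 0,
) -> dict:
    """Fixed-split repeatability protocol on one dataset/electrode.

    Each repeat draws ``test_per_emotion`` test trials per emotion (8 of 20
    by default, so 32 test / 72 training trials per dataset) and reports the
    per-repeat accuracy plus the average.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts <= test_per_emotion):
        raise EvalError(
            f"each class needs more than {test_per_emotion} trials "
            f"(got {dict(zip(classes, counts))})"
        )
    rng = np.random.default_rng(seed)
    accs = []
    for rep in range(repeats):
        test_idx = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            test_idx.extend(rng.choice(idx, size=test_per_emotion, replace=False))
        test_idx = np.array(sorted(test_idx))
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = make_classifier(classifier, X.shape[1], seed=seed + rep)
        model.fit(X[train_mask], y[train_mask])
        accs.append(100.0 * float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    accs = np.array(accs)
    return {"per_repeat": accs, "average": float(accs.mean())}
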
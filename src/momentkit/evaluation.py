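"""Cross-validated descriptor benchmark.

Protocol: stratified 10-fold cross-validation; per fold, feature z-scoring
and grid-search hyperparameter selection (inner stratified 3-fold CV) are
fit on the training fold only; the held-out fold is scored with the
support-weighted per-class one-vs-rest accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_TAGS",
    "DEFAULT_CATEGORIES",
    "default_grid",
    "stratified_kfold",
    "normalize_fit_apply",
    "make_classifier",
    "grid_search",
    "weighted_accuracy",
    "EvaluationResult",
    "run_benchmark",
    "aggregate_by_category",
]

CLASSIFIER_TAGS = ("SVM", "kNN", "DT", "NB", "BT")

#: descriptor -> category, mirroring the benchmark's grouping
DEFAULT_CATEGORIES = {
    "LM": "CM", "CHM": "CM", "CH2M": "CM",
    "ZM": "JM", "PZM": "JM", "OFMM": "JM", "CHFM": "JM", "PJFM": "JM",
    "JFM": "JM", "FrJFM": "JM",
    "BFM": "BM",
    "RHFM": "HM", "EFM": "HM", "PCET": "HM", "PCT": "HM", "PST": "HM",
    "FrRHFM": "HM", "FrPCET": "HM", "FrPCT": "HM", "FrPST": "HM",
    "HARri": "TF", "LBPri": "TF",
}


def default_grid(tag: str) -> List[dict]:
    """Small, reproducible hyperparameter grids, in tie-break order."""
    if tag == "SVM":
        grid = [{"kernel": "linear", "C": c} for c in (0.1, 1.0, 10.0, 100.0)]
        grid += [
            {"kernel": "rbf", "C": c, "gamma_mult": g}
            for c in (0.1, 1.0, 10.0, 100.0)
            for g in (0.1, 1.0, 10.0)
        ]
        return grid
    if tag == "kNN":
        return [
            {"n_neighbors": k, "metric": metric}
            for k in (1, 3, 5, 7, 9)
            for metric in ("euclidean", "cityblock")
        ]
    if tag == "DT":
        return [
            {"max_depth": d, "min_samples_leaf": leaf}
            for d in (3, 5, 10, None)
            for leaf in (1, 3, 5)
        ]
    if tag == "NB":
        return [{"var_smoothing": v} for v in (1e-9, 1e-6)]
    if tag == "BT":
        return [{"n_estimators": n} for n in (50, 100, 200)]
    raise ValueError(f"unknown classifier tag {tag!r}")


def stratified_kfold(labels: Sequence, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Each class's samples are shuffled with the seed and dealt round-robin to
    folds (with a rotating starting fold across classes), so per-fold class
    counts differ from the ideal stratification by at most one sample and a
    class with ``c < k`` members lands in exactly ``c`` distinct test folds.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 1):  # pragma: no cover - unique() guarantees this
        raise ValueError("every class needs at least one sample")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        folds[idx] = (offset + np.arange(idx.size)) % k
        offset = (offset + idx.size) % k
    return folds


def normalize_fit_apply(train: np.ndarray, other: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scoring fit on the training rows only.

    Zero-variance features are centered but not scaled.
    """
    train = np.asarray(train, dtype=float)
    other = np.asarray(other, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (train - mean) / std, (other - mean) / std


def make_classifier(tag: str, params: dict, seed: int, X_train: Optional[np.ndarray] = None):
    """Instantiate a classifier from its tag and a grid point."""
    params = dict(params)
    if tag == "SVM":
        gamma_mult = params.pop("gamma_mult", None)
        gamma = "scale"
        if gamma_mult is not None and X_train is not None:
            var = X_train.var()
            gamma = gamma_mult / (X_train.shape[1] * var) if var > 0 else "scale"
        elif gamma_mult is not None:
            gamma = "scale"
        return SVC(gamma=gamma, random_state=seed, **params)
    if tag == "kNN":
        return KNeighborsClassifier(**params)
    if tag == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if tag == "NB":
        return GaussianNB(**params)
    if tag == "BT":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **params,
        )
    raise ValueError(f"unknown classifier tag {tag!r}")


def weighted_accuracy(confusion: np.ndarray, class_weights: Optional[np.ndarray] = None) -> float:
    """Support-weighted mean of per-class one-vs-rest accuracies.

    For each class the confusion matrix is collapsed to one-vs-rest counts
    and ``(TP + TN) / (TP + FP + TN + FN)`` computed; the values are averaged
    with ``class_weights`` (default: class support shares).
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one sample")
    support = C.sum(axis=1)
    if class_weights is None:
        class_weights = support / total
    class_weights = np.asarray(class_weights, dtype=float)
    accs = np.empty(C.shape[0])
    for c in range(C.shape[0]):
        tp = C[c, c]
        fn = support[c] - tp
        fp = C[:, c].sum() - tp
        tn = total - tp - fn - fp
        accs[c] = (tp + tn) / total
    return float(np.sum(class_weights * accs) / np.sum(class_weights))


def _score_fit(tag, params, seed, Xtr, ytr, Xte, yte, classes) -> float:
    if tag == "kNN" and params.get("n_neighbors", 1) > Xtr.shape[0]:
        return 0.0  # degenerate grid point on a fold smaller than k
    clf = make_classifier(tag, params, seed, X_train=Xtr)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    conf = confusion_matrix(yte, pred, labels=classes)
    return weighted_accuracy(conf)


def grid_search(
    tag: str,
    grid: List[dict],
    train_features: np.ndarray,
    train_labels: np.ndarray,
    seed: int,
    inner_k: int = 3,
) -> dict:
    """Pick the grid point maximizing inner-CV weighted accuracy.

    Inner stratified ``inner_k``-fold CV on the training data; ties broken by
    first occurrence in the grid enumeration order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if len(grid) == 1:
        return dict(grid[0])
    folds = stratified_kfold(y, min(inner_k, X.shape[0]), seed)
    best_score, best_params = -np.inf, None
    for params in grid:
        scores = []
        for f in range(folds.max() + 1):
            tr, te = folds != f, folds == f
            if te.sum() == 0 or len(np.unique(y[tr])) < 2:
                continue
            Xtr, Xte = normalize_fit_apply(X[tr], X[te])
            scores.append(_score_fit(tag, params, seed, Xtr, y[tr], Xte, y[te], classes))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    return dict(best_params)


@dataclass
class EvaluationResult:
    """Per (descriptor, classifier) accuracies with fold-level detail."""

    fold_accuracies: Dict[Tuple[str, str], List[float]]
    chosen_params: Dict[Tuple[str, str], List[dict]]
    k: int
    seed: int

    def mean_accuracy(self, descriptor: str, classifier: str) -> float:
        return float(np.mean(self.fold_accuracies[(descriptor, classifier)]))

    @property
    def descriptors(self) -> List[str]:
        seen = []
        for d, _ in self.fold_accuracies:
            if d not in seen:
                seen.append(d)
        return seen

    @property
    def classifiers(self) -> List[str]:
        seen = []
        for _, c in self.fold_accuracies:
            if c not in seen:
                seen.append(c)
        return seen

    def to_frame(self) -> pd.DataFrame:
        """Results table: rows = descriptors, columns = classifiers + AVG."""
        rows = {}
        for d in self.descriptors:
            rows[d] = {c: self.mean_accuracy(d, c) for c in self.classifiers}
            rows[d]["AVG"] = float(np.mean(list(rows[d].values())))
        return pd.DataFrame.from_dict(rows, orient="index")


def run_benchmark(
    features: Dict[str, np.ndarray],
    labels: Sequence,
    classifiers: Sequence[str] = CLASSIFIER_TAGS,
    k: int = 10,
    seed: int = 42,
    grids: Optional[Dict[str, List[dict]]] = None,
) -> EvaluationResult:
    """Run the full benchmark over pre-extracted feature matrices.

    ``features`` maps descriptor name to an ``(n_samples, n_features)``
    matrix.  Deterministic given the seed (for deterministic classifiers).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for tag in classifiers:
        if tag not in CLASSIFIER_TAGS:
            raise ValueError(f"unknown classifier tag {tag!r}")
    fold_acc: Dict[Tuple[str, str], List[float]] = {}
    chosen: Dict[Tuple[str, str], List[dict]] = {}
    folds = stratified_kfold(y, k, seed)
    for name, X in features.items():
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError(f"feature matrix {name!r} row count != label count")
        for tag in classifiers:
            grid = (grids or {}).get(tag, default_grid(tag))
            accs, params_per_fold = [], []
            for f in range(k):
                tr, te = folds != f, folds == f
                if te.sum() == 0:
                    continue
                Xtr, Xte = normalize_fit_apply(X[tr], X[te])
                params = grid_search(tag, grid, X[tr], y[tr], seed)
                accs.append(_score_fit(tag, params, seed, Xtr, y[tr], Xte, y[te], classes))
                params_per_fold.append(params)
            fold_acc[(name, tag)] = accs
            chosen[(name, tag)] = params_per_fold
    return EvaluationResult(fold_accuracies=fold_acc, chosen_params=chosen, k=k, seed=seed)


def aggregate_by_category(
    means: Dict[str, float],
    category_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Aggregate per-descriptor mean accuracies by category.

    Returns mean, population standard deviation, min and max per category
    (single-member categories have std 0).
    """
    category_map = category_map or DEFAULT_CATEGORIES
    groups: Dict[str, List[float]] = {}
    for name, acc in means.items():
        if name not in category_map:
            raise ValueError(f"descriptor {name!r} has no category mapping")
        groups.setdefault(category_map[name], []).append(acc)
    rows = {
        cat: {
            "mean": float(np.mean(v)),
            "std": float(np.std(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": len(v),
        }
        for cat, v in groups.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
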
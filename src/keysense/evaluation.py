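"""Cross-validated recognition harness: confusion-matrix metrics,
stratified k-fold evaluation of the key-feature pipeline, and the
PCA / information-gain / mRMR comparator selectors.

Per class c on a confusion matrix with true classes on rows:
TP = diagonal(c), FN = row(c) - TP, FP = column(c) - TP;
precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2*precision*recall/(precision+recall), with the 0/0 convention -> 0;
accuracy = trace/total; macro metrics are unweighted class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from keysense.instances import FeatureMatrix
from keysense.pkfs import SelectionConfig, fit_scaler, rescale, select_key_features
from keysense.skfs import augment

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "metrics_from_confusion",
    "make_classifier",
    "kfold_evaluate",
    "baseline_select",
    "BaselineSelector",
]

#: Number of equal-frequency bins used to discretize continuous columns
#: for the mutual-information selectors (IG, mRMR).
MI_BINS = 5


@dataclass
class ConfusionMatrix:
    """Square count table; rows are true classes, columns predicted."""

    class_names: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Fold-wise and pooled confusion matrices with derived metrics."""

    fold_confusions: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    metrics: dict
    config: dict = field(default_factory=dict)


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """Per-class precision / recall / F, macro averages, and accuracy."""
    counts = cm.counts
    if counts.size == 0 or cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp

    def safe_div(a, b):
        return np.divide(a, b, out=np.zeros_like(a, dtype=float), where=b > 0)

    precision = safe_div(tp, tp + fp)
    recall = safe_div(tp, tp + fn)
    f = safe_div(2 * precision * recall, precision + recall)
    per_class = {
        name: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f": float(f[i]),
        }
        for i, name in enumerate(cm.class_names)
    }
    return {
        "per_class": per_class,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f": float(f.mean()),
        "accuracy": float(tp.sum() / cm.total),
    }


def make_classifier(spec: str, seed: int = 0):
    """Classifier roster; settings map the intent of the study design
    (1-NN unweighted, C4.5-like tree, polynomial-kernel SVM with C=1 and
    tol 1e-3, Gaussian NB, default forest)."""
    if spec == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=1)
    if spec == "svm":
        return SVC(kernel="poly", C=1.0, tol=1e-3, random_state=seed)
    if spec == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if spec == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier spec {spec!r}")


# ---------------------------------------------------------------------------
# comparator selectors


def _discretize(col: np.ndarray, bins: int = MI_BINS) -> np.ndarray:
    """Equal-frequency binning for mutual-information estimation."""
    if np.unique(col).size <= bins:
        # already effectively discrete; use the values themselves
        _, inv = np.unique(col, return_inverse=True)
        return inv
    edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(col, edges)


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    return float(mutual_info_score(a, b))


class BaselineSelector:
    """PCA / information-gain / mRMR reducer, fitted on training rows only.

    ``m`` (for ig / mrmr) is the number of features to keep; callers pass
    the PKFS union size for a like-for-like comparison.  ``variance`` is
    the PCA explained-variance fraction to retain (default 0.95).
    """

    def __init__(self, method: str, m: int | None = None, variance: float = 0.95):
        if method not in ("pca", "ig", "mrmr"):
            raise ValueError(f"unknown baseline method {method!r}")
        if method == "pca" and not 0 < variance <= 1:
            raise ValueError("pca variance retained must be in (0, 1]")
        self.method = method
        self.m = m
        self.variance = variance
        self._pca: PCA | None = None
        self.selected_: list[str] | None = None

    def fit(self, matrix: FeatureMatrix, target: np.ndarray) -> "BaselineSelector":
        X = matrix.data.to_numpy(dtype=float)
        names = matrix.feature_names
        if self.method == "pca":
            # mean-centering caps the rank at n-1
            n_comp = self.variance if self.variance < 1 else min(X.shape[0] - 1, X.shape[1])
            self._pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
            return self
        m = self.m if self.m is not None else min(10, len(names))
        if m > len(names):
            raise ValueError(f"m={m} exceeds feature count {len(names)}")
        _, y = np.unique(target, return_inverse=True)
        binned = [_discretize(X[:, j]) for j in range(X.shape[1])]
        relevance = np.array([_mi(b, y) for b in binned])
        if self.method == "ig":
            order = np.lexsort((np.arange(len(names)), -relevance))
            self.selected_ = [names[j] for j in order[:m]]
            return self
        # mRMR: greedy mutual-information-difference criterion
        chosen: list[int] = [int(np.argmax(relevance))]
        while len(chosen) < m:
            best_j, best_score = None, -np.inf
            for j in range(len(names)):
                if j in chosen:
                    continue
                redundancy = np.mean([_mi(binned[j], binned[s]) for s in chosen])
                score = relevance[j] - redundancy
                if score > best_score + 1e-12:
                    best_j, best_score = j, score
            chosen.append(best_j)
        self.selected_ = [names[j] for j in sorted(chosen)]
        return self

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if self.method == "pca":
            Z = self._pca.transform(matrix.data.to_numpy(dtype=float))
            cols = [f"pc{i + 1}" for i in range(Z.shape[1])]
            return matrix.with_data(pd.DataFrame(Z, columns=cols))
        return matrix.with_data(matrix.data[self.selected_].copy())


def baseline_select(
    matrix: FeatureMatrix,
    method: str,
    m: int | None = None,
    variance: float = 0.95,
    fit_rows: Sequence[int] | None = None,
    target: np.ndarray | None = None,
) -> FeatureMatrix:
    """One-shot comparator reduction of a feature matrix.

    Fits on ``fit_rows`` (default: all rows) against ``target`` (default:
    the matrix's class labels) and transforms the whole matrix.
    """
    sel = BaselineSelector(method, m=m, variance=variance)
    fit_fm = matrix if fit_rows is None else matrix.take_rows(fit_rows)
    y = fit_fm.class_labels if target is None else np.asarray(target)[
        fit_rows if fit_rows is not None else slice(None)
    ]
    sel.fit(fit_fm, y)
    return sel.transform(matrix)


# ---------------------------------------------------------------------------
# cross-validated evaluation


def _normalize_selector(spec: Union[str, Mapping, None]) -> dict:
    if spec is None:
        return {"method": "none"}
    if isinstance(spec, str):
        return {"method": spec}
    return dict(spec)


def _fold_transform(
    train: FeatureMatrix,
    test: FeatureMatrix,
    spec: dict,
    target: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the selector pipeline on the training fold only, then
    transform both folds.  For the key-feature pipeline, selection
    precedence is computed on raw training counts, rescaling is fitted
    on the training fold, and the statistics run on rescaled values."""
    method = spec.get("method", "xai-har")
    scaler = fit_scaler(train)
    train_sc, test_sc = rescale(train, scaler), rescale(test, scaler)
    if method == "none":
        return train_sc.data.to_numpy(float), test_sc.data.to_numpy(float)
    if method == "xai-har":
        config = spec.get("config") or SelectionConfig(
            u_f=spec.get("u_f", 7), u_i=spec.get("u_i", 2)
        )
        selection = select_key_features(train, config)
        if len(selection.union_set) < 2:
            raise ValueError(
                "key-feature union too small for statistical augmentation; "
                "relax u_i or raise u_f"
            )
        tr = augment(train_sc, selection)
        te = augment(test_sc, selection)
        return tr.data.to_numpy(float), te.data.to_numpy(float)
    if method in ("pca", "ig", "mrmr"):
        sel = BaselineSelector(
            method,
            m=spec.get("m"),
            variance=spec.get("variance", 0.95),
        ).fit(train_sc, target)
        return (
            sel.transform(train_sc).data.to_numpy(float),
            sel.transform(test_sc).data.to_numpy(float),
        )
    raise ValueError(f"unknown selector method {method!r}")


def kfold_evaluate(
    matrix: FeatureMatrix,
    selector_spec: Union[str, Mapping, None] = "xai-har",
    classifier_spec: str = "rf",
    k: int = 3,
    seed: int = 0,
    task: str = "activity",
) -> EvaluationReport:
    """Stratified k-fold evaluation of selector + classifier.

    ``task='activity'`` targets the activity class labels;
    ``task='cohort'`` targets the healthy/dementia cohort labels
    (binary mode).  Scaler and selector are fitted on training rows
    only; the pooled confusion matrix sums the fold matrices, so its
    total equals the instance count.
    """
    if task == "activity":
        y = matrix.class_labels
    elif task == "cohort":
        y = matrix.cohorts
    else:
        raise ValueError(f"unknown task {task!r}")
    names, y_idx = np.unique(y, return_inverse=True)
    class_names = names.tolist()
    smallest = np.bincount(y_idx).min()
    if smallest < k:
        raise ValueError(
            f"smallest class has {smallest} instances < k={k}; use a smaller k"
        )
    spec = _normalize_selector(selector_spec)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[ConfusionMatrix] = []
    pooled = np.zeros((len(class_names), len(class_names)), dtype=int)
    for train_idx, test_idx in skf.split(matrix.data, y_idx):
        train, test = matrix.take_rows(train_idx), matrix.take_rows(test_idx)
        Xtr, Xte = _fold_transform(train, test, spec, y_idx[train_idx])
        clf = make_classifier(classifier_spec, seed=seed)
        clf.fit(Xtr, y_idx[train_idx])
        pred = clf.predict(Xte)
        cm = np.zeros_like(pooled)
        np.add.at(cm, (y_idx[test_idx], pred), 1)
        folds.append(ConfusionMatrix(class_names, cm))
        pooled += cm
    pooled_cm = ConfusionMatrix(class_names, pooled)
    return EvaluationReport(
        fold_confusions=folds,
        pooled=pooled_cm,
        metrics=metrics_from_confusion(pooled_cm),
        config={
            "selector": spec,
            "classifier": classifier_spec,
            "k": k,
            "seed": seed,
            "task": task,
        },
    )
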
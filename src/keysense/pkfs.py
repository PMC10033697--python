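"""Physical key feature selection (PKFS).

Per activity class, features are ranked by *precedence* — the feature's
total occurrence frequency summed over the class's instances — subject
to an instance-support floor: a feature must be non-zero in at least
``U_i`` of the class's instances to be a candidate, and at most ``U_f``
features are kept per class.  The per-class selections are concatenated
in canonical class order into a deduplicated union set; downstream
stages operate on that union.

Precedence is computed on the raw (pre-rescaling) matrix: rescaling is a
per-feature affine map fitted for the classifiers' benefit and would
distort between-feature frequency comparisons.  Min-max rescaling
(fit on training rows only, clamped to [0, 1] on held-out rows) is
provided here because it is part of the same pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from keysense.instances import FeatureMatrix

__all__ = [
    "ScalerParams",
    "SelectionConfig",
    "SelectionResult",
    "fit_scaler",
    "rescale",
    "feature_support",
    "select_class_features",
    "select_key_features",
    "tune_thresholds",
]


@dataclass
class ScalerParams:
    """Per-feature min / max learned on training rows."""

    minimum: pd.Series
    maximum: pd.Series

    def __post_init__(self) -> None:
        if (self.maximum < self.minimum).any():
            raise ValueError("per-feature max must be >= min")


@dataclass(frozen=True)
class SelectionConfig:
    """User-facing PKFS thresholds.

    u_f
        Maximum number of features nominated per class (>= 1).
    u_i
        Minimum number of the class's instances in which a candidate
        feature must be strictly positive (>= 0).
    """

    u_f: int
    u_i: int = 0

    def __post_init__(self) -> None:
        if self.u_f < 1:
            raise ValueError("u_f must be >= 1")
        if self.u_i < 0:
            raise ValueError("u_i must be >= 0")


@dataclass
class SelectionResult:
    """Per-class selections plus their order-preserving deduplicated union."""

    per_class: dict[Hashable, list[tuple[str, float]]]
    union_set: list[str] = field(default_factory=list)
    config: SelectionConfig | None = None

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "union_set": self.union_set,
            "config": None
            if self.config is None
            else {"u_f": self.config.u_f, "u_i": self.config.u_i},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        cfg = d.get("config")
        return cls(
            per_class={k: [tuple(p) for p in v] for k, v in d["per_class"].items()},
            union_set=list(d["union_set"]),
            config=None if cfg is None else SelectionConfig(cfg["u_f"], cfg["u_i"]),
        )


def fit_scaler(matrix: FeatureMatrix, rows: Sequence[int] | None = None) -> ScalerParams:
    """Learn per-feature min / max over the designated (training) rows."""
    if rows is None:
        rows = np.arange(matrix.n_rows)
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("cannot fit a scaler on an empty row set")
    sub = matrix.data.iloc[rows]
    return ScalerParams(minimum=sub.min(axis=0), maximum=sub.max(axis=0))


def rescale(matrix: FeatureMatrix, params: ScalerParams) -> FeatureMatrix:
    """Min-max rescale every feature to [0, 1], clamping values outside
    the fitted range; zero-range (constant) features map to 0 everywhere."""
    missing = [c for c in matrix.feature_names if c not in params.minimum.index]
    if missing:
        raise ValueError(f"scaler params missing features: {missing}")
    lo = params.minimum[matrix.feature_names]
    span = (params.maximum[matrix.feature_names] - lo).replace(0.0, np.nan)
    scaled = ((matrix.data - lo) / span).fillna(0.0).clip(0.0, 1.0)
    return matrix.with_data(scaled)


def _class_rows(matrix: FeatureMatrix, class_label: Hashable) -> np.ndarray:
    mask = matrix.class_labels == class_label
    if not mask.any():
        raise ValueError(f"unknown class label {class_label!r}")
    return mask


def feature_support(matrix: FeatureMatrix, class_label: Hashable) -> dict[str, int]:
    """Number of the class's instances in which each feature is strictly
    positive."""
    mask = _class_rows(matrix, class_label)
    counts = (matrix.data.loc[mask] > 0).sum(axis=0)
    return {name: int(c) for name, c in counts.items()}


def select_class_features(
    matrix: FeatureMatrix,
    class_label: Hashable,
    config: SelectionConfig,
) -> list[tuple[str, float]]:
    """Top-``u_f`` features for one class by descending precedence.

    Candidates are the features non-zero in at least ``u_i`` of the
    class's instances; precedence is the feature's total frequency over
    those instances (sum of raw values).  Ties break on canonical
    (column) order.  Fewer than ``u_f`` pairs are returned when
    candidates are scarce.
    """
    mask = _class_rows(matrix, class_label)
    sub = matrix.data.loc[mask]
    support = (sub > 0).sum(axis=0)
    precedence = sub.sum(axis=0)
    order = [
        (name, float(precedence[name]))
        for name in matrix.feature_names
        if support[name] >= config.u_i and support[name] > 0
    ]
    order.sort(key=lambda t: -t[1])  # stable: ties keep canonical order
    return order[: config.u_f]


def select_key_features(
    matrix: FeatureMatrix, config: SelectionConfig
) -> SelectionResult:
    """Run the per-class selection over every class (sorted label order)
    and merge into the deduplicated union key-feature set.

    A feature already contributed by an earlier class is discarded from
    the union (set semantics); union membership is independent of the
    class iteration order, only the union's ordering reflects it.
    """
    labels = sorted(set(matrix.class_labels.tolist()))
    if not labels:
        raise ValueError("matrix has no class labels")
    per_class: dict[Hashable, list[tuple[str, float]]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for label in labels:
        chosen = select_class_features(matrix, label, config)
        per_class[label] = chosen
        for name, _ in chosen:
            if name not in seen:
                seen.add(name)
                union.append(name)
    return SelectionResult(per_class=per_class, union_set=union, config=config)


def tune_thresholds(
    matrix: FeatureMatrix,
    grid: Sequence[SelectionConfig],
    k: int = 3,
    classifier_spec: str = "rf",
    seed: int = 0,
):
    """Grid-search ``u_f`` / ``u_i`` by k-fold cross-validated macro F.

    For every config the full pipeline (scaler and selection fitted on
    training folds, statistical augmentation, classifier) is evaluated
    under stratified k-fold CV; the config maximizing the mean fold-wise
    macro F-score wins, ties to smaller ``u_f`` then larger ``u_i``.

    Returns ``(best_config, table)`` where ``table`` is a DataFrame with
    columns ``u_f, u_i, macro_f``.
    """
    from keysense.evaluation import kfold_evaluate, metrics_from_confusion

    if not grid:
        raise ValueError("grid must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    records = []
    for cfg in grid:
        report = kfold_evaluate(
            matrix,
            selector_spec={"method": "xai-har", "config": cfg},
            classifier_spec=classifier_spec,
            k=k,
            seed=seed,
        )
        fold_f = [
            metrics_from_confusion(cm)["macro_f"] for cm in report.fold_confusions
        ]
        records.append({"u_f": cfg.u_f, "u_i": cfg.u_i, "macro_f": float(np.mean(fold_f))})
    table = pd.DataFrame.from_records(records)
    best_i = min(
        range(len(records)),
        key=lambda i: (-records[i]["macro_f"], records[i]["u_f"], -records[i]["u_i"]),
    )
    best = SelectionConfig(int(records[best_i]["u_f"]), int(records[best_i]["u_i"]))
    return best, table
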
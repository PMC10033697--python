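"""Local and global explanation reports for a trained recognizer.

The local report approximates the model around one instance with a
seeded perturbation surrogate: Gaussian perturbations of the feature
vector, weighted by an exponential distance kernel, fitted with a ridge
regression against the model's probability for the predicted class
(one-vs-rest in the multiclass case).  Positive weights support the
predicted class.  The global report is seeded permutation importance:
the mean drop in model score when one feature's column is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge

from keysense.instances import FeatureMatrix

__all__ = ["Explanation", "local_explanation", "global_importance"]


@dataclass
class Explanation:
    """Local explanation of one prediction.

    ``top_features`` is sorted by absolute weight, descending, at most k
    entries; ``supported_class`` gives, per listed feature, the class its
    sign supports (the predicted class for positive weights, the
    alternative for negative ones).
    """

    instance_id: str
    class_probabilities: dict
    top_features: list[tuple[str, float]]
    supported_class: dict = field(default_factory=dict)


def _predict_proba(model, X: np.ndarray) -> tuple[np.ndarray, list]:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X), list(model.classes_)
    pred = model.predict(X)
    classes = list(getattr(model, "classes_", np.unique(pred)))
    proba = np.zeros((len(X), len(classes)))
    for i, p in enumerate(pred):
        proba[i, classes.index(p)] = 1.0
    return proba, classes


def local_explanation(
    model,
    instance,
    k: int = 10,
    n_samples: int = 1000,
    seed: int = 0,
    feature_names: list[str] | None = None,
    scale: float = 0.25,
) -> Explanation:
    """Perturbation-based local surrogate explanation of one instance.

    Parameters
    ----------
    model
        Trained classifier exposing ``predict`` (and ideally
        ``predict_proba``) over the same feature vector.
    instance
        One feature row (pandas Series with feature names in its index,
        or a plain 1-D array with ``feature_names`` given).
    k
        Maximum number of features to report.
    n_samples
        Perturbation sample count; more samples → more stable weights.
    scale
        Gaussian perturbation standard deviation, in feature units
        (the pipeline's features live on [0, 1] after rescaling).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(instance, pd.Series):
        names = list(instance.index)
        x0 = instance.to_numpy(dtype=float)
    else:
        x0 = np.asarray(instance, dtype=float)
        names = feature_names or [f"x{i}" for i in range(len(x0))]
    if len(names) != len(x0):
        raise ValueError("feature_names length must match the instance")
    n_expected = getattr(model, "n_features_in_", len(x0))
    if n_expected != len(x0):
        raise ValueError(
            f"model expects {n_expected} features, instance has {len(x0)}"
        )
    model_names = getattr(model, "feature_names_in_", None)
    if model_names is not None and list(model_names) != names:
        raise ValueError("feature names do not match the model's training names")

    rng = np.random.default_rng(seed)
    X = x0 + rng.normal(0.0, scale, size=(n_samples, len(x0)))
    X[0] = x0  # anchor the surrogate at the instance itself

    proba, classes = _predict_proba(model, X)
    p0, _ = _predict_proba(model, x0.reshape(1, -1))
    predicted = classes[int(np.argmax(p0[0]))]
    target = proba[:, classes.index(predicted)]

    dist = np.linalg.norm(X - x0, axis=1)
    width = np.sqrt(len(x0)) * scale * 0.75
    weights = np.exp(-((dist / width) ** 2))
    surrogate = Ridge(alpha=1.0)
    surrogate.fit(X - x0, target, sample_weight=weights)

    coefs = surrogate.coef_
    order = np.argsort(-np.abs(coefs))[:k]
    top = [(names[j], float(coefs[j])) for j in order]
    if len(classes) == 2:
        alternative = [c for c in classes if c != predicted][0]
        alt_name = str(alternative)
    else:
        alt_name = f"not {predicted}"
    supported = {
        name: (str(predicted) if w >= 0 else alt_name) for name, w in top
    }
    return Explanation(
        instance_id="row",
        class_probabilities={str(c): float(p) for c, p in zip(classes, p0[0])},
        top_features=top,
        supported_class=supported,
    )


def global_importance(
    model,
    matrix: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    n_repeats: int = 10,
    target: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Seeded permutation importance, top-k features by mean score drop.

    ``target`` defaults to the matrix's activity class labels; pass
    ``matrix.cohorts`` for the binary cohort model.  If ``k`` exceeds
    the feature count, all features are returned.
    """
    y = matrix.class_labels if target is None else np.asarray(target)
    n_expected = getattr(model, "n_features_in_", len(matrix.feature_names))
    if n_expected != len(matrix.feature_names):
        raise ValueError(
            f"model expects {n_expected} features, matrix has "
            f"{len(matrix.feature_names)}"
        )
    result = permutation_importance(
        model,
        matrix.data.to_numpy(dtype=float),
        y,
        n_repeats=n_repeats,
        random_state=seed,
    )
    order = np.argsort(-result.importances_mean)[:k]
    return [(matrix.feature_names[j], float(result.importances_mean[j])) for j in order]
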
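"""Confusion-matrix metrics, the cross-validated harness, and the
PCA / information-gain / mRMR comparator selectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keysense.datasets import casas_activity_confusion
from keysense.evaluation import (
    BaselineSelector,
    ConfusionMatrix,
    baseline_select,
    kfold_evaluate,
    metrics_from_confusion,
)
from keysense.pkfs import SelectionConfig
from tests.conftest import random_feature_matrix


# --- metrics ---------------------------------------------------------------


def test_reference_confusion_kitchen_and_soup_f():
    m = metrics_from_confusion(casas_activity_confusion())
    assert round(m["per_class"]["Kit"]["f"], 2) == 0.96
    assert round(m["per_class"]["Soup"]["f"], 2) == 0.98
    assert round(m["macro_f"], 2) == 0.96


def test_perfect_diagonal_gives_ones():
    cm = ConfusionMatrix(["a", "b", "c"], np.diag([5, 3, 2]))
    m = metrics_from_confusion(cm)
    assert m["accuracy"] == 1.0
    for stats in m["per_class"].values():
        assert stats == {"precision": 1.0, "recall": 1.0, "f": 1.0}


def test_never_predicted_class_zero_convention():
    cm = ConfusionMatrix(["a", "b"], np.array([[4, 0], [2, 0]]))
    m = metrics_from_confusion(cm)
    assert m["per_class"]["b"] == {"precision": 0.0, "recall": 0.0, "f": 0.0}


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        metrics_from_confusion(ConfusionMatrix(["a"], np.array([[0]])))


def random_confusion(rng, k):
    return ConfusionMatrix(
        [f"c{i}" for i in range(k)], rng.integers(0, 20, size=(k, k)) + np.eye(k, dtype=int)
    )


@given(seed=st.integers(0, 2**32 - 1), k=st.integers(2, 6))
@settings(max_examples=100, derandomize=True)
def test_micro_f_equals_accuracy(seed, k):
    """Pooled TP/FP/FN micro-F equals accuracy for single-label multiclass."""
    cm = random_confusion(np.random.default_rng(seed), k)
    counts = cm.counts
    tp = np.diag(counts).sum()
    fp = (counts.sum(axis=0) - np.diag(counts)).sum()
    fn = (counts.sum(axis=1) - np.diag(counts)).sum()
    micro_p = tp / (tp + fp)
    micro_r = tp / (tp + fn)
    micro_f = 2 * micro_p * micro_r / (micro_p + micro_r)
    assert micro_f == pytest.approx(metrics_from_confusion(cm)["accuracy"])


@given(seed=st.integers(0, 2**32 - 1), k=st.integers(2, 6))
@settings(max_examples=100, derandomize=True)
def test_f_invariant_under_transpose(seed, k):
    """Transposing swaps precision and recall; F is unchanged."""
    cm = random_confusion(np.random.default_rng(seed), k)
    m = metrics_from_confusion(cm)
    mt = metrics_from_confusion(ConfusionMatrix(cm.class_names, cm.counts.T))
    for name in cm.class_names:
        assert m["per_class"][name]["f"] == pytest.approx(mt["per_class"][name]["f"])
        assert m["per_class"][name]["precision"] == pytest.approx(
            mt["per_class"][name]["recall"]
        )
    assert m["macro_f"] == pytest.approx(mt["macro_f"])


# --- k-fold harness --------------------------------------------------------


def test_kfold_deterministic_under_seed(small_dataset):
    fm, _ = small_dataset
    spec = {"method": "xai-har", "config": SelectionConfig(4, 1)}
    r1 = kfold_evaluate(fm, spec, "rf", k=3, seed=9)
    r2 = kfold_evaluate(fm, spec, "rf", k=3, seed=9)
    assert np.array_equal(r1.pooled.counts, r2.pooled.counts)
    assert r1.metrics == r2.metrics


def test_pooled_matrix_conserves_instances(small_dataset):
    fm, _ = small_dataset
    rep = kfold_evaluate(fm, "none", "dt", k=3, seed=0)
    assert rep.pooled.total == fm.n_rows
    summed = sum(cm.counts for cm in rep.fold_confusions)
    assert np.array_equal(summed, rep.pooled.counts)


def test_stratified_fold_sizes_balanced(small_dataset):
    fm, _ = small_dataset
    rep = kfold_evaluate(fm, "none", "dt", k=3, seed=0)
    per_fold_class_totals = np.array([cm.counts.sum(axis=1) for cm in rep.fold_confusions])
    spread = per_fold_class_totals.max(axis=0) - per_fold_class_totals.min(axis=0)
    assert (spread <= 1).all()


def test_class_smaller_than_k_rejected(small_dataset):
    fm, _ = small_dataset
    with pytest.raises(ValueError, match="smaller k"):
        kfold_evaluate(fm, "none", "dt", k=99, seed=0)


def test_unknown_specs_rejected(small_dataset):
    fm, _ = small_dataset
    with pytest.raises(ValueError, match="classifier"):
        kfold_evaluate(fm, "none", "xgboost", k=3, seed=0)
    with pytest.raises(ValueError, match="selector"):
        kfold_evaluate(fm, "nope", "dt", k=3, seed=0)


def test_cohort_task_targets_cohort_labels(small_dataset):
    fm, _ = small_dataset
    rep = kfold_evaluate(fm, "none", "rf", k=3, seed=0, task="cohort")
    assert rep.pooled.class_names == ["dementia", "healthy"]


# --- comparator selectors --------------------------------------------------


def test_pca_full_variance_rank_bound():
    rng = np.random.default_rng(0)
    fm = random_feature_matrix(rng, 8, 5, 2)
    fm = fm.with_data(fm.data + rng.normal(0, 0.01, fm.data.shape))  # full rank
    out = baseline_select(fm, "pca", variance=1.0)
    assert len(out.feature_names) == min(fm.n_rows - 1, 5)


def test_pca_default_variance_reduces_dimension(small_dataset):
    fm, _ = small_dataset
    out = baseline_select(fm, "pca")
    assert len(out.feature_names) < len(fm.feature_names)


def test_ig_ranks_label_copy_first():
    rng = np.random.default_rng(1)
    fm = random_feature_matrix(rng, 30, 4, 3)
    fm.data["f0"] = fm.class_labels.astype(float)  # identical to the label
    sel = BaselineSelector("ig", m=2).fit(fm, fm.class_labels)
    assert sel.selected_[0] == "f0"


def naive_greedy_mrmr(binned, y, m):
    """Independent oracle: greedy mutual-information-difference."""
    from sklearn.metrics import mutual_info_score

    rel = [mutual_info_score(b, y) for b in binned]
    chosen = [int(np.argmax(rel))]
    while len(chosen) < m:
        best, best_s = None, -np.inf
        for j in range(len(binned)):
            if j in chosen:
                continue
            red = np.mean([mutual_info_score(binned[j], binned[s]) for s in chosen])
            s = rel[j] - red
            if s > best_s + 1e-12:
                best, best_s = j, s
        chosen.append(best)
    return set(chosen)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_mrmr_matches_greedy_oracle(seed):
    from keysense.evaluation import _discretize

    rng = np.random.default_rng(seed)
    fm = random_feature_matrix(rng, 25, 6, 3)
    sel = BaselineSelector("mrmr", m=3).fit(fm, fm.class_labels)
    X = fm.data.to_numpy(float)
    binned = [_discretize(X[:, j]) for j in range(6)]
    _, y = np.unique(fm.class_labels, return_inverse=True)
    expected = {fm.feature_names[j] for j in naive_greedy_mrmr(binned, y, 3)}
    assert set(sel.selected_) == expected


def test_baseline_m_exceeding_features_rejected(toy_matrix):
    with pytest.raises(ValueError, match="exceeds"):
        baseline_select(toy_matrix, "ig", m=99)
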
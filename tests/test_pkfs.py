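"""Physical key feature selection: rescaling, support, precedence
ranking against a brute-force oracle, union semantics, and threshold
tuning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keysense.instances import FeatureMatrix
from keysense.pkfs import (
    SelectionConfig,
    feature_support,
    fit_scaler,
    rescale,
    select_class_features,
    select_key_features,
    tune_thresholds,
)
from tests.conftest import random_feature_matrix


# --- rescaling -------------------------------------------------------------


def one_col_matrix(values):
    return FeatureMatrix(
        data=pd.DataFrame({"f": values}, dtype=float),
        class_labels=np.zeros(len(values), dtype=int),
        cohorts=np.array(["healthy"] * len(values)),
        participant_ids=np.array([f"p{i}" for i in range(len(values))]),
    )


def test_scaler_min_max():
    params = fit_scaler(one_col_matrix([0, 5, 10]))
    assert params.minimum["f"] == 0 and params.maximum["f"] == 10


def test_scaler_constant_and_single_row():
    p = fit_scaler(one_col_matrix([3, 3, 3]))
    assert p.minimum["f"] == p.maximum["f"] == 3
    p1 = fit_scaler(one_col_matrix([7, 8]), rows=[1])
    assert p1.minimum["f"] == p1.maximum["f"] == 8


def test_scaler_empty_rows_error():
    with pytest.raises(ValueError):
        fit_scaler(one_col_matrix([1, 2]), rows=[])


def test_rescale_maps_to_unit_interval():
    m = one_col_matrix([0, 5, 10])
    out = rescale(m, fit_scaler(m))
    assert out.data["f"].tolist() == [0.0, 0.5, 1.0]


def test_rescale_constant_column_maps_to_zero():
    m = one_col_matrix([3, 3, 3])
    assert rescale(m, fit_scaler(m)).data["f"].tolist() == [0.0, 0.0, 0.0]


def test_rescale_clamps_out_of_range_test_values():
    train = one_col_matrix([0, 10])
    test = one_col_matrix([12, -3])
    out = rescale(test, fit_scaler(train))
    assert out.data["f"].tolist() == [1.0, 0.0]


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, derandomize=True)
def test_rescaled_nonconstant_features_attain_zero_and_one(seed):
    rng = np.random.default_rng(seed)
    fm = random_feature_matrix(rng, 8, 4, 2)
    out = rescale(fm, fit_scaler(fm))
    assert ((out.data >= 0) & (out.data <= 1)).all().all()
    for c in out.feature_names:
        if fm.data[c].nunique() > 1:
            assert out.data[c].min() == 0.0 and out.data[c].max() == 1.0


# --- support & selection ---------------------------------------------------


def test_feature_support_counts_positive_rows(toy_matrix):
    support = feature_support(toy_matrix, 1)
    assert support == {"f1": 2, "f2": 2, "f3": 0, "f4": 1}
    with pytest.raises(ValueError, match="unknown class"):
        feature_support(toy_matrix, 99)


def test_support_bounded_by_class_size(toy_matrix):
    for label in (1, 2, 3):
        n = int((toy_matrix.class_labels == label).sum())
        assert all(s <= n for s in feature_support(toy_matrix, label).values())


def test_select_ranks_by_total_frequency(toy_matrix):
    # class 1 totals: f1=10, f2=4, f3=0, f4=1; supports 2,2,0,1
    chosen = select_class_features(toy_matrix, 1, SelectionConfig(u_f=2, u_i=1))
    assert chosen == [("f1", 10.0), ("f2", 4.0)]


def test_ui_above_class_size_gives_empty_list(toy_matrix):
    assert select_class_features(toy_matrix, 1, SelectionConfig(u_f=3, u_i=5)) == []


def brute_force_select(fm, label, config):
    """Exhaustive oracle: enumerate candidates and sort by the definition."""
    rows = [i for i in range(fm.n_rows) if fm.class_labels[i] == label]
    scored = []
    for rank, name in enumerate(fm.feature_names):
        col = [fm.data.iloc[i][name] for i in rows]
        support = sum(1 for v in col if v > 0)
        if support >= config.u_i and support >= 1:
            scored.append((-sum(col), rank, name))
    scored.sort()
    return [(name, -neg_total) for neg_total, _, name in scored[: config.u_f]]


@given(
    seed=st.integers(0, 2**32 - 1),
    n_rows=st.integers(3, 12),
    n_features=st.integers(1, 6),
    u_f=st.integers(1, 4),
    u_i=st.integers(0, 3),
)
@settings(max_examples=150, derandomize=True)
def test_selection_matches_brute_force_oracle(seed, n_rows, n_features, u_f, u_i):
    rng = np.random.default_rng(seed)
    fm = random_feature_matrix(rng, n_rows, n_features, 3)
    config = SelectionConfig(u_f=u_f, u_i=u_i)
    for label in sorted(set(fm.class_labels.tolist())):
        assert select_class_features(fm, label, config) == brute_force_select(
            fm, label, config
        )


@given(seed=st.integers(0, 2**32 - 1), u_f=st.integers(1, 5), u_i=st.integers(0, 3))
@settings(max_examples=60, derandomize=True)
def test_threshold_monotonicity(seed, u_f, u_i):
    """Raising u_i never grows a class's candidate set; raising u_f never
    shrinks its selection."""
    rng = np.random.default_rng(seed)
    fm = random_feature_matrix(rng, 10, 5, 2)
    uncapped = SelectionConfig(u_f=10, u_i=u_i)  # u_f >= feature count
    for label in sorted(set(fm.class_labels.tolist())):
        candidates = select_class_features(fm, label, uncapped)
        tighter = select_class_features(fm, label, SelectionConfig(u_f=10, u_i=u_i + 1))
        assert {n for n, _ in tighter} <= {n for n, _ in candidates}
        lo = select_class_features(fm, label, SelectionConfig(u_f=u_f, u_i=u_i))
        hi_uf = select_class_features(fm, label, SelectionConfig(u_f=u_f + 1, u_i=u_i))
        assert {n for n, _ in lo} <= {n for n, _ in hi_uf}


# --- union -----------------------------------------------------------------


def test_union_deduplicates_shared_features(toy_matrix):
    res = select_key_features(toy_matrix, SelectionConfig(u_f=2, u_i=1))
    assert len(res.union_set) == len(set(res.union_set))
    members = {n for chosen in res.per_class.values() for n, _ in chosen}
    assert set(res.union_set) == members


def test_noop_thresholds_keep_every_nonzero_feature(toy_matrix):
    res = select_key_features(toy_matrix, SelectionConfig(u_f=10, u_i=0))
    nonzero = {c for c in toy_matrix.feature_names if (toy_matrix.data[c] > 0).any()}
    assert set(res.union_set) == nonzero


def test_union_membership_order_independent(toy_matrix):
    res = select_key_features(toy_matrix, SelectionConfig(u_f=2, u_i=1))
    perm = np.array([8, 2, 5, 0, 7, 1, 4, 6, 3])
    res_perm = select_key_features(toy_matrix.take_rows(perm), SelectionConfig(2, 1))
    assert set(res.union_set) == set(res_perm.union_set)
    assert res.per_class.keys() == res_perm.per_class.keys()


def test_union_invariant_to_row_duplication_at_ui_zero(toy_matrix):
    res = select_key_features(toy_matrix, SelectionConfig(u_f=2, u_i=0))
    dup = toy_matrix.take_rows(list(range(9)) + [0])
    res_dup = select_key_features(dup, SelectionConfig(u_f=2, u_i=0))
    assert set(res.union_set) == set(res_dup.union_set)


def test_selection_uses_training_rows_only(small_dataset):
    """Perturbing held-out rows must not change a fold's fitted transform."""
    from keysense.evaluation import _fold_transform

    fm, _ = small_dataset
    train = fm.take_rows(np.arange(0, 30))
    test_a = fm.take_rows(np.arange(30, 40))
    test_b = test_a.with_data(test_a.data * 7.0 + 1.0)
    spec = {"method": "xai-har", "config": SelectionConfig(u_f=4, u_i=1)}
    y = train.class_labels
    tr_a, _ = _fold_transform(train, test_a, spec, y)
    tr_b, _ = _fold_transform(train, test_b, spec, y)
    assert np.array_equal(tr_a, tr_b)


# --- tuning ----------------------------------------------------------------


def test_tune_single_config_returned(small_dataset):
    fm, _ = small_dataset
    cfg = SelectionConfig(u_f=4, u_i=1)
    best, table = tune_thresholds(fm, [cfg], k=3, classifier_spec="dt", seed=0)
    assert best == cfg and len(table) == 1


def test_tune_deterministic_under_seed(small_dataset):
    fm, _ = small_dataset
    grid = [SelectionConfig(3, 1), SelectionConfig(5, 1)]
    b1, t1 = tune_thresholds(fm, grid, k=3, classifier_spec="dt", seed=11)
    b2, t2 = tune_thresholds(fm, grid, k=3, classifier_spec="dt", seed=11)
    assert b1 == b2
    pd.testing.assert_frame_equal(t1, t2)


def test_tune_recovers_planted_budget():
    """With 5 planted sensors per activity and no duration signal, the
    tuned u_f should land within a factor of 2 of 5."""
    from keysense.simulate import SimulationConfig, default_planted, make_cohort_dataset

    activities = (1, 2, 3, 4)
    cfg = SimulationConfig(
        n_healthy=10,
        n_dementia=3,
        activities=activities,
        planted=default_planted(activities=activities),
        duration_step_s=0.0,
        seed=5,
    )
    fm, _ = make_cohort_dataset(cfg)
    grid = [SelectionConfig(u, 1) for u in (2, 5, 7)]
    best, table = tune_thresholds(fm, grid, k=3, classifier_spec="rf", seed=5)
    assert 2.5 <= best.u_f <= 10
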
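"""Class weights, weighted loss, splits, training loop, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from dermaprep import classify
from dermaprep.classify import (
    AugmentConfig,
    EarlyStopper,
    LabeledDataset,
    TrainConfig,
    _epoch_lr,
    augment,
    compute_class_weights,
    evaluate,
    roc_auc,
    select_threshold,
    stratified_split,
    weighted_bce,
)


# --------------------------------------------------------- class weights
def test_study_composition_weights():
    """200 melanoma / 1000 non-melanoma gives weights 3.0 and 0.6."""
    spec = compute_class_weights({"MEL": 200, "NMSC": 1000})
    assert spec.w_c == {"MEL": 3.0, "NMSC": 0.6}
    assert spec.N == 1200 and spec.C == 2


def test_balanced_weights_are_unit():
    assert compute_class_weights({"A": 50, "B": 50}).w_c == {"A": 1.0, "B": 1.0}


def test_three_class_weights():
    w = compute_class_weights({"A": 100, "B": 150, "C": 50}).w_c
    assert w["A"] == pytest.approx(1.0)
    assert w["B"] == pytest.approx(2 / 3)
    assert w["C"] == pytest.approx(2.0)


def test_zero_count_rejected():
    with pytest.raises(ValueError):
        compute_class_weights({"A": 0, "B": 10})


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 5000), min_size=1, max_size=6))
def test_weight_conservation(counts):
    """sum_c w_c * n_c == N for any composition."""
    n_c = {i: c for i, c in enumerate(counts)}
    spec = compute_class_weights(n_c)
    assert sum(spec.w_c[k] * n_c[k] for k in n_c) == pytest.approx(spec.N)


# ----------------------------------------------------------- weighted BCE
def test_bce_perfect_predictions_near_zero():
    y = np.array([0, 1, 1, 0])
    assert weighted_bce(y, y.astype(float)) <= 1e-6


def test_bce_single_weighted_sample():
    # y=1, p=0.5, w1=3 -> 3 ln 2
    loss = weighted_bce([1], [0.5], {1: 3.0, 0: 0.6})
    assert loss == pytest.approx(3 * np.log(2), abs=1e-12)


def test_unit_weights_reduce_to_plain_bce():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 64)
    p = rng.uniform(0.01, 0.99, 64)
    plain = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    assert weighted_bce(y, p, {0: 1.0, 1: 1.0}) == pytest.approx(plain, abs=1e-12)
    assert weighted_bce(y, p, None) == pytest.approx(plain, abs=1e-12)


# ------------------------------------------------------------------ split
def _dummy_dataset(n_mel, n_nmsc):
    items = [(f"m{i}", 1) for i in range(n_mel)] + [
        (f"n{i}", 0) for i in range(n_nmsc)
    ]
    return LabeledDataset(items)


def test_split_arithmetic_on_study_composition():
    ds = _dummy_dataset(200, 1000)
    train, val, test = stratified_split(ds, (0.8, 0.1, 0.1), seed=42)
    assert train.class_counts() == {1: 160, 0: 800}
    assert val.class_counts() == {1: 20, 0: 100}
    assert test.class_counts() == {1: 20, 0: 100}
    # per-split ratios equal the global 1:5 ratio exactly
    for part in (train, val, test):
        c = part.class_counts()
        assert c[0] == 5 * c[1]


def test_split_deterministic_and_disjoint():
    ds = _dummy_dataset(30, 70)
    a = stratified_split(ds, seed=42)
    b = stratified_split(ds, seed=42)
    for pa, pb in zip(a, b):
        assert [r for r, _ in pa.items] == [r for r, _ in pb.items]
    refs = [r for part in a for r, _ in part.items]
    assert len(refs) == len(set(refs)) == len(ds)


def test_split_small_class_rejected():
    with pytest.raises(ValueError):
        stratified_split(_dummy_dataset(2, 50))


# ---------------------------------------------------------- augmentation
def test_augment_disabled_is_identity():
    cfg = AugmentConfig(
        rotation_deg=0.0, hflip=False, vflip=False,
        zoom_range=(1.0, 1.0), brightness_range=(1.0, 1.0),
    )
    img = np.random.default_rng(0).integers(0, 255, (32, 32, 3), dtype=np.uint8)
    assert (augment(img, cfg, seed=5) == img).all()


def test_augment_seed_determinism_and_dims():
    cfg = AugmentConfig()
    img = np.random.default_rng(1).integers(0, 255, (48, 48, 3), dtype=np.uint8)
    a = augment(img, cfg, seed=9)
    b = augment(img, cfg, seed=9)
    assert (a == b).all() and a.shape == img.shape


def test_augment_brightness_scale():
    cfg = AugmentConfig(
        rotation_deg=0.0, hflip=False, vflip=False,
        zoom_range=(1.0, 1.0), brightness_range=(1.2, 1.2),
    )
    img = np.full((16, 16, 3), 100, np.uint8)
    assert (augment(img, cfg, seed=0) == 120).all()


def test_zoom_rejects_nonpositive_factor():
    from dermaprep.classify import _zoom

    with pytest.raises(ValueError):
        _zoom(np.zeros((8, 8, 3), np.uint8), 0.0)


# -------------------------------------------------------------- training
def test_early_stopper_contract():
    """Scripted loss: no improvement for 5 epochs stops training there."""
    stopper = EarlyStopper(patience=5)
    losses = [1.0, 0.8, 0.9, 0.9, 0.9, 0.9, 0.9]
    stops = [stopper.update(l, e) for e, l in enumerate(losses, start=1)]
    assert stops == [False, False, False, False, False, False, True]
    assert stopper.best_epoch == 2


def test_lr_decay_schedule():
    cfg = TrainConfig(lr=1e-4)
    assert all(_epoch_lr(cfg, e) == 1e-4 for e in range(1, 11))
    assert all(_epoch_lr(cfg, e) == pytest.approx(9e-5) for e in range(11, 21))


def test_training_learns_separable_classes(trained_backbone):
    """On synthetic data separable by construction the reference CNN
    reaches >= 0.90 training accuracy and >= 0.9 test AUC."""
    backbone, history, (train, val, test) = trained_backbone
    assert max(history["train_acc"]) >= 0.90
    probs, _ = backbone.forward(backbone.prepare(test.images()))
    assert roc_auc(probs, test.labels) >= 0.9


def test_training_history_records_lr_decay(trained_backbone):
    _, history, _ = trained_backbone
    assert history["lr"][0] == pytest.approx(1e-2)
    if len(history["lr"]) > 10:
        assert history["lr"][10] == pytest.approx(9e-3)


def test_train_rejects_overlapping_splits(imbalanced_dataset):
    from dermaprep.backbone import TinyCNN

    dataset, _ = imbalanced_dataset
    small = LabeledDataset(dataset.items[:10])
    with pytest.raises(ValueError):
        classify.train_classifier(small, small, TinyCNN(seed=0), TrainConfig(epochs=1))


# --------------------------------------------------------------- metrics
def test_evaluate_perfect_separation():
    m = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
    assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)


def test_evaluate_hand_counts():
    scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05, 0.6]
    labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    m = evaluate(scores, labels, 0.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (3, 2, 4, 1)
    assert m.precision == pytest.approx(0.6)
    assert m.recall == pytest.approx(0.75)


def test_counts_to_metrics_arithmetic():
    # tp=3, fp=1, tn=5, fn=1
    scores = [0.9, 0.8, 0.7, 0.3, 0.6, 0.1, 0.2, 0.3, 0.4, 0.45]
    labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    m = evaluate(scores, labels, 0.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 5, 1)
    assert m.precision == pytest.approx(0.75)
    assert m.recall == pytest.approx(0.75)
    assert m.accuracy == pytest.approx(0.8)
    assert m.f1 == pytest.approx(0.75)


def test_auc_threshold_invariance():
    rng = np.random.default_rng(4)
    scores = rng.uniform(size=40)
    labels = rng.integers(0, 2, 40)
    assert evaluate(scores, labels, 0.3).auc == evaluate(scores, labels, 0.7).auc


def test_single_class_auc_is_none():
    m = evaluate([0.2, 0.8], [1, 1], 0.5)
    assert m.auc is None and m.recall == 0.5


# ------------------------------------------------------------------- AUC
def test_auc_hand_examples():
    assert roc_auc([0.9, 0.3, 0.8], [1, 1, 0]) == pytest.approx(0.5)
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0


def test_auc_null_distribution():
    rng = np.random.default_rng(42)
    scores = rng.uniform(size=10_000)
    labels = rng.integers(0, 2, 10_000)
    assert abs(roc_auc(scores, labels) - 0.5) < 0.02


def test_auc_matches_trapezoidal_oracle():
    """Rank statistic equals sklearn's trapezoidal ROC integration on
    every random set of <= 50 samples (including ties)."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(4, 51))
        scores = np.round(rng.uniform(size=n), 2)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


# -------------------------------------------------------------- threshold
def test_threshold_perfect_separation_midpoint():
    t = select_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], "youden")
    assert t == pytest.approx(0.5)


def test_threshold_youden_enumeration():
    t = select_threshold([0.9, 0.6, 0.4, 0.5, 0.2, 0.1], [1, 1, 1, 0, 0, 0], "youden")
    pos = np.array([0.9, 0.6, 0.4])
    neg = np.array([0.5, 0.2, 0.1])
    j = (pos >= t).mean() - (neg >= t).mean()
    assert j == pytest.approx(2 / 3)  # the maximal Youden J on this set
    # ties between cut points resolve toward the lower threshold
    assert t <= 0.45


def test_threshold_specificity_policy():
    scores = [0.9, 0.7, 0.65, 0.6, 0.4, 0.3]
    labels = [1, 1, 0, 1, 0, 0]
    t = select_threshold(
        scores, labels, "max_sensitivity_at_specificity", specificity=1.0
    )
    assert t > 0.65
    with pytest.raises(ValueError):  # target beyond the achievable range
        select_threshold([0.5, 0.5], [1, 0], "max_sensitivity_at_specificity",
                         specificity=1.01)


# --------------------------------------------------------------- ablation
def test_balanced_dataset_weights_are_unit(imbalanced_dataset):
    ds, _ = imbalanced_dataset
    balanced = LabeledDataset(ds.items[:40] + ds.items[40:80])
    w = compute_class_weights(balanced.class_counts())
    assert w.w_c == {0: 1.0, 1: 1.0}
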
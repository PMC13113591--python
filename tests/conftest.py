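"""Shared fixtures: in-memory synthetic datasets and a trained backbone.

The expensive artifacts (a 5:1-imbalanced synthetic dataset and one
trained reference CNN) are session-scoped so the classification,
explainability and acceptance tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from dermaprep import classify, synthgen
from dermaprep.backbone import TinyCNN


def make_labeled_dataset(
    n_mel: int, n_nmsc: int, seed: int, with_hair: bool = False
) -> tuple[classify.LabeledDataset, list[np.ndarray]]:
    """In-memory class-conditional dataset plus truth lesion masks."""
    items, masks = [], []
    for i in range(n_mel + n_nmsc):
        label = 1 if i < n_mel else 0
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        scene, lesion, hair = synthgen.sample_specs(label, rng, with_hair=with_hair)
        sample = synthgen.generate_image(scene, lesion, hair, int(rng.integers(2**31)))
        items.append((sample.image, label))
        masks.append(sample.lesion_mask)
    return classify.LabeledDataset(items), masks


@pytest.fixture(scope="session")
def imbalanced_dataset():
    """40 melanoma / 200 non-melanoma hair-free frames (5:1 imbalance)."""
    return make_labeled_dataset(40, 200, seed=123)


@pytest.fixture(scope="session")
def train_config():
    """From-scratch training settings for the reference CNN."""
    return classify.TrainConfig(lr=1e-2, epochs=30, seed=42)


@pytest.fixture(scope="session")
def trained_backbone(imbalanced_dataset, train_config):
    """Reference CNN trained on the imbalanced dataset with Eq-style
    inverse-frequency class weights; returns (backbone, history, splits)."""
    dataset, _ = imbalanced_dataset
    train, val, test = classify.stratified_split(dataset, seed=42)
    weights = classify.compute_class_weights(dataset.class_counts())
    backbone, history = classify.train_classifier(
        train, val, TinyCNN(seed=42), train_config, weights
    )
    return backbone, history, (train, val, test)
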
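"""Training utilities: weights, losses, augmentations, dropout, schedules, loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantfuse.training import (MultimodalDropoutSpec, TinyCNNBackbone,
                                TrainSpec, compute_class_weights,
                                contrast_augment, exponential_lr,
                                multimodal_dropout, train_multimodal,
                                train_unimodal, weighted_cross_entropy)
from conftest import FakeBackbone, toy_bitwise_data


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def test_balanced_counts_give_unit_weights():
    cw = compute_class_weights([10, 10, 10])
    assert np.allclose(cw.weights, 1.0)


def test_class_weight_formula():
    cw = compute_class_weights([10, 30, 60])
    assert np.allclose(cw.weights, [10 / 3, 10 / 9, 5 / 9])


@given(st.lists(st.integers(1, 500), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_weight_conservation_over_random_counts(counts):
    counts = np.array(counts)
    cw = compute_class_weights(counts)
    assert (counts * cw.weights).sum() == pytest.approx(cw.n_total)


def test_zero_count_rejected():
    with pytest.raises(ValueError):
        compute_class_weights([5, 0, 3])


# ---------------------------------------------------------------------------
# weighted cross-entropy
# ---------------------------------------------------------------------------

def test_one_hot_correct_predictions_have_near_zero_loss():
    probs = np.eye(4)[[0, 1, 2, 3]]
    assert weighted_cross_entropy(probs, np.arange(4)) < 1e-6


def test_uniform_predictions_give_log_c():
    for c in (2, 5, 17):
        probs = np.full((8, c), 1.0 / c)
        labels = np.arange(8) % c
        assert weighted_cross_entropy(probs, labels) == pytest.approx(np.log(c))


def test_single_sample_reduction():
    probs = np.array([[0.2, 0.7, 0.1]])
    w = np.array([1.0, 2.5, 1.0])
    assert weighted_cross_entropy(probs, [1], w) == pytest.approx(-2.5 * np.log(0.7))


def test_unit_weights_equal_plain_cross_entropy():
    rng = np.random.default_rng(1)
    for _ in range(20):
        logits = rng.normal(size=(16, 6))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 6, 16)
        plain = -np.log(probs[np.arange(16), labels]).mean()
        weighted = weighted_cross_entropy(probs, labels, np.ones(6))
        assert abs(weighted - plain) < 1e-12


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def test_contrast_k1_is_identity():
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 1, size=(8, 8, 3))
    assert np.allclose(contrast_augment(img, 1.0), img)


def test_contrast_constant_channel_unchanged():
    img = np.full((8, 8, 3), 0.4)
    assert np.allclose(contrast_augment(img, 1.25), img)


def test_contrast_k0_collapses_to_channel_means():
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 1, size=(8, 8, 3))
    out = contrast_augment(img, 0.0)
    assert np.allclose(out, img.mean(axis=(0, 1), keepdims=True))


def test_contrast_preserves_channel_means():
    rng = np.random.default_rng(4)
    img = rng.uniform(0.3, 0.7, size=(16, 16, 3))  # away from clip bounds
    out = contrast_augment(img, 1.2)
    assert np.allclose(out.mean(axis=(0, 1)), img.mean(axis=(0, 1)), atol=1e-12)


# ---------------------------------------------------------------------------
# multimodal dropout
# ---------------------------------------------------------------------------

def test_md_rate_zero_is_identity():
    imgs = {"flower": np.ones((4, 4, 3)), "leaf": np.full((4, 4, 3), 0.5)}
    out = multimodal_dropout(imgs, MultimodalDropoutSpec(0.0),
                             np.random.default_rng(0))
    for k in imgs:
        assert np.array_equal(out[k], imgs[k])


def test_md_rate_one_zeroes_everything():
    imgs = {"flower": np.ones((4, 4, 3)), "stem": np.ones((4, 4, 3))}
    out = multimodal_dropout(imgs, MultimodalDropoutSpec(1.0),
                             np.random.default_rng(0))
    for k in imgs:
        assert np.all(out[k] == 0)


def test_md_empirical_rate_matches_spec():
    rng = np.random.default_rng(5)
    spec = MultimodalDropoutSpec(0.125)
    img = np.ones((2, 2, 3))
    drops = {"flower": 0, "leaf": 0}
    n = 10_000
    for _ in range(n):
        out = multimodal_dropout({"flower": img, "leaf": img}, spec, rng)
        for k in drops:
            drops[k] += int(out[k].sum() == 0)
    for k, count in drops.items():
        assert abs(count / n - 0.125) <= 0.01, k


def test_md_invalid_rate_rejected():
    with pytest.raises(ValueError):
        MultimodalDropoutSpec(1.5)


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def test_exponential_lr():
    assert exponential_lr(0, 1e-3) == pytest.approx(1e-3)
    assert exponential_lr(200, 1e-3, 0.95, 200) == pytest.approx(0.95e-3)
    lrs = [exponential_lr(s, 1e-3, 0.95, 200) for s in range(0, 1000, 50)]
    assert all(a > b for a, b in zip(lrs, lrs[1:]))
    # staircase is flat within a decay window
    assert exponential_lr(150, 1e-3, 0.95, 200, staircase=True) == 1e-3


# ---------------------------------------------------------------------------
# unimodal training loop
# ---------------------------------------------------------------------------

def _small_organ_data(seed=0, n_classes=3, n=60):
    from plantfuse.synthetic import render_organ_image
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n)
    x = np.stack([render_organ_image(c, "flower", rng, n_classes=n_classes,
                                     size=16) * 2 - 1 for c in y])
    return x[:40], y[:40], x[40:], y[40:]


def test_frozen_base_weights_unchanged():
    x_tr, y_tr, x_va, y_va = _small_organ_data()
    model = TinyCNNBackbone("flower", 3, seed=1)
    before = [p.value.copy() for p in model.base_params()]
    spec = TrainSpec(epochs=3, train_base=False, batch_size=16)
    train_unimodal(model, x_tr, y_tr, x_va, y_va, spec, seed=0)
    after = [p.value for p in model.base_params()]
    assert all(np.array_equal(a, b) for a, b in zip(before, after))


def test_early_stopping_bounds_extra_epochs():
    x_tr, y_tr, x_va, y_va = _small_organ_data(seed=1)
    model = TinyCNNBackbone("flower", 3, seed=2)
    spec = TrainSpec(epochs=50, es_patience=3, batch_size=16)
    history = train_unimodal(model, x_tr, y_tr, x_va, y_va, spec, seed=0)
    best_epoch = int(np.argmin([h["val_loss"] for h in history]))
    assert len(history) - 1 - best_epoch <= spec.es_patience


def test_unimodal_training_learns_synthetic_organ(small_built_dataset):
    from plantfuse.pipeline import _load_split
    d = small_built_dataset["dir"]
    x_tr, y_tr = _load_split(d, "flower", "train", 32)
    x_va, y_va = _load_split(d, "flower", "val", 32)
    model = TinyCNNBackbone("flower", 5, seed=7)
    train_unimodal(model, x_tr, y_tr, x_va, y_va,
                   TrainSpec(epochs=30, es_patience=8, batch_size=32), seed=7)
    acc = float((np.argmax(model.forward(x_va), 1) == y_va).mean())
    assert acc > 0.6


def test_empty_split_rejected():
    model = TinyCNNBackbone("flower", 3, seed=0)
    with pytest.raises(ValueError):
        train_unimodal(model, np.zeros((0, 16, 16, 3)), np.zeros(0, dtype=int),
                       np.zeros((0, 16, 16, 3)), np.zeros(0, dtype=int),
                       TrainSpec(epochs=1))


# ---------------------------------------------------------------------------
# multimodal training loop
# ---------------------------------------------------------------------------

def _toy_fusion_model(seed=0):
    from plantfuse.search import (FusionConfig, FusionLayerSpec,
                                  build_fusion_network)
    backbones = {"A": FakeBackbone([4, 2]), "B": FakeBackbone([2, 4])}
    cfg = FusionConfig((FusionLayerSpec((2, 1, 1)),))
    zero_feats = {"A": [np.zeros(4), np.zeros(2)],
                  "B": [np.zeros(2), np.zeros(4)]}
    return build_fusion_network(backbones, cfg, 16, 4,
                                np.random.default_rng(seed),
                                activations=("relu",), zero_features=zero_feats)


def test_multimodal_loss_decreases_on_separable_data():
    train = toy_bitwise_data(200, 3)
    val = toy_bitwise_data(80, 4)
    model = _toy_fusion_model()
    hist = train_multimodal(model, train[0], train[1], val[0], val[1],
                            TrainSpec(epochs=5, es_patience=10, batch_size=32),
                            seed=0)
    assert hist[-1]["loss"] < hist[0]["loss"]


def test_md_substream_does_not_perturb_batch_order():
    """rate-0 dropout and no dropout give identical runs with the same seed."""
    train = toy_bitwise_data(200, 3)
    val = toy_bitwise_data(80, 4)
    h1 = train_multimodal(_toy_fusion_model(), train[0], train[1], val[0],
                          val[1], TrainSpec(epochs=3, batch_size=32), seed=5,
                          md_spec=MultimodalDropoutSpec(0.0))
    h2 = train_multimodal(_toy_fusion_model(), train[0], train[1], val[0],
                          val[1], TrainSpec(epochs=3, batch_size=32), seed=5,
                          md_spec=None)
    assert [h["loss"] for h in h1] == [h["loss"] for h in h2]
    h3 = train_multimodal(_toy_fusion_model(), train[0], train[1], val[0],
                          val[1], TrainSpec(epochs=3, batch_size=32), seed=5,
                          md_spec=MultimodalDropoutSpec(0.5))
    assert [h["loss"] for h in h3] != [h["loss"] for h in h1]


def test_missing_modality_equals_dropped_modality(small_built_dataset):
    """Records lacking an organ carry exactly the zero-image features that
    multimodal dropout would substitute."""
    import os
    from plantfuse.dataset import load_index
    from plantfuse.search import build_feature_cache, zero_image_features

    d = small_built_dataset["dir"]
    backbones = {o: TinyCNNBackbone(o, 5, seed=i)
                 for i, o in enumerate(("flower", "leaf", "fruit", "stem"))}
    records = load_index(os.path.join(d, "multimodal", "train.jsonl"))
    feats, labels, modality_sets = build_feature_cache(backbones, records, d, 32)
    zero_feats = {m: zero_image_features(b, 32) for m, b in backbones.items()}
    missing = [(i, m) for i, mods in enumerate(modality_sets)
               for m in backbones if m not in mods]
    assert missing, "fixture should contain at least one missing modality"
    for i, m in missing[:20]:
        for li, layer in enumerate(feats[m]):
            assert np.array_equal(layer[i], zero_feats[m][li])
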
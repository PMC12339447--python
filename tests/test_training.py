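"""Pre-training and supervised-transfer contracts."""

import numpy as np
import pytest

from retmae.manifest import fuse_for_pretraining
from retmae.mae import preset, sample_masks
from retmae.training import (Classifier, ClassifierHeadSpec, PretrainConfig,
                             SupervisedConfig, build_classifier, pretrain,
                             train_classifier, resolve_images)


def _fusion(small_study):
    _, manifests = small_study
    return fuse_for_pretraining(list(manifests.values()), rng_seed=0)


def test_pretrain_config_rejects_zero_epochs():
    with pytest.raises(ValueError):
        PretrainConfig(epochs=0)


def test_pretrain_learns_and_selects_best_epoch(small_study):
    store, _ = small_study
    fusion = _fusion(small_study)
    cfg = PretrainConfig(epochs=3, batch_size=32, seed=1)
    result = pretrain(fusion, preset("swinv2-tiny"), cfg, store)
    assert len(result.history) == 3
    assert result.history.val_loss.iloc[-1] < result.history.val_loss.iloc[0]
    assert result.best_val_loss == result.history.val_loss.min()


def test_pretrain_is_deterministic(small_study):
    store, _ = small_study
    fusion = _fusion(small_study)
    cfg = PretrainConfig(epochs=2, batch_size=32, seed=5)
    h1 = pretrain(fusion, preset("swinv2-tiny"), cfg, store).history
    h2 = pretrain(fusion, preset("swinv2-tiny"), cfg, store).history
    assert h1.equals(h2)


@pytest.fixture(scope="module")
def pretrained(small_study):
    store, _ = small_study
    fusion = fuse_for_pretraining(
        list(small_study[1].values()), rng_seed=0)
    cfg = PretrainConfig(epochs=2, batch_size=32, seed=2)
    return pretrain(fusion, preset("swinv2-tiny"), cfg, store)


def test_transfer_is_bit_exact(pretrained, small_study):
    store, manifests = small_study
    clf = build_classifier(pretrained.model, freeze=True, rng_seed=0)
    some = manifests["srcA"].subset("test")
    images = resolve_images(some, store)
    from_mae = pretrained.model.encode(images).data
    from_clf = clf.features(images).data
    assert np.array_equal(from_mae, from_clf)


def test_family_mismatch_rejected(pretrained):
    with pytest.raises(ValueError, match="family"):
        build_classifier(pretrained.model, config=preset("vit-tiny"))


def test_head_parameter_count_closed_form(pretrained):
    head = ClassifierHeadSpec((512, 256))
    clf = build_classifier(pretrained.model, head=head, freeze=True)
    d = pretrained.model.config.encoder.final_dim
    expected = d * 512 + 512 + 512 * 256 + 256 + 256 * 2 + 2
    got = sum(p.size for _, p in clf.head_parameters())
    assert got == expected == head.n_parameters(d)


def _binary(manifests, source, split):
    from retmae.manifest import map_labels_binary
    return map_labels_binary(manifests[source]).subset(split)


def test_frozen_encoder_is_bit_identical_after_training(pretrained,
                                                        small_study):
    store, manifests = small_study
    clf = build_classifier(pretrained.model, head=ClassifierHeadSpec((32, 16)),
                           freeze=True, rng_seed=3)
    before = {k: v.copy() for k, v in clf.mae.state_dict().items()}
    cfg = SupervisedConfig(epochs=4, early_stop_patience=2,
                           augmentations=(), lr=3e-3, seed=3)
    train_classifier(clf, _binary(manifests, "srcA", "train"),
                     _binary(manifests, "srcA", "val"), cfg, store)
    after = clf.mae.state_dict()
    assert before.keys() == after.keys()
    for name in before:
        assert np.array_equal(before[name], after[name]), name


def test_single_class_training_set_rejected(pretrained, small_study):
    store, manifests = small_study
    binary = _binary(manifests, "srcA", "train")
    one_class = type(binary)(
        binary.records[binary.records.class_label == "NORMAL"])
    clf = build_classifier(pretrained.model, freeze=True)
    cfg = SupervisedConfig(epochs=3, early_stop_patience=2, augmentations=())
    with pytest.raises(ValueError, match="both classes"):
        train_classifier(clf, one_class, _binary(manifests, "srcA", "val"),
                         cfg, store)


def test_classifier_learns_separable_data(domains):
    """Frozen pre-trained features + trained head must reach
    val accuracy > 0.8 within 30 epochs on separable synthetic data."""
    from retmae.manifest import DatasetManifest, split_random_stratified
    from retmae.synth import generate_source
    images, rows = generate_source(domains[0], 50, 4,
                                   {"NORMAL": 0.5, "AMD": 0.5}, rng_seed=77)
    m = split_random_stratified(DatasetManifest(rows), (0.7, 0.15, 0.15), 1)
    fusion = fuse_for_pretraining([m], rng_seed=1)
    pre = pretrain(fusion, preset("swinv2-tiny"),
                   PretrainConfig(epochs=3, seed=1), images)
    clf = build_classifier(pre.model, head=ClassifierHeadSpec((64, 32)),
                           freeze=True, rng_seed=1)
    cfg = SupervisedConfig(epochs=30, early_stop_patience=10,
                           augmentations=(), lr=3e-3, seed=1)
    result = train_classifier(clf, m.subset("train"), m.subset("val"),
                              cfg, images)
    assert result.best_val_acc > 0.8


def test_early_stopping_counter_semantics(pretrained, small_study):
    """Patience p with no improvement after the best epoch stops the loop
    exactly p epochs later."""
    store, manifests = small_study
    clf = build_classifier(pretrained.model, head=ClassifierHeadSpec((8, 4)),
                           freeze=True, rng_seed=11)
    # lr=0 head never changes, so epoch 1 is the best and patience runs out
    cfg = SupervisedConfig(epochs=20, early_stop_patience=5,
                           augmentations=(), lr=0.0, seed=0,
                           weight_decay=0.0)
    result = train_classifier(clf, _binary(manifests, "srcB", "train"),
                              _binary(manifests, "srcB", "val"), cfg, store)
    assert result.best_epoch == 1
    assert result.stopped_epoch == 1 + 5


def test_augmentations_never_touch_evaluation(pretrained, small_study):
    store, manifests = small_study
    test_m = _binary(manifests, "srcC", "test")
    images = resolve_images(test_m, store)
    clf = build_classifier(pretrained.model, freeze=True, rng_seed=0)
    p1 = clf.predict_proba(images)
    p2 = clf.predict_proba(images)
    assert np.array_equal(p1, p2)
    assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-12)


def test_augment_image_outputs_stay_in_range(domains):
    from retmae.training import AUGMENTATIONS, augment_image
    from retmae.synth import LesionParams, generate_bscan
    img = generate_bscan(domains[0], LesionParams("NORMAL"), 0)
    rng = np.random.default_rng(0)
    out = augment_image(img, rng, AUGMENTATIONS)
    assert out.shape == img.shape
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert not np.array_equal(out, img)
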
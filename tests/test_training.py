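import numpy as np
import pytest

from ocutax.model import BackboneConfig, HierarchicalHeadConfig, build_hierarchical_model
from ocutax.training import (
    AugmentConfig,
    StageStep,
    TrainConfig,
    augment,
    desk_preset,
    evaluate_loss,
    full_preset,
    train,
    training_schedule,
)

SMALL = BackboneConfig(channels=(8, 16))
HEADS = HierarchicalHeadConfig(hidden=(32, 16))


def _rng_img(seed=0, size=24):
    return np.random.default_rng(seed).random((size, size, 3)).astype(np.float32)


def test_augment_identity_when_disabled():
    cfg = AugmentConfig(horizontal_flip=0, vertical_flip=0, rotation_degrees=0, jitter=0)
    img = _rng_img()
    out = augment(img, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(out, img)


def test_augment_flip_is_involution():
    cfg = AugmentConfig(horizontal_flip=1.0, vertical_flip=0, rotation_degrees=0, jitter=0)
    img = _rng_img(1)
    once = augment(img, cfg, np.random.default_rng(0))
    twice = augment(once, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(twice, img)


def test_augment_reproducible_and_label_preserving():
    cfg = AugmentConfig()
    img = _rng_img(2)
    a = augment(img, cfg, np.random.default_rng(123))
    b = augment(img, cfg, np.random.default_rng(123))
    np.testing.assert_array_equal(a, b)
    assert a.shape == img.shape
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(horizontal_flip=1.5)
    with pytest.raises(ValueError):
        AugmentConfig(rotation_degrees=-3)


def test_full_schedule_epoch_count_and_lrs():
    cfg = full_preset()
    rows = training_schedule(cfg, n_backbone_blocks=4)
    assert len(rows) == 5 + 20 * 4  # 5 frozen epochs + four 20-epoch steps
    assert rows[0]["trainable"] == ["head1", "head2"]
    assert cfg.input_size == 299 and cfg.stage1_lr == 1e-4 and cfg.adam_eps == 0.1
    lrs = [s.learning_rate for s in cfg.stage2]
    assert lrs[0] == pytest.approx(1e-4) and lrs[-1] == pytest.approx(1e-6)
    assert all(b < a for a, b in zip(lrs, lrs[1:]))
    # blocks unfreeze last-first, cumulatively
    assert rows[5]["trainable"] == ["head1", "head2", "backbone.block3"]
    assert "backbone.block0" in rows[-1]["trainable"]


def test_increasing_stage2_lr_rejected():
    with pytest.raises(ValueError, match="decreasing"):
        TrainConfig(stage2=(StageStep(1, 1e-4), StageStep(1, 1e-3)))


def _fit(tiny_dataset, config, seed=0, n=64):
    cfg, X, records, labels = tiny_dataset
    net = build_hierarchical_model(cfg.taxonomy, SMALL, HEADS, seed=seed)
    idx = np.arange(min(n, X.shape[0]))
    log = train(net, X[idx], {l: labels[l][idx] for l in (1, 2)}, config)
    return net, log, idx


def test_stage1_freezes_backbone_bit_exact(tiny_dataset):
    cfg, X, records, labels = tiny_dataset
    net = build_hierarchical_model(cfg.taxonomy, SMALL, HEADS, seed=0)
    before = {p.name: p.data.copy() for g in net.backbone.param_groups().values() for p in g}
    head_before = net.head1.out_w.data.copy()
    config = TrainConfig(
        input_size=32, batch_size=16, stage1_epochs=2, stage1_lr=1e-3,
        adam_eps=1e-8, stage2=(), seed=0,
    )
    log = train(net, X[:48], {l: labels[l][:48] for l in (1, 2)}, config)
    for p in (p for g in net.backbone.param_groups().values() for p in g):
        np.testing.assert_array_equal(p.data, before[p.name])  # frozen, bit-identical
    assert not np.array_equal(net.head1.out_w.data, head_before)  # heads moved
    assert len(log) == 2
    assert set(log["trainable"]) == {"head1;head2"}


def test_stage2_unfreezes_blocks_and_logs_groups(tiny_dataset):
    config = TrainConfig(
        input_size=32, batch_size=16, stage1_epochs=1, stage1_lr=1e-3,
        adam_eps=1e-8,
        stage2=(StageStep(1, 5e-4), StageStep(1, 1e-4)),
        seed=0,
    )
    net, log, idx = _fit(tiny_dataset, config, n=48)
    assert len(log) == 1 + 1 + 1
    assert log["trainable"].iloc[1] == "head1;head2;backbone.block1"
    assert log["trainable"].iloc[2] == "head1;head2;backbone.block0;backbone.block1"


def test_training_reduces_loss(tiny_dataset):
    config = TrainConfig(
        input_size=32, batch_size=16, stage1_epochs=3, stage1_lr=3e-3,
        adam_eps=1e-8, stage2=(StageStep(3, 1e-3),), seed=0,
    )
    net, log, idx = _fit(tiny_dataset, config)
    assert log["loss_total"].iloc[-1] <= 0.5 * log["loss_total"].iloc[0]


def test_stage1_validation_loss_mostly_non_increasing(tiny_dataset):
    """Soft property: on a fixed validation batch the total loss does not
    increase over stage 1 for at least 4 of 5 seeds."""
    cfg, X, records, labels = tiny_dataset
    tr = np.arange(48)
    val = np.arange(48, 64)
    config = TrainConfig(
        input_size=32, batch_size=16, stage1_epochs=2, stage1_lr=1e-3,
        adam_eps=1e-8, stage2=(), augment=None,
    )
    wins = 0
    for seed in range(5):
        net = build_hierarchical_model(cfg.taxonomy, SMALL, HEADS, seed=seed)
        from dataclasses import replace

        log = train(
            net,
            X[tr], {l: labels[l][tr] for l in (1, 2)},
            replace(config, seed=seed),
            val_images=X[val], val_labels={l: labels[l][val] for l in (1, 2)},
        )
        if log["val_loss_total"].iloc[-1] <= log["val_loss_total"].iloc[0] + 1e-9:
            wins += 1
    assert wins >= 4


def test_train_input_validation(tiny_dataset, desk):
    cfg, X, records, labels = tiny_dataset
    net = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    config = TrainConfig(stage2=(), stage1_epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train(net, X[:0], {1: labels[1][:0], 2: labels[2][:0]}, config)
    with pytest.raises(ValueError, match="label"):
        train(net, X[:4], {1: labels[1][:4, :1], 2: labels[2][:4]}, config)
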
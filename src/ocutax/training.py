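"""On-the-fly augmentation and the freeze-then-unfreeze fine-tuning schedule.

Training proceeds in two stages.  In **stage 1** the backbone is frozen and
only the branch heads are trained (5 epochs, Adam, lr 1e-4, eps 0.1 in the
``full`` preset).  **Stage 2** then unfreezes the backbone block by block,
last block first, one block per step, with the learning rate decreasing
geometrically across steps (1e-4 down to 1e-6 over 20-epoch steps in the
``full`` preset).  The ``desk`` preset keeps the same structure at CPU scale:
96-px inputs, short stages and a larger learning rate / standard Adam epsilon
so the small NumPy backbone converges in minutes.

Augmentation (flips, rotation, color jitter) is applied independently per
draw to increase data diversity; it does not rebalance class counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import autodiff as ad
from .losses import FocalParams, LevelWeights, total_loss
from .model import HierarchicalNetwork

__all__ = [
    "AugmentConfig",
    "StageStep",
    "TrainConfig",
    "full_preset",
    "desk_preset",
    "preset",
    "augment",
    "training_schedule",
    "train",
]


@dataclass(frozen=True)
class AugmentConfig:
    horizontal_flip: float = 0.5
    vertical_flip: float = 0.5
    rotation_degrees: float = 15.0
    jitter: float = 0.2  # brightness/contrast/saturation amplitude

    def __post_init__(self) -> None:
        for p in (self.horizontal_flip, self.vertical_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.rotation_degrees < 0 or self.jitter < 0:
            raise ValueError("rotation and jitter amplitudes must be >= 0")


@dataclass(frozen=True)
class StageStep:
    """One stage-2 step: how long, how fast, how many blocks are unfrozen."""

    epochs: int
    learning_rate: float


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 299
    batch_size: int = 32
    stage1_epochs: int = 5
    stage1_lr: float = 1e-4
    adam_eps: float = 0.1
    stage2: tuple[StageStep, ...] = ()
    focal: FocalParams = field(default_factory=FocalParams)
    weights: LevelWeights = field(default_factory=LevelWeights)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_epochs < 1:
            raise ValueError("stage-1 epochs must be >= 1")
        lrs = [s.learning_rate for s in self.stage2]
        if any(b >= a for a, b in zip(lrs, lrs[1:])):
            raise ValueError("stage-2 learning rates must be strictly decreasing")
        if any(s.epochs < 1 for s in self.stage2):
            raise ValueError("stage-2 epochs must be >= 1")


def full_preset(n_unfreeze_steps: int = 4) -> TrainConfig:
    """Full-scale schedule: 299-px input, 5 frozen epochs, then
    ``n_unfreeze_steps`` steps of 20 epochs with lr geometric 1e-4 -> 1e-6."""
    lrs = np.geomspace(1e-4, 1e-6, n_unfreeze_steps)
    return TrainConfig(
        input_size=299,
        stage1_epochs=5,
        stage1_lr=1e-4,
        adam_eps=0.1,
        stage2=tuple(StageStep(epochs=20, learning_rate=float(lr)) for lr in lrs),
    )


def desk_preset(seed: int = 0) -> TrainConfig:
    """CPU-scale schedule used by the synthetic end-to-end experiments."""
    return TrainConfig(
        input_size=96,
        batch_size=32,
        stage1_epochs=4,
        stage1_lr=3e-3,
        adam_eps=1e-8,
        stage2=(
            StageStep(epochs=4, learning_rate=1e-3),
            StageStep(epochs=4, learning_rate=3e-4),
        ),
        seed=seed,
    )


def preset(name: str, **kwargs) -> TrainConfig:
    if name == "full":
        return full_preset()
    if name == "desk":
        return desk_preset(**kwargs)
    raise ValueError(f"unknown preset {name!r} (expected 'full' or 'desk')")


# ---------------------------------------------------------------------------
# augmentation

def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving random transform of one HWC RGB image in [0, 1].

    All randomness comes from ``rng``; draws are consumed in a fixed order so
    a given generator state reproduces the same output exactly.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    if rng.random() < config.horizontal_flip:
        img = img[:, ::-1]
    if rng.random() < config.vertical_flip:
        img = img[::-1]
    if config.rotation_degrees > 0:
        angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
        img = ndimage.rotate(
            img, angle, axes=(1, 0), reshape=False, order=1, mode="nearest"
        )
    if config.jitter > 0:
        a = config.jitter
        brightness, contrast, saturation = 1.0 + rng.uniform(-a, a, size=3)
        img = img * brightness
        mean = img.mean()
        img = (img - mean) * contrast + mean
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * saturation
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# schedule

def training_schedule(config: TrainConfig, n_backbone_blocks: int) -> list[dict]:
    """Expand the config into per-epoch rows: stage, lr, trainable groups.

    Stage 1 trains heads only; stage-2 step *i* additionally unfreezes the
    last *i* backbone blocks (first blocks unfrozen last).
    """
    head_groups = ["head1", "head2"]
    rows: list[dict] = []
    epoch = 0
    for _ in range(config.stage1_epochs):
        rows.append(
            {
                "epoch": epoch,
                "stage": "stage1",
                "lr": config.stage1_lr,
                "trainable": list(head_groups),
            }
        )
        epoch += 1
    for i, step in enumerate(config.stage2, start=1):
        unfrozen = [
            f"backbone.block{j}"
            for j in range(n_backbone_blocks - min(i, n_backbone_blocks), n_backbone_blocks)
        ]
        for _ in range(step.epochs):
            rows.append(
                {
                    "epoch": epoch,
                    "stage": f"stage2.step{i}",
                    "lr": step.learning_rate,
                    "trainable": head_groups + unfrozen,
                }
            )
            epoch += 1
    return rows


# ---------------------------------------------------------------------------
# training loop

def _epoch_pass(
    net: HierarchicalNetwork,
    images: np.ndarray,
    labels: dict[int, np.ndarray],
    config: TrainConfig,
    opt: ad.Adam,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    n = images.shape[0]
    perm = rng.permutation(n)
    sums = np.zeros(3)
    n_batches = 0
    for start in range(0, n, config.batch_size):
        idx = perm[start : start + config.batch_size]
        batch = images[idx]
        if config.augment is not None:
            batch = np.stack([augment(im, config.augment, rng) for im in batch])
        x = batch.transpose(0, 3, 1, 2)
        res = net.forward(x)
        l1 = ad.focal_loss(res.probs[1], labels[1][idx], config.focal)
        l2 = ad.focal_loss(res.probs[2], labels[2][idx], config.focal)
        loss = ad.weighted_sum([l1, l2], config.weights.weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
        sums += (float(loss.data), float(l1.data), float(l2.data))
        n_batches += 1
    return tuple(sums / n_batches)  # type: ignore[return-value]


def evaluate_loss(
    net: HierarchicalNetwork, images: np.ndarray, labels: dict[int, np.ndarray], config: TrainConfig
) -> float:
    """Total loss on a fixed batch (no augmentation, no update)."""
    from .losses import level_loss

    scores = {}
    x = images.transpose(0, 3, 1, 2)
    res = net.forward(x)
    per_level = [level_loss(res.probs[lvl].data, labels[lvl], config.focal) for lvl in (1, 2)]
    return total_loss(per_level, config.weights)


def train(
    net: HierarchicalNetwork,
    images: np.ndarray,
    labels: dict[int, np.ndarray],
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Train in place following the staged schedule; return the per-epoch log.

    ``images`` is NHWC float32 in [0, 1]; ``labels`` maps level -> multi-hot
    matrix aligned with the network's taxonomy class order.
    """
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    for lvl in (1, 2):
        if labels[lvl].shape != (images.shape[0], net.taxonomy.n_classes(lvl)):
            raise ValueError(f"level-{lvl} label matrix does not match taxonomy/images")
    rng = np.random.default_rng(config.seed)
    groups = net.param_groups()
    schedule = training_schedule(config, len(net.backbone.blocks))
    log_rows: list[dict] = []
    opt: ad.Adam | None = None
    current_key: tuple | None = None
    for row in schedule:
        key = (row["stage"], row["lr"], tuple(row["trainable"]))
        if key != current_key:  # new stage/step: fresh optimizer over the unfrozen set
            params = [p for g in row["trainable"] for p in groups[g]]
            opt = ad.Adam(params, lr=row["lr"], eps=config.adam_eps)
            current_key = key
        tot, l1, l2 = _epoch_pass(net, images, labels, config, opt, rng)
        entry = {
            "epoch": row["epoch"],
            "stage": row["stage"],
            "lr": row["lr"],
            "loss_total": tot,
            "loss_l1": l1,
            "loss_l2": l2,
            "trainable": ";".join(row["trainable"]),
        }
        if val_images is not None and val_labels is not None:
            entry["val_loss_total"] = evaluate_loss(net, val_images, val_labels, config)
        log_rows.append(entry)
    return pd.DataFrame(log_rows)
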
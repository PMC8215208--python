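"""Hierarchical multi-task & multi-label network and the flat ablation baseline.

Architecture (two taxonomy levels):

* a convolutional **backbone** maps an RGB image to a final spatial feature
  map and, by global average pooling, to a pooled feature vector;
* the **level-1 branch** (stacked fully connected units) consumes the pooled
  vector and ends in one sigmoid output per level-1 class;
* the **level-2 branch** consumes the *concatenation* of the pooled vector
  with the level-1 branch's penultimate hidden activations — the coarse
  classifier's representation acts as a prior for the fine classifier — and
  ends in one sigmoid per level-2 class.

Sigmoids (not softmax) keep classes independent so multiple diseases can be
positive simultaneously.  The **flat baseline** is identical except the
level-1 -> level-2 connection is removed: each level is an independent set of
binary classifiers, the ablation comparator.

The default backbone is a small stack of stride-2 3x3 convolution blocks
suited to CPU-scale experiments; any feature extractor exposing the same
contract (final map + pooled vector) can be plugged in instead, e.g. a large
pretrained network.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .taxonomy import DiseaseTaxonomy

__all__ = [
    "BackboneConfig",
    "HierarchicalHeadConfig",
    "ConvBackbone",
    "BranchHead",
    "HierarchicalNetwork",
    "build_hierarchical_model",
    "build_flat_baseline",
    "predict_calls",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Channel plan of the default convolutional backbone.

    Each entry is one 3x3 stride-2 convolution + ReLU block; the pooled
    feature dimension D equals the last entry.
    """

    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


@dataclass(frozen=True)
class HierarchicalHeadConfig:
    """Per-level branch layout: hidden widths of the stacked FC units."""

    hidden: tuple[int, ...] = (256, 128)


def _he(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class ConvBlock:
    def __init__(self, rng, c_in: int, c_out: int, k: int, name: str):
        self.w = ad.Tensor(_he(rng, (c_out, c_in, k, k), c_in * k * k), True, name=f"{name}.w")
        self.b = ad.Tensor(np.zeros(c_out, np.float32), True, name=f"{name}.b")
        self.k = k

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.relu(ad.conv2d(x, self.w, self.b, stride=2, padding=self.k // 2))

    @property
    def params(self) -> list[ad.Tensor]:
        return [self.w, self.b]


class ConvBackbone:
    """Stride-2 conv blocks ending in a spatial map + global average pooling."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        self.blocks: list[ConvBlock] = []
        c_in = 3
        for i, c_out in enumerate(config.channels):
            self.blocks.append(ConvBlock(rng, c_in, c_out, config.kernel, f"backbone.block{i}"))
            c_in = c_out

    def __call__(self, x: ad.Tensor) -> tuple[list[ad.Tensor], ad.Tensor]:
        """Return (per-block activation maps, pooled feature vector)."""
        maps: list[ad.Tensor] = []
        h = x
        for blk in self.blocks:
            h = blk(h)
            maps.append(h)
        return maps, ad.global_avg_pool(h)

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def param_groups(self) -> dict[str, list[ad.Tensor]]:
        return {f"backbone.block{i}": blk.params for i, blk in enumerate(self.blocks)}


class BranchHead:
    """Stacked fully connected units ending in per-class sigmoid outputs."""

    def __init__(self, rng, d_in: int, hidden: Sequence[int], n_out: int, name: str):
        self.layers: list[tuple[ad.Tensor, ad.Tensor]] = []
        d = d_in
        for j, width in enumerate(hidden):
            w = ad.Tensor(_he(rng, (d, width), d), True, name=f"{name}.fc{j}.w")
            b = ad.Tensor(np.zeros(width, np.float32), True, name=f"{name}.fc{j}.b")
            self.layers.append((w, b))
            d = width
        self.out_w = ad.Tensor(_he(rng, (d, n_out), d), True, name=f"{name}.out.w")
        self.out_b = ad.Tensor(np.zeros(n_out, np.float32), True, name=f"{name}.out.b")
        self.penultimate_dim = d

    def __call__(self, x: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor, ad.Tensor]:
        """Return (penultimate activations, logits, sigmoid probabilities)."""
        h = x
        for w, b in self.layers:
            h = ad.relu(ad.dense(h, w, b))
        logits = ad.dense(h, self.out_w, self.out_b)
        return h, logits, ad.sigmoid(logits)

    @property
    def params(self) -> list[ad.Tensor]:
        ps = [p for pair in self.layers for p in pair]
        return ps + [self.out_w, self.out_b]


@dataclass
class ForwardResult:
    """All graph nodes of one forward pass that callers may need."""

    probs: dict[int, ad.Tensor]
    logits: dict[int, ad.Tensor]
    block_maps: list[ad.Tensor]
    pooled: ad.Tensor

    @property
    def feature_map(self) -> ad.Tensor:
        return self.block_maps[-1]


class HierarchicalNetwork:
    """Backbone + per-level branches; ``hierarchical=False`` gives the flat baseline."""

    def __init__(
        self,
        taxonomy: DiseaseTaxonomy,
        backbone: ConvBackbone,
        head_config: HierarchicalHeadConfig,
        rng: np.random.Generator,
        hierarchical: bool = True,
    ):
        self.taxonomy = taxonomy
        self.backbone = backbone
        self.head_config = head_config
        self.hierarchical = hierarchical
        d = backbone.feature_dim
        n1 = taxonomy.n_classes(1)
        n2 = taxonomy.n_classes(2)
        self.head1 = BranchHead(rng, d, head_config.hidden, n1, "head1")
        d2 = d + (self.head1.penultimate_dim if hierarchical else 0)
        self.head2 = BranchHead(rng, d2, head_config.hidden, n2, "head2")

    # -- forward ----------------------------------------------------------
    def forward(self, images: np.ndarray) -> ForwardResult:
        """Run a batch of NCHW float images through the network.

        Scores are per-class sigmoids in [0, 1]; they do not sum to 1 across a
        level (multi-label).  Deterministic given weights and input.
        """
        x = self._check_input(images)
        maps, pooled = self.backbone(ad.Tensor(x))
        h1, logits1, p1 = self.head1(pooled)
        if self.hierarchical:
            z2 = ad.concat(pooled, h1)
        else:
            z2 = pooled
        _, logits2, p2 = self.head2(z2)
        return ForwardResult(
            probs={1: p1, 2: p2},
            logits={1: logits1, 2: logits2},
            block_maps=maps,
            pooled=pooled,
        )

    def predict_scores(self, images: np.ndarray) -> dict[int, np.ndarray]:
        res = self.forward(images)
        return {lvl: t.data.copy() for lvl, t in res.probs.items()}

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(
                f"expected NCHW RGB batch (n, 3, H, W), got shape {x.shape}"
            )
        return x

    # -- parameters -------------------------------------------------------
    def param_groups(self) -> dict[str, list[ad.Tensor]]:
        groups = dict(self.backbone.param_groups())
        groups["head1"] = self.head1.params
        groups["head2"] = self.head2.params
        return groups

    def parameters(self) -> list[ad.Tensor]:
        return [p for ps in self.param_groups().values() for p in ps]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = state[p.name].copy()


def build_hierarchical_model(
    taxonomy: DiseaseTaxonomy,
    backbone_config: BackboneConfig = BackboneConfig(),
    head_config: HierarchicalHeadConfig = HierarchicalHeadConfig(),
    seed: int = 0,
) -> HierarchicalNetwork:
    """Build the coarse-to-fine network; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    backbone = ConvBackbone(backbone_config, rng)
    return HierarchicalNetwork(taxonomy, backbone, head_config, rng, hierarchical=True)


def build_flat_baseline(
    taxonomy: DiseaseTaxonomy,
    backbone_config: BackboneConfig = BackboneConfig(),
    head_config: HierarchicalHeadConfig = HierarchicalHeadConfig(),
    seed: int = 0,
) -> HierarchicalNetwork:
    """Same backbone and head widths, but no level-1 -> level-2 connection."""
    rng = np.random.default_rng(seed)
    backbone = ConvBackbone(backbone_config, rng)
    return HierarchicalNetwork(taxonomy, backbone, head_config, rng, hierarchical=False)


# ---------------------------------------------------------------------------
# decision rules

def predict_calls(
    scores: dict[int, np.ndarray],
    taxonomy: DiseaseTaxonomy,
    threshold: float = 0.5,
    k: int = 3,
) -> dict[int, dict]:
    """Screening calls and top-k ranking from one sample's per-level scores.

    A class is called positive when its score is *strictly* above the
    threshold (the >50% referral rule at the default).  The top-k list is
    sorted by descending score with ties broken by class-order position; k is
    truncated to the class count.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[int, dict] = {}
    for lvl, vec in scores.items():
        vec = np.asarray(vec, dtype=float).ravel()
        order = taxonomy.class_order[lvl]
        if vec.shape[0] != len(order):
            raise ValueError(f"level-{lvl} score length mismatch")
        positives = [order[i] for i in range(len(order)) if vec[i] > threshold]
        kk = min(k, len(order))
        ranked = sorted(range(len(order)), key=lambda i: (-vec[i], i))[:kk]
        out[lvl] = {
            "positive": positives,
            "topk": [(order[i], float(vec[i])) for i in ranked],
        }
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: HierarchicalNetwork, path: str | Path, extra: dict | None = None) -> None:
    """Persist weights together with the taxonomy hash guarding class order."""
    payload = {
        "state": net.state_dict(),
        "taxonomy_hash": net.taxonomy.content_hash(),
        "hierarchical": net.hierarchical,
        "backbone_channels": net.backbone.config.channels,
        "head_hidden": net.head_config.hidden,
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path, taxonomy: DiseaseTaxonomy) -> HierarchicalNetwork:
    """Rebuild a network from a checkpoint; refuses a mismatched taxonomy."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload["taxonomy_hash"] != taxonomy.content_hash():
        raise ValueError(
            "checkpoint was trained against a different taxonomy/class order"
        )
    build = build_hierarchical_model if payload["hierarchical"] else build_flat_baseline
    net = build(
        taxonomy,
        BackboneConfig(channels=tuple(payload["backbone_channels"])),
        HierarchicalHeadConfig(hidden=tuple(payload["head_hidden"])),
        seed=0,
    )
    net.load_state_dict(payload["state"])
    return net
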
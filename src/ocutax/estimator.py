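"""scikit-learn style estimator wrapping the hierarchical network and trainer.

:class:`HierarchicalImageClassifier` follows the sklearn estimator contract
(constructor stores hyperparameters verbatim, ``fit`` returns ``self``,
fitted state lives in trailing-underscore attributes, ``get_params`` /
``set_params`` work), so it composes with sklearn model selection.  ``X`` is
an NHWC float array of RGB images in [0, 1]; ``y`` is a sequence of
finest-level label sets (e.g. ``[["cool_vertical"], ["warm_horizontal",
"cool_vertical"], ...]``) or ready :class:`MultiLevelLabel` objects.

``predict``/``predict_proba`` follow sklearn's multilabel-indicator
convention at the finest level; the per-level view is available through
``predict_scores`` and ``predict_calls``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .losses import FocalParams, LevelWeights
from .model import (
    BackboneConfig,
    HierarchicalHeadConfig,
    build_flat_baseline,
    build_hierarchical_model,
)
from .synthetic import labels_to_matrices
from .taxonomy import DiseaseTaxonomy, MultiLevelLabel, expand_labels
from .training import AugmentConfig, TrainConfig, preset, train
from . import model as _model

__all__ = ["HierarchicalImageClassifier"]


class HierarchicalImageClassifier(ClassifierMixin, BaseEstimator):
    """Coarse-to-fine multi-task & multi-label image classifier.

    Parameters
    ----------
    taxonomy : DiseaseTaxonomy
        Fixes the two output layers' sizes and class order.
    architecture : {"hierarchical", "flat"}
        ``"hierarchical"`` feeds the level-1 branch's penultimate features
        into the level-2 branch; ``"flat"`` is the ablation baseline without
        inter-level connections.
    preset : {"desk", "full"}
        Training schedule preset; individual fields can be overridden.
    gamma, alpha : focal focusing parameter and level-1 loss weight.
    augment : apply on-the-fly augmentation during training.
    random_state : seed for weight init, batching and augmentation.
    """

    def __init__(
        self,
        taxonomy: DiseaseTaxonomy = None,
        architecture: str = "hierarchical",
        preset: str = "desk",
        backbone_channels: tuple[int, ...] = (16, 32, 64, 128),
        head_hidden: tuple[int, ...] = (256, 128),
        gamma: float = 2.0,
        alpha: float = 0.3,
        batch_size: int | None = None,
        stage1_epochs: int | None = None,
        stage2: tuple[tuple[int, float], ...] | None = None,
        learning_rate: float | None = None,
        adam_eps: float | None = None,
        augment: bool = True,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.taxonomy = taxonomy
        self.architecture = architecture
        self.preset = preset
        self.backbone_channels = backbone_channels
        self.head_hidden = head_hidden
        self.gamma = gamma
        self.alpha = alpha
        self.batch_size = batch_size
        self.stage1_epochs = stage1_epochs
        self.stage2 = stage2
        self.learning_rate = learning_rate
        self.adam_eps = adam_eps
        self.augment = augment
        self.threshold = threshold
        self.random_state = random_state

    # -- config assembly ----------------------------------------------------
    def _train_config(self) -> TrainConfig:
        from dataclasses import replace

        cfg = preset(self.preset)
        overrides: dict = {
            "focal": FocalParams(gamma=self.gamma),
            "weights": LevelWeights.from_alpha(self.alpha),
            "seed": self.random_state,
            "augment": AugmentConfig() if self.augment else None,
        }
        if self.batch_size is not None:
            overrides["batch_size"] = self.batch_size
        if self.stage1_epochs is not None:
            overrides["stage1_epochs"] = self.stage1_epochs
        if self.learning_rate is not None:
            overrides["stage1_lr"] = self.learning_rate
        if self.adam_eps is not None:
            overrides["adam_eps"] = self.adam_eps
        if self.stage2 is not None:
            from .training import StageStep

            overrides["stage2"] = tuple(StageStep(e, lr) for e, lr in self.stage2)
        return replace(cfg, **overrides)

    def _coerce_y(self, y, n: int) -> dict[int, np.ndarray]:
        if isinstance(y, dict):
            return {int(k): np.asarray(v, dtype=np.float32) for k, v in y.items()}
        labels = []
        for item in y:
            if isinstance(item, MultiLevelLabel):
                labels.append(item)
            else:
                ids = item.split(";") if isinstance(item, str) else list(item)
                labels.append(expand_labels(self.taxonomy, ids))
        if len(labels) != n:
            raise ValueError("X and y length mismatch")
        return labels_to_matrices(labels, self.taxonomy)

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be an NHWC RGB image array, got shape {X.shape}")
        return X

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> "HierarchicalImageClassifier":
        if self.taxonomy is None:
            raise ValueError("taxonomy is required")
        if self.architecture not in ("hierarchical", "flat"):
            raise ValueError("architecture must be 'hierarchical' or 'flat'")
        X = self._check_X(X)
        labels = self._coerce_y(y, X.shape[0])
        build = (
            build_hierarchical_model
            if self.architecture == "hierarchical"
            else build_flat_baseline
        )
        self.network_ = build(
            self.taxonomy,
            BackboneConfig(channels=tuple(self.backbone_channels)),
            HierarchicalHeadConfig(hidden=tuple(self.head_hidden)),
            seed=self.random_state,
        )
        cfg = self._train_config()
        val_labels = None
        if X_val is not None and y_val is not None:
            X_val = self._check_X(X_val)
            val_labels = self._coerce_y(y_val, X_val.shape[0])
        self.train_config_ = cfg
        self.history_ = train(
            self.network_, X, labels, cfg, val_images=X_val, val_labels=val_labels
        )
        self.classes_ = np.array(self.taxonomy.class_order[2])
        self.classes_per_level_ = {
            lvl: list(self.taxonomy.class_order[lvl]) for lvl in (1, 2)
        }
        return self

    def predict_scores(self, X, batch_size: int = 64) -> dict[int, np.ndarray]:
        """Per-level sigmoid score matrices, rows aligned with X."""
        self._require_fitted()
        X = self._check_X(X)
        chunks: dict[int, list[np.ndarray]] = {1: [], 2: []}
        for start in range(0, X.shape[0], batch_size):
            scores = self.network_.predict_scores(
                X[start : start + batch_size].transpose(0, 3, 1, 2)
            )
            for lvl in (1, 2):
                chunks[lvl].append(scores[lvl])
        return {lvl: np.concatenate(parts) for lvl, parts in chunks.items()}

    def predict_proba(self, X) -> np.ndarray:
        """Finest-level (level-2) per-class probabilities, shape (n, C2)."""
        return self.predict_scores(X)[2]

    def predict(self, X) -> np.ndarray:
        """Multilabel indicator matrix at level 2 under the strict > threshold rule."""
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def predict_calls(self, X, k: int = 3) -> list[dict[int, dict]]:
        """Per-sample screening calls and top-k rankings at every level."""
        scores = self.predict_scores(X)
        n = scores[1].shape[0]
        return [
            _model.predict_calls(
                {lvl: scores[lvl][i] for lvl in scores},
                self.taxonomy,
                threshold=self.threshold,
                k=k,
            )
            for i in range(n)
        ]

    def _require_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.multi_label = True
        return tags
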
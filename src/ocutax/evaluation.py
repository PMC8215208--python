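"""Evaluation: ROC/AUC per class, confusion matrices, k-fold CV, top-k rule.

Metric definitions (per class, at a threshold):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

ROC curves sweep all distinct score thresholds; the AUC equals the
Mann-Whitney rank statistic (probability that a random positive outranks a
random negative, ties counted 1/2).  ROC and the >threshold screening calls
are per-class sigmoid views; confusion matrices use the per-level argmax on
single-positive samples, with multi-label samples excluded and counted.

Cross-validation splits by image (5 folds by default); fold curves are
aggregated by vertical averaging of the interpolated ROC on a common
false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .taxonomy import DiseaseTaxonomy

__all__ = [
    "ConfusionCounts",
    "binary_metrics",
    "roc_auc",
    "confusion_matrix",
    "kfold_split",
    "topk_correct",
    "EvalReport",
    "evaluate_scores",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    sensitivity: float  # nan when TP + FN == 0
    specificity: float  # nan when TN + FP == 0


def binary_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    """Accuracy, sensitivity and specificity from one confusion table.

    Undefined ratios (0/0 denominators) are flagged as NaN rather than
    raising, so per-class sweeps over rare classes stay usable.
    """
    if counts.total <= 0:
        raise ValueError("confusion table is empty")
    acc = (counts.tp + counts.tn) / counts.total
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return BinaryMetrics(acc, sens, spec)


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC for one class.

    Returns ``(fpr, tpr, auc)``; the curve sweeps all distinct thresholds.
    Both label values must be present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; AUC undefined")
    fpr, tpr, _ = skm.roc_curve(y, s)
    return fpr, tpr, float(skm.roc_auc_score(y, s))


def confusion_matrix(
    scores: np.ndarray, truth: np.ndarray, n_classes: int
) -> tuple[np.ndarray, int]:
    """Per-level argmax confusion matrix over single-positive samples.

    ``truth`` is the multi-hot matrix for the level; samples with more than
    one positive (multi-label composites) are excluded from the matrix and
    returned as a count.  Rows are true classes, columns argmax predictions.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    single = truth.sum(axis=1) == 1
    excluded = int((~single).sum())
    if not single.any():
        raise ValueError("no single-positive samples to tabulate")
    y_true = truth[single].argmax(axis=1)
    y_pred = scores[single].argmax(axis=1)
    mat = skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    return mat, excluded


def kfold_split(n_samples: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded fold index per sample: disjoint, exhaustive, sizes differ by <= 1."""
    if n_samples < k:
        raise ValueError(f"need at least k={k} samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    folds = np.empty(n_samples, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def topk_correct(truth: str, topk: list) -> bool:
    """True iff the true class appears among the top-k ranked classes."""
    ids = [t[0] if isinstance(t, (tuple, list)) else t for t in topk]
    return truth in ids


# ---------------------------------------------------------------------------
# reports

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalReport:
    """Per-class and per-level evaluation results for one model on one set."""

    per_class: dict[int, dict[str, dict]]  # level -> class id -> metrics
    confusion: dict[int, dict]  # level -> {"matrix", "classes", "excluded_multilabel"}
    threshold: float
    topk_accuracy: dict[int, float] | None = None
    fold: int | None = None

    def mean_auc(self, level: int) -> float:
        aucs = [m["auc"] for m in self.per_class[level].values() if m["auc"] is not None]
        return float(np.mean(aucs))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lvl, classes in self.per_class.items():
            for cid, m in classes.items():
                rows.append(
                    {
                        "level": lvl,
                        "class": cid,
                        "auc": m["auc"],
                        "accuracy": m["accuracy"],
                        "sensitivity": m["sensitivity"],
                        "specificity": m["specificity"],
                        "n_positive": m["n_positive"],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> dict:
        return {
            "threshold": self.threshold,
            "fold": self.fold,
            "topk_accuracy": self.topk_accuracy,
            "per_class": {
                str(lvl): {
                    cid: {k: v for k, v in m.items() if k not in ("fpr", "tpr")}
                    for cid, m in classes.items()
                }
                for lvl, classes in self.per_class.items()
            },
            "confusion": {
                str(lvl): {
                    "matrix": np.asarray(c["matrix"]).tolist(),
                    "classes": c["classes"],
                    "excluded_multilabel": c["excluded_multilabel"],
                }
                for lvl, c in self.confusion.items()
            },
        }


def evaluate_scores(
    scores: Mapping[int, np.ndarray],
    labels: Mapping[int, np.ndarray],
    taxonomy: DiseaseTaxonomy,
    threshold: float = 0.5,
    k: int = 3,
) -> EvalReport:
    """Build an :class:`EvalReport` from per-level score and truth matrices."""
    per_class: dict[int, dict[str, dict]] = {}
    confusion: dict[int, dict] = {}
    topk_acc: dict[int, float] = {}
    for lvl in sorted(scores):
        s, t = np.asarray(scores[lvl], float), np.asarray(labels[lvl])
        order = taxonomy.class_order[lvl]
        per_class[lvl] = {}
        for j, cid in enumerate(order):
            y = t[:, j].astype(int)
            called = (s[:, j] > threshold).astype(int)
            counts = ConfusionCounts(
                tp=int(((called == 1) & (y == 1)).sum()),
                fp=int(((called == 1) & (y == 0)).sum()),
                tn=int(((called == 0) & (y == 0)).sum()),
                fn=int(((called == 0) & (y == 1)).sum()),
            )
            bm = binary_metrics(counts)
            if len(np.unique(y)) == 2:
                fpr, tpr, auc = roc_auc(s[:, j], y)
            else:  # class absent (or universal) in this split: AUC undefined
                fpr = tpr = np.array([])
                auc = None
            per_class[lvl][cid] = {
                "auc": auc,
                "accuracy": bm.accuracy,
                "sensitivity": bm.sensitivity,
                "specificity": bm.specificity,
                "n_positive": int(y.sum()),
                "fpr": fpr,
                "tpr": tpr,
            }
        mat, excluded = confusion_matrix(s, t, len(order))
        confusion[lvl] = {
            "matrix": mat,
            "classes": list(order),
            "excluded_multilabel": excluded,
        }
        # top-k over single-positive samples
        single = t.sum(axis=1) == 1
        if single.any():
            truths = t[single].argmax(axis=1)
            kk = min(k, len(order))
            ranked = np.argsort(-s[single], axis=1, kind="stable")[:, :kk]
            topk_acc[lvl] = float(np.mean([tr in row for tr, row in zip(truths, ranked)]))
    return EvalReport(
        per_class=per_class, confusion=confusion, threshold=threshold, topk_accuracy=topk_acc
    )


def mean_roc(reports: list[EvalReport], level: int, class_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Vertical (threshold-averaged) mean ROC across folds on a common FPR grid."""
    tprs = []
    for rep in reports:
        m = rep.per_class[level][class_id]
        if m["auc"] is None:
            continue
        tprs.append(np.interp(FPR_GRID, m["fpr"], m["tpr"]))
    if not tprs:
        raise ValueError(f"no fold has a defined ROC for class {class_id!r}")
    return FPR_GRID, np.mean(tprs, axis=0)


def cross_validate(
    images: np.ndarray,
    labels: Mapping[int, np.ndarray],
    taxonomy: DiseaseTaxonomy,
    estimator_factory: Callable[[], "object"],
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """k-fold cross-validation: train on k-1 folds, score the held-out fold.

    Returns per-fold reports, fold assignments, the across-fold mean per-class
    AUC and the vertically averaged mean ROC per class.
    """
    n = images.shape[0]
    folds = kfold_split(n, k=k, seed=seed)
    reports: list[EvalReport] = []
    for f in range(k):
        val = folds == f
        est = estimator_factory()
        est.fit(images[~val], {lvl: labels[lvl][~val] for lvl in (1, 2)})
        scores = est.predict_scores(images[val])
        rep = evaluate_scores(
            scores, {lvl: labels[lvl][val] for lvl in (1, 2)}, taxonomy, threshold
        )
        rep.fold = f
        reports.append(rep)
    mean_auc = {
        lvl: {
            cid: _nanmean([r.per_class[lvl][cid]["auc"] for r in reports])
            for cid in taxonomy.class_order[lvl]
        }
        for lvl in (1, 2)
    }
    mean_curves = {}
    for lvl in (1, 2):
        mean_curves[lvl] = {}
        for cid in taxonomy.class_order[lvl]:
            try:
                mean_curves[lvl][cid] = mean_roc(reports, lvl, cid)
            except ValueError:
                mean_curves[lvl][cid] = None
    return {
        "folds": folds,
        "reports": reports,
        "mean_auc": mean_auc,
        "mean_roc": mean_curves,
        "aggregation": "vertical threshold-averaging on a common FPR grid",
    }


def _nanmean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None
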
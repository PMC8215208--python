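import numpy as np
import pytest

from ocutax.evaluation import (
    ConfusionCounts,
    EvalReport,
    binary_metrics,
    confusion_matrix,
    cross_validate,
    evaluate_scores,
    kfold_split,
    mean_roc,
    roc_auc,
    topk_correct,
)


def brute_force_auc(scores, labels):
    """Pairwise rank oracle: P(random positive outranks random negative)."""
    s = np.asarray(scores, float)
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_binary_metrics_arithmetic():
    m = binary_metrics(ConfusionCounts(tp=91, fn=9, tn=90, fp=10))
    assert m.sensitivity == pytest.approx(0.91)
    assert m.specificity == pytest.approx(0.90)
    assert m.accuracy == pytest.approx(0.905)

    perfect = binary_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
    assert (perfect.accuracy, perfect.sensitivity, perfect.specificity) == (1, 1, 1)

    no_pos = binary_metrics(ConfusionCounts(tp=0, fn=0, tn=9, fp=1))
    assert np.isnan(no_pos.sensitivity)  # 0/0 flagged, not raised
    with pytest.raises(ValueError):
        binary_metrics(ConfusionCounts(0, 0, 0, 0))


def test_roc_auc_worked_example_and_edges():
    fpr, tpr, auc = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
    assert auc == 0.75  # 3 of 4 positive-negative pairs concordant
    _, _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    with pytest.raises(ValueError, match="single class"):
        roc_auc([0.3, 0.4], [1, 1])


def test_roc_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    for _ in range(60):
        n = int(rng.integers(4, 60))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-9)


def test_roc_auc_random_scores_near_half():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, 2000)
    scores = rng.random(2000)
    _, _, auc = roc_auc(scores, labels)
    assert auc == pytest.approx(0.5, abs=0.03)


def test_confusion_matrix_tally_and_exclusions():
    rng = np.random.default_rng(1)
    n, c = 30, 3
    scores = rng.random((n, c))
    truth = np.zeros((n, c), dtype=int)
    truth[np.arange(n), rng.integers(0, c, n)] = 1
    truth[0] = [1, 1, 0]  # one multi-label row -> excluded
    mat, excluded = confusion_matrix(scores, truth, c)
    assert excluded == 1
    assert mat.sum() == n - 1  # conservation
    # brute-force tally
    manual = np.zeros((c, c), dtype=int)
    for i in range(1, n):
        manual[truth[i].argmax(), scores[i].argmax()] += 1
    np.testing.assert_array_equal(mat, manual)

    perfect = np.eye(c)
    mat, _ = confusion_matrix(perfect, np.eye(c, dtype=int), c)
    np.testing.assert_array_equal(mat, np.eye(c, dtype=int))
    constant = np.tile([0.9, 0.1, 0.0], (c, 1))
    mat, _ = confusion_matrix(constant, np.eye(c, dtype=int), c)
    assert (mat[:, 1:] == 0).all() and mat[:, 0].sum() == c


def test_kfold_split_properties():
    folds = kfold_split(100, k=5, seed=0)
    sizes = np.bincount(folds, minlength=5)
    assert (sizes == 20).all()
    rng = np.random.default_rng(3)
    for _ in range(40):
        n = int(rng.integers(5, 500))
        f1 = kfold_split(n, k=5, seed=11)
        f2 = kfold_split(n, k=5, seed=11)
        np.testing.assert_array_equal(f1, f2)  # seeded determinism
        sizes = np.bincount(f1, minlength=5)
        assert sizes.sum() == n and sizes.max() - sizes.min() <= 1
    with pytest.raises(ValueError):
        kfold_split(3, k=5)


def test_topk_rule():
    ranked = [("a", 0.9), ("b", 0.5), ("c", 0.4)]
    assert topk_correct("c", ranked)  # position 3 of 3 still correct
    assert not topk_correct("d", ranked)
    assert topk_correct("a", ranked[:1])  # k=1 reduces to argmax accuracy


def test_evaluate_scores_report_structure(desk):
    rng = np.random.default_rng(5)
    n = 40
    t2 = np.zeros((n, 4), dtype=int)
    t2[np.arange(n), rng.integers(0, 4, n)] = 1
    t1 = np.zeros((n, 2), dtype=int)
    t1[:, 0] = t2[:, :2].max(axis=1)
    t1[:, 1] = t2[:, 2:].max(axis=1)
    scores = {1: rng.random((n, 2)), 2: rng.random((n, 4))}
    rep = evaluate_scores(scores, {1: t1, 2: t2}, desk, threshold=0.5)
    assert set(rep.per_class[1]) == set(desk.class_order[1])
    assert rep.confusion[2]["matrix"].sum() == n
    df = rep.to_frame()
    assert len(df) == 2 + 4
    js = rep.to_json()
    assert "per_class" in js and "confusion" in js
    assert 0 <= rep.topk_accuracy[2] <= 1


def test_cross_validate_plumbing(desk, tiny_dataset):
    from ocutax.estimator import HierarchicalImageClassifier

    cfg, X, records, labels = tiny_dataset

    def factory():
        return HierarchicalImageClassifier(
            taxonomy=desk,
            backbone_channels=(8, 16),
            head_hidden=(32, 16),
            stage1_epochs=1,
            stage2=((1, 1e-4),),
            learning_rate=1e-3,
            adam_eps=1e-8,
            augment=False,
            random_state=0,
        )

    result = cross_validate(X, labels, desk, factory, k=3, seed=2)
    assert len(result["reports"]) == 3
    assert sorted(np.unique(result["folds"])) == [0, 1, 2]
    # union of validation folds covers every sample exactly once
    assert len(result["folds"]) == X.shape[0]
    for lvl in (1, 2):
        for cid in desk.class_order[lvl]:
            assert cid in result["mean_auc"][lvl]
    curve = result["mean_roc"][1][desk.class_order[1][0]]
    assert curve is not None and curve[1].shape == curve[0].shape
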
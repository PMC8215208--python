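import numpy as np
import pytest

from ocutax import autodiff as ad
from ocutax.losses import FocalParams, LevelWeights
from ocutax.model import (
    BackboneConfig,
    HierarchicalHeadConfig,
    build_flat_baseline,
    build_hierarchical_model,
    load_checkpoint,
    predict_calls,
    save_checkpoint,
)

SMALL = BackboneConfig(channels=(8, 16))
HEADS = HierarchicalHeadConfig(hidden=(32, 16))


def _batch(rng, n=4, size=32):
    return rng.random((n, 3, size, size)).astype(np.float32)


def test_output_sizes_follow_taxonomy(anterior, retinal):
    rng = np.random.default_rng(0)
    for tax, (n1, n2) in [(anterior, (4, 9)), (retinal, (3, 8))]:
        net = build_hierarchical_model(tax, SMALL, HEADS, seed=1)
        res = net.forward(_batch(rng))
        assert res.probs[1].shape == (4, n1)
        assert res.probs[2].shape == (4, n2)
        assert (res.probs[1].data >= 0).all() and (res.probs[1].data <= 1).all()
        # sigmoids are independent: scores need not sum to 1
        assert not np.allclose(res.probs[2].data.sum(axis=1), 1.0)


def test_level2_branch_consumes_concatenated_features(desk):
    net = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    d = net.backbone.feature_dim
    assert net.head2.layers[0][0].shape[0] == d + net.head1.penultimate_dim
    flat = build_flat_baseline(desk, SMALL, HEADS, seed=0)
    assert flat.head2.layers[0][0].shape[0] == d


def test_flat_baseline_is_smaller_but_same_shapes(desk):
    rng = np.random.default_rng(1)
    hier = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    flat = build_flat_baseline(desk, SMALL, HEADS, seed=0)
    n_hier = sum(p.data.size for p in hier.parameters())
    n_flat = sum(p.data.size for p in flat.parameters())
    assert n_flat < n_hier
    x = _batch(rng)
    for lvl in (1, 2):
        assert hier.forward(x).probs[lvl].shape == flat.forward(x).probs[lvl].shape


def test_forward_is_deterministic_and_batch_consistent(desk):
    rng = np.random.default_rng(2)
    net = build_hierarchical_model(desk, SMALL, HEADS, seed=3)
    x = _batch(rng, n=2)
    dup = np.concatenate([x, x[:1]])  # duplicate first image
    s1 = net.predict_scores(dup)
    s2 = net.predict_scores(dup)
    for lvl in (1, 2):
        np.testing.assert_array_equal(s1[lvl], s2[lvl])
        np.testing.assert_array_equal(s1[lvl][0], s1[lvl][2])


def test_seed_controls_initialization(desk):
    a = build_hierarchical_model(desk, SMALL, HEADS, seed=5)
    b = build_hierarchical_model(desk, SMALL, HEADS, seed=5)
    c = build_hierarchical_model(desk, SMALL, HEADS, seed=6)
    np.testing.assert_array_equal(a.head1.out_w.data, b.head1.out_w.data)
    assert not np.array_equal(a.head1.out_w.data, c.head1.out_w.data)


def test_flat_level2_gradients_do_not_touch_level1_branch(desk):
    rng = np.random.default_rng(4)
    flat = build_flat_baseline(desk, SMALL, HEADS, seed=0)
    res = flat.forward(_batch(rng))
    t2 = np.zeros(res.probs[2].shape, dtype=np.float32)
    t2[:, 0] = 1
    loss2 = ad.focal_loss(res.probs[2], t2, FocalParams())
    loss2.backward()
    assert all(p.grad is None or not p.grad.any() for p in flat.head1.params)

    hier = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    res = hier.forward(_batch(rng))
    loss2 = ad.focal_loss(res.probs[2], t2, FocalParams())
    loss2.backward()
    # in the hierarchical wiring the level-2 loss reaches the level-1 branch
    assert any(p.grad is not None and p.grad.any() for p in hier.head1.params[:2])


def test_wrong_input_shape_raises(desk):
    net = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    with pytest.raises(ValueError, match="NCHW"):
        net.forward(np.zeros((2, 32, 32, 3), dtype=np.float32))


def test_overfit_sanity_small_batch(desk):
    """Capacity check: the default backbone drives the total loss below 0.01
    on a 16-image synthetic batch within 200 optimization steps."""
    from ocutax.synthetic import SynthConfig, generate_arrays, labels_to_matrices

    cfg = SynthConfig(
        taxonomy=desk,
        image_size=32,
        n_per_class={c: 4 for c in desk.class_order[2]},
        composite_fraction=0.0,
        noise_sd=0.01,
        seed=9,
    )
    X, records = generate_arrays(cfg)
    labels = labels_to_matrices([r.label for r in records], desk)
    net = build_hierarchical_model(desk, seed=0)  # default backbone
    opt = ad.Adam(net.parameters(), lr=3e-3)
    x = X.transpose(0, 3, 1, 2)
    w = LevelWeights.from_alpha(0.3)
    loss_value = np.inf
    for step in range(200):
        res = net.forward(x)
        l1 = ad.focal_loss(res.probs[1], labels[1], FocalParams())
        l2 = ad.focal_loss(res.probs[2], labels[2], FocalParams())
        loss = ad.weighted_sum([l1, l2], w.weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_value = float(loss.data)
        if loss_value < 0.01:
            break
    assert loss_value < 0.01


def test_predict_calls_threshold_and_topk(anterior):
    order1 = anterior.class_order[1]
    scores1 = np.zeros(4)
    scores1[order1.index("cataract")] = 0.7674
    scores1[order1.index("ocular_surface")] = 0.7594
    calls = predict_calls({1: scores1}, anterior, threshold=0.5, k=3)
    assert set(calls[1]["positive"]) == {"cataract", "ocular_surface"}
    assert calls[1]["topk"][0] == ("cataract", 0.7674)

    # a score of exactly 0.5 is NOT positive (strict > rule)
    s = np.full(4, 0.5)
    calls = predict_calls({1: s}, anterior, threshold=0.5, k=10)
    assert calls[1]["positive"] == []
    assert len(calls[1]["topk"]) == 4  # k truncated to class count
    # ties broken by class-order position
    assert [c for c, _ in calls[1]["topk"]] == order1

    calls = predict_calls({1: np.zeros(4)}, anterior, threshold=0.5, k=2)
    assert calls[1]["positive"] == [] and len(calls[1]["topk"]) == 2


def test_checkpoint_guards_taxonomy(tmp_path, desk, anterior):
    net = build_hierarchical_model(desk, SMALL, HEADS, seed=0)
    path = tmp_path / "m.ckpt"
    save_checkpoint(net, path)
    again = load_checkpoint(path, desk)
    x = np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32)
    np.testing.assert_array_equal(
        net.predict_scores(x)[2], again.predict_scores(x)[2]
    )
    with pytest.raises(ValueError, match="different taxonomy"):
        load_checkpoint(path, anterior)
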
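"""Losses, aggregation, augmentation, network gradients, training loop."""

import numpy as np
import pytest

from evtrack import MultiChannelFrame, SceneParams, generate_scene
from evtrack._nn import DualUNet, Conv2d, sigmoid, softmax_channels
from evtrack.dual_unet import (
    ModelConfig,
    AugmentConfig,
    dice_loss,
    smooth_l1,
    aggregate_channel,
    augment,
    train_model,
    training_targets,
    save_checkpoint,
    load_checkpoint,
    _loss_and_grads,
    _smooth_l1_batched,
    _dice_loss_batched,
    _onehot,
)

# ---------------------------------------------------------------- dice loss


def test_dice_perfect_prediction_is_zero():
    target = np.array([[0, 1], [2, 1]])
    pred = np.eye(3)[target].transpose(2, 0, 1)
    assert dice_loss(pred, target) == pytest.approx(0.0, abs=1e-6)


def test_dice_disjoint_prediction_is_one():
    target = np.zeros((2, 2), dtype=int)          # all class 0
    pred = np.zeros((2, 2, 2))
    pred[1] = 1.0                                  # all mass on class 1
    assert dice_loss(pred, target) == pytest.approx(1.0, abs=1e-5)


def test_dice_uniform_two_pixel_hand_computation():
    # 2 pixels, 2 classes, target [A, B], uniform prediction:
    # per-class Dice = (2*0.5)/(1+1) = 0.5 -> loss 0.5
    target = np.array([[0, 1]])
    pred = np.full((2, 1, 2), 0.5)
    assert dice_loss(pred, target) == pytest.approx(0.5, abs=1e-6)


def test_dice_brute_force_random_grids():
    rng = np.random.default_rng(0)
    for _ in range(20):
        c, h, w = 3, 4, 5
        logits = rng.normal(size=(c, h, w))
        pred = np.exp(logits) / np.exp(logits).sum(axis=0)
        target = rng.integers(0, c, (h, w))
        t = np.eye(c)[target].transpose(2, 0, 1)
        eps = 1e-6
        brute = 1.0 - np.mean([
            (2 * (pred[k] * t[k]).sum() + eps) / (pred[k].sum() + t[k].sum() + eps)
            for k in range(c)])
        assert dice_loss(pred, target) == pytest.approx(brute, abs=1e-12)


def test_dice_symmetric_for_onehot_and_bounded():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 3, (6, 6))
    b = rng.integers(0, 3, (6, 6))
    pa = np.eye(3)[a].transpose(2, 0, 1)
    pb = np.eye(3)[b].transpose(2, 0, 1)
    assert dice_loss(pa, b) == pytest.approx(dice_loss(pb, a), abs=1e-12)
    assert 0.0 <= dice_loss(pa, b) <= 1.0


def test_dice_shape_mismatch_raises():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((3, 4, 4)), np.zeros((5, 5), dtype=int))


# ------------------------------------------------------------ smooth L1


def test_smooth_l1_closed_forms():
    z = np.zeros((3, 3))
    assert smooth_l1(z, z) == 0.0
    assert smooth_l1(np.array([[2.0]]), np.array([[0.0]]), beta=1.0) == pytest.approx(1.5)
    assert smooth_l1(np.array([[0.5]]), np.array([[0.0]]), beta=1.0) == pytest.approx(0.125)


def test_smooth_l1_limits():
    rng = np.random.default_rng(2)
    d = rng.normal(size=(8, 8))
    target = np.zeros_like(d)
    # beta -> 0 converges to mean absolute error
    assert smooth_l1(d, target, beta=1e-9) == pytest.approx(np.abs(d).mean(), rel=1e-6)
    # |d| < beta behaves as 0.5 d^2 / beta (scaled L2); with beta=1, 0.5 d^2
    small = 0.3 * d / np.abs(d).max()
    assert smooth_l1(small, target, beta=1.0) == pytest.approx(
        (0.5 * small ** 2).mean(), rel=1e-9)


def test_smooth_l1_shape_mismatch_raises():
    with pytest.raises(ValueError):
        smooth_l1(np.zeros((2, 2)), np.zeros((3, 3)))


# ------------------------------------------------------------- aggregation


def _frame_from(planes):
    return MultiChannelFrame(*[np.asarray(p, dtype=float) for p in planes])


def test_aggregate_single_active_plane():
    ev = np.array([[0.0, 2.0], [4.0, 0.0]])
    frame = _frame_from([np.zeros((2, 2)), ev, np.zeros((2, 2))])
    agg = aggregate_channel(frame)
    assert np.allclose(agg, ev / 4.0)


def test_aggregate_all_zero_and_max_rule():
    frame = _frame_from([np.zeros((2, 2))] * 3)
    assert not aggregate_channel(frame).any()
    # per-pixel max after per-plane normalization: normalized values
    # (0.2, 0.9, 0.4) at the middle pixel -> 0.9
    a = np.array([[0.0, 0.2, 1.0]])
    b = np.array([[0.0, 0.9, 1.0]])
    c = np.array([[0.0, 0.4, 1.0]])
    frame = _frame_from([a, b, c])
    assert aggregate_channel(frame)[0, 1] == pytest.approx(0.9)


# ------------------------------------------------------------ augmentation


@pytest.fixture
def aug_sample(small_scene):
    _, frame, truth = small_scene
    x = aggregate_channel(frame)
    return x, training_targets(truth)


def test_augment_zero_probabilities_is_identity(aug_sample):
    x, (d, c) = aug_sample
    cfg = AugmentConfig(p_flip=0, p_contrast=0, p_scale=0, p_blur=0, p_noise=0)
    xa, (da, ca) = augment(x, (d, c), cfg, seed=3)
    assert np.array_equal(xa, x) and np.array_equal(da, d) and np.array_equal(ca, c)


def test_augment_flip_is_involution(aug_sample):
    x, (d, c) = aug_sample
    cfg = AugmentConfig(p_flip=1.0, p_contrast=0, p_scale=0, p_blur=0, p_noise=0)
    once = augment(x, (d, c), cfg, seed=5)
    twice = augment(once[0], once[1], cfg, seed=5)   # same seed -> same axis
    assert np.array_equal(twice[0], x)
    assert np.array_equal(twice[1][1], c)


def test_augment_deterministic_and_geometry_consistent(aug_sample):
    x, (d, c) = aug_sample
    cfg = AugmentConfig(p_flip=0.5, p_contrast=0.5, p_scale=0.5, p_blur=0.5, p_noise=0.5)
    r1 = augment(x, (d, c), cfg, seed=17)
    r2 = augment(x, (d, c), cfg, seed=17)
    assert np.array_equal(r1[0], r2[0])
    assert np.array_equal(r1[1][0], r2[1][0])
    assert np.array_equal(r1[1][1], r2[1][1])
    # photometric-only transforms leave the targets untouched
    cfg_photo = AugmentConfig(p_flip=0, p_scale=0, p_contrast=1.0, p_blur=1.0, p_noise=1.0)
    _, (da, ca) = augment(x, (d, c), cfg_photo, seed=23)
    assert np.array_equal(da, d) and np.array_equal(ca, c)


def test_augment_default_probabilities_in_band():
    cfg = AugmentConfig()
    for name in ("p_flip", "p_contrast", "p_scale", "p_blur", "p_noise"):
        assert 0.25 <= getattr(cfg, name) <= 0.3
    with pytest.raises(ValueError):
        AugmentConfig(p_flip=1.5).validate()


# ------------------------------------------------------- network gradients


def test_network_gradients_match_numerical():
    rng = np.random.default_rng(0)
    net = DualUNet(depth=2, base_features=8, seed=1)
    x = rng.random((1, 1, 8, 8)).astype(np.float32)
    dmap = rng.random((1, 8, 8))
    cmap = rng.integers(0, 3, (1, 8, 8))
    cfg = ModelConfig(depth=2, base_features=8)

    def total_loss():
        reg, cls = net.forward(x)
        s = sigmoid(reg[:, 0])
        p = softmax_channels(cls.astype(np.float64))
        t = np.stack([_onehot(c, 3) for c in cmap])
        l1, _ = _smooth_l1_batched(s, dmap, 1.0, fg_weight=cfg.reg_fg_weight)
        l2, _ = _dice_loss_batched(p, t, 1e-6)
        return l1 + l2

    _loss_and_grads(net, x, dmap, cmap, cfg)
    convs = [ly for ly in net._layers() if isinstance(ly, Conv2d)]
    checked = 0
    for ly in convs[::2]:
        flat = ly.W.ravel()
        for idx in rng.integers(0, flat.size, 3):
            eps = 1e-3
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = total_loss()
            flat[idx] = orig - eps
            lm = total_loss()
            flat[idx] = orig
            numerical = (lp - lm) / (2 * eps)
            analytical = ly.dW.ravel()[idx]
            assert numerical == pytest.approx(analytical, abs=2e-3), (
                f"gradient mismatch at conv weight {idx}")
            checked += 1
    assert checked >= 9


# ------------------------------------------------------------ training loop


def _tiny_dataset(n=4, seed0=100):
    return [generate_scene(SceneParams(seed=seed0 + i, image_size=(64, 64),
                                       n_cells=2, n_evs_internal=3,
                                       n_evs_external=2))
            for i in range(n)]


def test_train_zero_epochs_returns_init():
    run = train_model(_tiny_dataset(2), ModelConfig(base_features=8), epochs=0, seed=1)
    assert run.history == []
    assert run.model is not None


def test_train_loss_decreases_and_history_recorded():
    run = train_model(_tiny_dataset(4), ModelConfig(base_features=8),
                      AugmentConfig(), epochs=5, seed=1)
    assert len(run.history) == 5
    assert all(np.isfinite(h["total"]) for h in run.history)
    assert run.history[-1]["total"] <= run.history[0]["total"]


def test_train_same_seed_identical_history():
    r1 = train_model(_tiny_dataset(2), ModelConfig(base_features=8), epochs=2, seed=9)
    r2 = train_model(_tiny_dataset(2), ModelConfig(base_features=8), epochs=2, seed=9)
    assert r1.history == r2.history


def test_train_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train_model([], ModelConfig(), epochs=1)


def test_checkpoint_roundtrip(tmp_path):
    run = train_model(_tiny_dataset(2), ModelConfig(base_features=8), epochs=1, seed=3)
    save_checkpoint(tmp_path / "ckpt", run)
    loaded = load_checkpoint(tmp_path / "ckpt")
    assert loaded.history == run.history
    for k, v in run.model.state_dict().items():
        assert np.array_equal(loaded.model.state_dict()[k], v)
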
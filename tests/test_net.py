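"""Attention-DFCNN: SE-block oracles, forward contracts, gradients."""

import math

import numpy as np
import pytest

from semgshift.net import (
    ModelConfig,
    build_model,
    load_model,
    make_optimizer,
    save_model,
    se_excite,
    se_scale,
    se_squeeze,
)

TINY = dict(
    n_classes=3,
    conv_channels=(4, 6, 8),
    se_reduction=4,
    hidden_units=(10, 8, 6),
    seed=3,
)


# -- SE-block oracles --------------------------------------------------------


def test_se_squeeze_is_spatial_mean():
    u = np.full((2, 3, 5), 1.25)
    np.testing.assert_allclose(se_squeeze(u), np.full(5, 1.25))
    one = np.arange(4.0).reshape(1, 1, 4)
    np.testing.assert_allclose(se_squeeze(one), one[0, 0])
    u = np.array([1.0, 2.0, 3.0, 6.0]).reshape(2, 2, 1)
    assert se_squeeze(u)[0] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        se_squeeze(np.zeros((3, 5)))


def test_se_excite_zero_weights_gate_half():
    z = np.array([0.3, -1.2])
    s = se_excite(z, np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2))
    np.testing.assert_allclose(s, 0.5)


def test_se_excite_matches_scalar_hand_computation():
    z = np.array([1.0, -2.0])
    w1 = np.array([[0.5, -1.0], [0.25, 0.75]])
    b1 = np.array([0.1, -0.2])
    w2 = np.array([[1.0, 0.5], [-0.5, 2.0]])
    b2 = np.array([0.0, 0.3])
    # scalar path: h = relu(z W1 + b1); s = sigmoid(h W2 + b2)
    h0 = max(0.0, 1.0 * 0.5 + (-2.0) * 0.25 + 0.1)
    h1 = max(0.0, 1.0 * (-1.0) + (-2.0) * 0.75 - 0.2)
    s0 = 1.0 / (1.0 + math.exp(-(h0 * 1.0 + h1 * (-0.5) + 0.0)))
    s1 = 1.0 / (1.0 + math.exp(-(h0 * 0.5 + h1 * 2.0 + 0.3)))
    np.testing.assert_allclose(se_excite(z, w1, b1, w2, b2)[0], [s0, s1])


def test_se_excite_gate_in_open_interval():
    rng = np.random.default_rng(0)
    s = se_excite(rng.normal(size=(10, 8)), rng.normal(size=(8, 2)), rng.normal(size=2), rng.normal(size=(2, 8)), rng.normal(size=8))
    assert ((s > 0) & (s < 1)).all()
    with pytest.raises(ValueError):
        se_excite(np.zeros(8), np.zeros((4, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4))


def test_se_scale_elementwise():
    u = np.arange(8.0).reshape(2, 2, 2)
    np.testing.assert_array_equal(se_scale(u, np.ones(2)), u)
    np.testing.assert_array_equal(se_scale(u, np.zeros(2)), np.zeros_like(u))
    scaled = se_scale(u, np.array([0.5, 2.0]))
    np.testing.assert_allclose(scaled[..., 0], u[..., 0] * 0.5)
    np.testing.assert_allclose(scaled[..., 1], u[..., 1] * 2.0)
    with pytest.raises(ValueError):
        se_scale(u, np.ones(3))


# -- model contracts ---------------------------------------------------------


def test_forward_output_shape_and_normalization():
    model = build_model(ModelConfig(input_shape=(8, 12), n_classes=9, seed=0))
    x = np.random.default_rng(0).random((5, 8, 12)).astype(np.float32)
    logp = model.forward(x)
    assert logp.shape == (5, 9)
    np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, atol=1e-6)


def test_forward_finite_on_degenerate_input():
    model = build_model(ModelConfig(input_shape=(4, 24), n_classes=9, seed=1))
    assert np.isfinite(model.forward(np.zeros((2, 4, 24)))).all()


def test_forward_batch_equivariance():
    model = build_model(ModelConfig(input_shape=(6, 12), n_classes=9, seed=2))
    x = np.random.default_rng(1).random((6, 6, 12)).astype(np.float32)
    logp = model.forward(x)
    perm = np.array([3, 0, 5, 1, 4, 2])
    np.testing.assert_array_equal(model.forward(x[perm]), logp[perm])


def test_seeded_builds_are_bit_identical():
    cfg = ModelConfig(input_shape=(8, 12), n_classes=9, seed=7)
    x = np.random.default_rng(2).random((3, 8, 12)).astype(np.float32)
    np.testing.assert_array_equal(build_model(cfg).forward(x), build_model(cfg).forward(x))
    other = build_model(ModelConfig(input_shape=(8, 12), n_classes=9, seed=8))
    assert not np.array_equal(other.forward(x), build_model(cfg).forward(x))


def test_shape_validation():
    with pytest.raises(ValueError):
        ModelConfig(input_shape=(2, 24))
    model = build_model(ModelConfig(input_shape=(8, 12)))
    with pytest.raises(ValueError):
        model.forward(np.zeros((2, 4, 24)))


def test_untrained_model_predicts_at_chance():
    """Random-weight networks on balanced random inputs score ~1/9."""
    accs = []
    for seed in range(20):
        model = build_model(ModelConfig(input_shape=(8, 12), n_classes=9, seed=seed))
        rng = np.random.default_rng(1000 + seed)
        x = rng.random((180, 8, 12)).astype(np.float32)
        y = np.repeat(np.arange(9), 20)
        accs.append(np.mean(model.predict(x) == y))
    assert abs(np.mean(accs) - 1 / 9) < 0.03


def test_se_bypass_equals_gate_free_network():
    x = np.random.default_rng(3).random((4, 8, 12)).astype(np.float32)
    gated = build_model(ModelConfig(input_shape=(8, 12), seed=5, se_enabled=True))
    gated.se_bypass = True
    plain = build_model(ModelConfig(input_shape=(8, 12), seed=5, se_enabled=False))
    np.testing.assert_array_equal(gated.forward(x), plain.forward(x))


@pytest.mark.parametrize("shape", [(8, 12), (4, 24), (6, 12), (3, 24)])
def test_parameter_count_formula(shape):
    """Parameters depend on input shape only through the flatten width."""
    h, w = shape
    c1, c2, c3 = 32, 64, 128
    conv = (9 * 1 * c1 + c1) + (9 * c1 * c2 + c2) + (9 * c2 * c3 + c3) + (c1 * c3 + c3)
    se = c3 * (c3 // 4) + c3 // 4 + (c3 // 4) * c3 + c3
    flat = h * w * c3
    dense = (flat * 512 + 512) + (512 * 256 + 256) + (256 * 64 + 64) + (64 * 9 + 9)
    model = build_model(ModelConfig(input_shape=shape, n_classes=9))
    assert model.n_parameters() == conv + se + dense


def test_gradients_match_finite_differences():
    cfg = ModelConfig(input_shape=(4, 5), dropout_rate=0.0, dtype="float64", **TINY)
    model = build_model(cfg)
    rng = np.random.default_rng(0)
    x = rng.random((7, 4, 5))
    y = rng.integers(0, 3, 7)
    for p in model.params:
        p.grad[...] = 0
    model.loss_and_grad(x, y, train=False)
    analytic = [p.grad.copy() for p in model.params]

    def loss():
        return -float(model.forward(x)[np.arange(len(y)), y].mean())

    for p, g in zip(model.params, analytic):
        for _ in range(2):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps, old = 1e-6, p.value[idx]
            p.value[idx] = old + eps
            up = loss()
            p.value[idx] = old - eps
            down = loss()
            p.value[idx] = old
            num = (up - down) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-5 * max(1.0, abs(num))


def test_training_reduces_loss():
    cfg = ModelConfig(input_shape=(4, 5), dropout_rate=0.0, **TINY)
    model = build_model(cfg)
    opt = make_optimizer(model, lr=1e-3)
    rng = np.random.default_rng(0)
    x = rng.random((32, 4, 5)).astype(np.float32)
    y = rng.integers(0, 3, 32)
    losses = []
    for _ in range(30):
        opt.zero_grad()
        losses.append(model.loss_and_grad(x, y, train=False))
        opt.step()
    assert losses[-1] < losses[0]


def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(input_shape=(4, 5), **TINY)
    model = build_model(cfg)
    x = np.random.default_rng(4).random((2, 4, 5)).astype(np.float32)
    path = tmp_path / "model.npz"
    save_model(model, path)
    restored = load_model(path)
    assert restored.cfg == cfg
    np.testing.assert_array_equal(restored.forward(x), model.forward(x))
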
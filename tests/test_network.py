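"""Unit and property tests for the deep memory capsule network."""

import math

import numpy as np
import pytest

from capsite import _tape as T
from capsite.features import FeatureBundle
from capsite.network import (
    CapsuleLayerParams,
    LstmParams,
    ModelConfig,
    deep_memory_forward,
    dynamic_routing,
    init_params,
    lstm_step,
    model_forward,
    routing_softmax,
    squash,
    stratified_split,
    train_model,
)


def _zero_lstm(input_size, hidden):
    z = lambda shape: T.Tensor(np.zeros(shape))
    w = (input_size + hidden, hidden)
    return LstmParams(z(w), z(w), z(w), z(w), z(hidden), z(hidden), z(hidden),
                      z(hidden), hidden)


def _random_lstm(rng, input_size, hidden):
    t = lambda shape: T.Tensor(rng.standard_normal(shape))
    w = (input_size + hidden, hidden)
    return LstmParams(t(w), t(w), t(w), t(w), t(hidden), t(hidden), t(hidden),
                      t(hidden), hidden)


# -- memory cell ---------------------------------------------------------------


def test_lstm_step_all_zero_parameters():
    """sigmoid(0)=0.5 for every gate, tanh(0)=0 kills the state."""
    params = _zero_lstm(3, 2)
    h, M, O = lstm_step(np.ones(3), np.zeros(2), np.zeros(2), params)
    np.testing.assert_allclose(M.data, 0.0)
    np.testing.assert_allclose(O.data, 0.0)
    z = T.concatenate([T.Tensor(np.zeros(2)), T.Tensor(np.ones(3))], axis=0)
    f = T.sigmoid(z @ params.W_f + params.b_f)
    np.testing.assert_allclose(f.data, 0.5)


def test_lstm_step_pure_carry():
    """Huge forget bias, zero candidate path: the cell state passes through."""
    params = _zero_lstm(3, 2)
    params.b_f = T.Tensor(np.full(2, 50.0))  # f -> 1
    params.b_r = T.Tensor(np.full(2, -50.0))  # r -> 0
    M_prev = np.array([0.3, -0.7])
    _, M, _ = lstm_step(np.ones(3), np.zeros(2), M_prev, params)
    np.testing.assert_allclose(M.data, M_prev, atol=1e-12)


def test_lstm_step_matches_scalar_recurrence(rng):
    """The vectorized step reproduces a hand-rolled scalar evaluation of the
    gate equations on a 2-unit cell."""
    params = _random_lstm(rng, 3, 2)
    m_t = rng.standard_normal(3)
    h_prev = rng.standard_normal(2)
    M_prev = rng.standard_normal(2)
    h, M, O = lstm_step(m_t, h_prev, M_prev, params)

    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    z = list(h_prev) + list(m_t)
    for unit in range(2):
        f = sig(sum(z[k] * params.W_f.data[k, unit] for k in range(5))
                + params.b_f.data[unit])
        r = sig(sum(z[k] * params.W_r.data[k, unit] for k in range(5))
                + params.b_r.data[unit])
        m_tilde = math.tanh(
            sum(z[k] * params.W_M.data[k, unit] for k in range(5))
            + params.b_M.data[unit]
        )
        m_new = f * M_prev[unit] + r * m_tilde
        g = sig(sum(z[k] * params.W_g.data[k, unit] for k in range(5))
                + params.b_g.data[unit])
        o = g * math.tanh(m_new)
        assert abs(M.data[unit] - m_new) < 1e-12
        assert abs(O.data[unit] - o) < 1e-12
        assert abs(h.data[unit] - o) < 1e-12


def test_gate_activations_in_unit_interval(rng):
    params = _random_lstm(rng, 4, 3)
    z = T.Tensor(rng.standard_normal(7) * 10)
    for W, b in ((params.W_f, params.b_f), (params.W_r, params.b_r),
                 (params.W_g, params.b_g)):
        gate = T.sigmoid(z @ W + b).data
        assert np.all((gate > 0) & (gate < 1))


# -- multi-scale bidirectional encoder ----------------------------------------


def test_deep_memory_output_shapes(rng):
    X = rng.standard_normal((3, 5))
    one = [( _random_lstm(rng, 5, 4), _random_lstm(rng, 5, 4) )]
    assert deep_memory_forward(X, one).shape == (3, 8)
    two = one + [(_random_lstm(rng, 5, 7), _random_lstm(rng, 5, 7))]
    assert deep_memory_forward(X, two).shape == (3, 22)


def test_deep_memory_default_width():
    cfg = ModelConfig(channels=("embedding",))
    assert cfg.encoder_width == 2 * (64 + 128) == 384


def test_deep_memory_bidirectional_symmetry(rng):
    """Reversing the sequence and swapping the forward/backward parameter
    roles reproduces the outputs in reverse row order (halves swapped)."""
    X = rng.standard_normal((6, 5))
    fwd, bwd = _random_lstm(rng, 5, 4), _random_lstm(rng, 5, 4)
    out = deep_memory_forward(X, [(fwd, bwd)])
    swapped = deep_memory_forward(X[::-1], [(bwd, fwd)])
    reassembled = np.concatenate([swapped[:, 4:], swapped[:, :4]], axis=1)
    np.testing.assert_allclose(reassembled, out[::-1], atol=1e-12)


def test_deep_memory_requires_a_stack(rng):
    with pytest.raises(ValueError):
        deep_memory_forward(rng.standard_normal((3, 5)), [])


# -- squash and routing --------------------------------------------------------


def test_squash_zero_vector():
    np.testing.assert_array_equal(squash(np.zeros(4)).data, np.zeros(4))


def test_squash_unit_vector_halves():
    s = np.array([0.0, 1.0, 0.0])
    v = squash(s).data
    np.testing.assert_allclose(np.linalg.norm(v), 0.5, atol=1e-9)
    np.testing.assert_allclose(v, s / 2, atol=1e-9)


def test_squash_large_norm(rng):
    s = rng.standard_normal(5)
    s = 10.0 * s / np.linalg.norm(s)
    v = squash(s).data
    np.testing.assert_allclose(np.linalg.norm(v), 100.0 / 101.0, atol=1e-9)
    np.testing.assert_allclose(v / np.linalg.norm(v), s / 10.0, atol=1e-9)


def test_squash_monotone_in_norm(rng):
    direction = rng.standard_normal(4)
    direction /= np.linalg.norm(direction)
    norms = [np.linalg.norm(squash(direction * r).data) for r in
             np.linspace(0.1, 5, 20)]
    assert np.all(np.diff(norms) > 0)
    assert all(n < 1 for n in norms)


def test_routing_softmax_values():
    np.testing.assert_allclose(
        routing_softmax(np.array([0.0, 0.0])).data, [0.5, 0.5]
    )
    np.testing.assert_allclose(
        routing_softmax(np.array([np.log(2.0), 0.0])).data,
        [2 / 3, 1 / 3],
        atol=1e-12,
    )


def test_routing_softmax_shift_invariance(rng):
    b = rng.standard_normal(6)
    np.testing.assert_allclose(
        routing_softmax(b).data, routing_softmax(b + 123.456).data, atol=1e-12
    )


def naive_routing(u, W, iters):
    """Triple-loop routing-by-agreement reference."""
    num_in, num_out, out_dim, _ = W.shape
    u_hat = np.zeros((num_in, num_out, out_dim))
    for i in range(num_in):
        for j in range(num_out):
            u_hat[i, j] = W[i, j] @ u[i]
    b = np.zeros((num_in, num_out))
    for it in range(iters):
        o = np.exp(b - b.max(axis=1, keepdims=True))
        o /= o.sum(axis=1, keepdims=True)
        s = np.zeros((num_out, out_dim))
        for j in range(num_out):
            for i in range(num_in):
                s[j] += o[i, j] * u_hat[i, j]
        v = np.zeros_like(s)
        for j in range(num_out):
            n2 = (s[j] ** 2).sum()
            v[j] = (n2 / (1 + n2)) * s[j] / np.sqrt(n2 + 1e-12)
        if it < iters - 1:
            for i in range(num_in):
                for j in range(num_out):
                    b[i, j] += u_hat[i, j] @ v[j]
    return v


@pytest.mark.parametrize("iters", [1, 3])
def test_dynamic_routing_matches_naive_reference(rng, iters):
    for _ in range(10):
        u = rng.standard_normal((4, 3))
        W = rng.standard_normal((4, 4, 5, 3))
        params = CapsuleLayerParams(T.Tensor(W), routing_iters=iters)
        got = dynamic_routing(u, params).data
        np.testing.assert_allclose(got, naive_routing(u, W, iters), atol=1e-6)


def test_single_capsule_identity_pose(rng):
    c = rng.standard_normal(3)
    W = np.eye(3)[None, None]  # 1 in-capsule, 1 out-capsule, identity pose
    params = CapsuleLayerParams(T.Tensor(W), routing_iters=3)
    np.testing.assert_allclose(
        dynamic_routing(c[None, None], params).data[0, 0],
        squash(c).data,
        atol=1e-12,
    )


def test_capsule_output_norms_below_one(rng):
    W = rng.standard_normal((4, 4, 5, 3))
    params = CapsuleLayerParams(T.Tensor(W), routing_iters=2)
    for _ in range(100):
        v = dynamic_routing(rng.standard_normal((4, 3)) * 5, params).data
        assert np.all(np.linalg.norm(v, axis=-1) < 1.0)


def test_coupling_coefficients_sum_to_one(rng):
    b = rng.standard_normal((7, 4, 6))
    o = routing_softmax(b, axis=2).data
    np.testing.assert_allclose(o.sum(axis=2), 1.0, atol=1e-6)


def test_routing_iters_validation(rng):
    with pytest.raises(ValueError):
        CapsuleLayerParams.init(rng, 2, 3, 2, 3, routing_iters=0)


# -- full forward pass ---------------------------------------------------------


@pytest.fixture(scope="module")
def small_forward():
    rng = np.random.default_rng(42)
    cfg = ModelConfig(
        channels=("mbf", "embedding"), hidden_sizes=(4,), caps_in_dim=2,
        caps_count=3, caps_dim=3, routing_iters=2, epochs=2, seed=0,
    )
    bundles = [
        FeatureBundle(
            f"p{i}",
            rng.standard_normal((L, 12)),
            rng.standard_normal((L, 6)),
            rng.integers(0, 2, L),
        )
        for i, L in enumerate([5, 7, 4])
    ]
    params = init_params(cfg, {"mbf": 12, "embedding": 6}, seed=1)
    return cfg, bundles, params


def test_forward_rows_sum_to_one(small_forward):
    _, bundles, params = small_forward
    probs = model_forward(bundles, params)
    for p, b in zip(probs, bundles):
        assert p.shape == (len(b), 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_forward_deterministic_for_duplicates(small_forward):
    _, bundles, params = small_forward
    probs = model_forward([bundles[0], bundles[0]], params)
    np.testing.assert_allclose(probs[0], probs[1], atol=1e-12)


def test_forward_permutation_consistency(small_forward):
    _, bundles, params = small_forward
    straight = model_forward(bundles, params)
    shuffled = model_forward(bundles[::-1], params)
    for a, b in zip(straight, shuffled[::-1]):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_forward_mbf_only_two_columns(small_forward):
    cfg, bundles, _ = small_forward
    mbf_cfg = ModelConfig(**{**cfg.to_dict(), "channels": ("mbf",)})
    params = init_params(mbf_cfg, {"mbf": 12}, seed=1)
    probs = model_forward(bundles[0], params)
    assert probs.shape == (5, 2)


def test_forward_channel_mismatch(small_forward):
    cfg, bundles, params = small_forward
    incomplete = FeatureBundle("q", bundles[0].mbf, None, None)
    with pytest.raises(ValueError, match="channel"):
        model_forward(incomplete, params)


# -- training ------------------------------------------------------------------


def _training_setup(n=20, L=12, seed=0):
    rng = np.random.default_rng(seed)
    offset = np.zeros(8)
    offset[0] = 3.0
    bundles = []
    for i in range(n):
        y = rng.integers(0, 2, L)
        emb = rng.standard_normal((L, 8)) + np.outer(y, offset)
        bundles.append(FeatureBundle(f"p{i}", None, emb, y))
    cfg = ModelConfig(
        channels=("embedding",), hidden_sizes=(4,), caps_in_dim=4,
        caps_count=4, caps_dim=3, routing_iters=2, epochs=5, patience=5,
        seed=3, batch_size=8,
    )
    return bundles, cfg


def test_training_loss_decreases():
    bundles, cfg = _training_setup()
    _, history = train_model(bundles, cfg)
    assert history[1]["train_loss"] < history[0]["train_loss"]


def test_training_is_seeded_deterministic():
    bundles, cfg = _training_setup()
    _, h1 = train_model(bundles, cfg)
    _, h2 = train_model(bundles, cfg)
    assert h1[-1]["val_loss"] == h2[-1]["val_loss"]


def test_training_rejects_unlabelled():
    bundles, cfg = _training_setup()
    bundles[0].labels = None
    with pytest.raises(ValueError, match="label"):
        train_model(bundles, cfg)


def test_training_rejects_single_class():
    bundles, cfg = _training_setup()
    for b in bundles:
        b.labels = np.zeros(len(b), dtype=int)
    with pytest.raises(ValueError, match="single class"):
        train_model(bundles, cfg)


def test_stratified_split_preserves_prevalence(rng):
    labels = (rng.random(1000) < 0.10).astype(int)
    train_idx, val_idx = stratified_split(labels, 0.2, seed=0)
    overall = labels.mean()
    assert abs(labels[val_idx].mean() - overall) < 0.02
    assert abs(labels[train_idx].mean() - overall) < 0.02
    assert len(np.intersect1d(train_idx, val_idx)) == 0
    assert len(train_idx) + len(val_idx) == 1000


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(hidden_sizes=())
    with pytest.raises(ValueError):
        ModelConfig(routing_iters=0)
    with pytest.raises(ValueError):
        ModelConfig(hidden_sizes=(5,), caps_in_dim=4)  # 10 % 4 != 0
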
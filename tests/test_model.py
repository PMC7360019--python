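"""The computational graph: layer oracles, gradients, determinism,
parameter accounting and checkpoint round trips."""

import numpy as np
import pytest

from clinseg import nn
from clinseg.estimators import SentenceSegmenter
from clinseg.model import (
    Head,
    ModelConfig,
    SBDNetwork,
    Tower,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)

TINY = dict(word_dim=4, char_dim=3, cnn_filters=4, lstm_units=3,
            dropout=0.0, recurrent_dropout=0.0, l1=1e-3,
            sequence_length=5, batch_size=2, seed=0)


def _tiny_net(char_vocab=12, word_vocab=8):
    cfg = ModelConfig(**TINY)
    rng = np.random.default_rng(0)
    tower = Tower(cfg, char_vocab, word_vocab, rng)
    head = Head(2 * cfg.lstm_units, rng)
    return SBDNetwork([tower], [True], head, cfg), cfg


def _tiny_batch(rng, b=2, t=5, length=7, char_vocab=12, word_vocab=8):
    # draw char ids without replacement per token so max-pool ties (kinks in
    # the loss surface) cannot occur in the finite-difference check
    char_ids = np.stack(
        [np.stack([rng.permutation(np.arange(1, char_vocab))[:length] for _ in range(t)])
         for _ in range(b)]
    ).astype(np.int32)
    word_ids = rng.integers(1, word_vocab, (b, t)).astype(np.int32)
    target = (rng.random((b, t)) < 0.3).astype(float)
    mask = np.ones((b, t))
    mask[-1, -1] = 0.0
    weights = np.where(target == 1, 2.0, 0.7) * mask
    return word_ids, char_ids, target, mask, weights


def test_gradients_match_finite_differences():
    net, _ = _tiny_net()
    rng = np.random.default_rng(1)
    word_ids, char_ids, target, mask, weights = _tiny_batch(rng)

    def loss_fn():
        prob, cache = net.forward(word_ids, char_ids, training=True)
        loss, dz = nn.weighted_bce(prob, target, weights, mask)
        return loss + net.l1_penalty(), dz, cache

    _, dz, cache = loss_fn()
    grads = net.backward(dz, cache)
    params = net.trainable_params()
    eps = 1e-6
    for name, p in params.items():
        flat, gf = p.reshape(-1), grads[name].reshape(-1)
        for i in np.linspace(0, flat.size - 1, min(12, flat.size)).astype(int):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn()[0]
            flat[i] = orig - eps
            lm = loss_fn()[0]
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - gf[i]) <= 1e-4 * max(1.0, abs(numeric), abs(gf[i])), (
                f"{name}[{i}]: numeric {numeric} vs analytic {gf[i]}"
            )


def test_word_representation_zero_cnn_is_batchnormed_word_vector():
    net, cfg = _tiny_net()
    tower = net.towers[0]
    tower.params["conv_w"][:] = 0.0
    tower.params["conv_b"][:] = 0.0
    tower.params["char_emb"][:] = 0.0
    rng = np.random.default_rng(2)
    word_ids = rng.integers(1, 8, (2, 5)).astype(np.int32)
    char_ids = rng.integers(1, 12, (2, 5, 6)).astype(np.int32)
    x, _ = tower.word_representation(word_ids, char_ids, training=True)
    wv = tower.params["word_emb"][word_ids].reshape(10, -1)
    expected, _ = nn.batchnorm_forward(
        wv, tower.params["bn1_gamma"], tower.params["bn1_beta"],
        {"mean": np.zeros(4), "var": np.ones(4)}, training=True,
    )
    assert np.allclose(x.reshape(10, -1), expected)


def test_conv_maxpool_matches_hand_computation():
    # one filter of width 4 on a single 4-char input: pooled value is the
    # plain dot product of the flattened window with the kernel
    x = np.arange(12, dtype=float).reshape(1, 4, 3)
    kernel = np.linspace(-1, 1, 12).reshape(12, 1)
    bias = np.array([0.25])
    pooled, _ = nn.conv1d_maxpool_forward(x, kernel, bias)
    hand = float(x.reshape(-1) @ kernel[:, 0] + 0.25)
    assert pooled.shape == (1, 1)
    assert pooled[0, 0] == pytest.approx(hand)
    # two positions: pooling takes the max
    x2 = np.concatenate([x, -x[:, :1, :] + 1], axis=1)  # length 5 -> 2 windows
    pooled2, _ = nn.conv1d_maxpool_forward(x2, kernel, bias)
    w0 = x2[0, 0:4].reshape(-1) @ kernel[:, 0] + 0.25
    w1 = x2[0, 1:5].reshape(-1) @ kernel[:, 0] + 0.25
    assert pooled2[0, 0] == pytest.approx(max(w0, w1))


def test_prediction_layer_examples():
    rng = np.random.default_rng(0)
    head = Head(2, rng)
    head.params["head_w"][:] = 0.0
    head.params["head_b"][:] = 0.0
    h = rng.standard_normal((1, 4, 2))
    prob, _ = head.forward(h)
    assert np.allclose(prob, 0.5)  # sigmoid(0)
    head.params["head_b"][:] = 50.0
    prob, _ = head.forward(h)
    assert np.all(prob > 0.999)  # saturation
    head.params["head_w"][:] = [0.3, -0.7]
    head.params["head_b"][:] = 0.1
    h0 = np.array([[[1.5, 2.0]]])
    prob, _ = head.forward(h0)
    hand = 1.0 / (1.0 + np.exp(-(1.5 * 0.3 + 2.0 * -0.7 + 0.1)))
    assert prob[0, 0] == pytest.approx(hand)


def test_encode_context_inference_is_deterministic():
    net, _ = _tiny_net()
    rng = np.random.default_rng(3)
    x = rng.standard_normal((2, 4, 4))
    tower = net.towers[0]
    h1, _ = tower.encode_context(x, training=False)
    h2, _ = tower.encode_context(x, training=False)
    assert np.array_equal(h1, h2)
    # degenerate single-step sequence still yields both directions
    h3, _ = tower.encode_context(x[:, :1, :], training=False)
    assert h3.shape == (2, 1, 6)


def test_encode_context_direction_symmetry():
    """Reversing the input sequence with direction-swapped weights swaps
    the forward/backward halves of the (pre-normalization) encoding."""
    cfg = ModelConfig(**TINY)
    rng = np.random.default_rng(4)
    tower = Tower(cfg, 12, 8, rng)
    swapped = Tower(cfg, 12, 8, np.random.default_rng(5))
    for side in ("wx", "wh", "b"):
        swapped.params[f"fwd_{side}"] = tower.params[f"bwd_{side}"].copy()
        swapped.params[f"bwd_{side}"] = tower.params[f"fwd_{side}"].copy()
    # bypass batch norm to compare raw LSTM outputs
    for t in (tower, swapped):
        t.params["bn2_gamma"][:] = 1.0
        t.params["bn2_beta"][:] = 0.0
        t.buffers["bn2"] = {"mean": np.zeros(6), "var": np.ones(6) - 1e-5}
    x = rng.standard_normal((1, 5, 4))
    h, _ = tower.encode_context(x, training=False)
    h_rev, _ = swapped.encode_context(x[:, ::-1, :], training=False)
    u = cfg.lstm_units
    assert np.allclose(h[:, :, :u], h_rev[:, ::-1, u:], atol=1e-10)
    assert np.allclose(h[:, :, u:], h_rev[:, ::-1, :u], atol=1e-10)


def test_forward_pass_deterministic_at_inference():
    net, _ = _tiny_net()
    rng = np.random.default_rng(6)
    word_ids, char_ids, *_ = _tiny_batch(rng)
    p1, _ = net.forward(word_ids, char_ids, training=False)
    p2, _ = net.forward(word_ids, char_ids, training=False)
    assert np.array_equal(p1, p2)


def test_parameter_count_closed_form():
    net, cfg = _tiny_net(char_vocab=12, word_vocab=8)
    assert net.n_parameters() == count_parameters(cfg, 12, 8)
    # published dimensions: regression against the closed form
    full = ModelConfig()
    expected = count_parameters(full, 100, 5000)
    assert expected == (
        100 * 30 + 4 * 30 * 300 + 300 + 5000 * 300 + 600
        + 2 * (300 * 800 + 200 * 800 + 800) + 800 + 401
    )


def test_config_validation():
    with pytest.raises(ValueError, match="cnn_filters"):
        ModelConfig(word_dim=300, cnn_filters=200)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.5)


def test_checkpoint_round_trip(tmp_path, tiny_fitted, small_xy):
    x, _ = small_xy
    path = tiny_fitted.save(tmp_path / "model.npz")
    loaded = SentenceSegmenter.load(path)
    assert loaded.char_vocab_ == tiny_fitted.char_vocab_
    assert loaded.word_vocab_ == tiny_fitted.word_vocab_
    for a, b in zip(tiny_fitted.predict_proba(x[:3]), loaded.predict_proba(x[:3])):
        assert np.allclose(a, b)


def test_checkpoint_format_is_versioned(tmp_path, tiny_fitted):
    path = tiny_fitted.save(tmp_path / "model.npz")
    network, _cv, _wv, extra = load_checkpoint(path)
    assert network.config.lstm_units == tiny_fitted.lstm_units
    assert "log" in extra
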
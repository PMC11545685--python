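"""Architecture contracts: shapes, ranges, gating algebra, parameter count."""

import numpy as np
import pytest

from iousseg import nn
from iousseg.model import ModelConfig, WeightedBlock, WeightedUNet, build_model


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(encoder_filters=(32, 64))
    with pytest.raises(ValueError):
        ModelConfig(input_side=100)
    with pytest.raises(ValueError):
        ModelConfig(output_channels=3)
    with pytest.raises(ValueError):
        ModelConfig(dropout_rate=1.2)


def test_default_config_matches_design():
    cfg = ModelConfig()
    assert cfg.encoder_filters == (32, 32, 64, 64, 128)
    assert cfg.kernel_size == 3
    assert cfg.dropout_rate == 0.0
    assert cfg.input_side == 256


def test_block_output_shapes_at_256():
    """Gated skip O_l: side 256/2^l, 128 channels; gate X single channel."""
    model = build_model(ModelConfig(seed=0))
    rng = np.random.default_rng(0)
    f = rng.random((1, 256, 256, 1)).astype(np.float32)
    w = rng.random((1, 256, 256, 1)).astype(np.float32)
    pyramid = model.weight_pyramid(w)
    assert [p.shape[1] for p in pyramid] == [128, 64, 32, 16]
    x = f
    for i in range(4):
        x = model.enc_relu[i].forward(model.enc[i].forward(x))
        o_l = model.blocks[i].forward(x, pyramid[i])
        side = 256 // 2 ** (i + 1)
        assert o_l.shape == (1, side, side, 128)
        gate = model.blocks[i].last_gate
        assert gate.shape == (1, side, side, 1)
        assert gate.min() >= 0.0 and gate.max() <= 1.0
        x = model.enc_pool[i].forward(x)


def test_forward_output_shape_and_range():
    model = build_model(ModelConfig(input_side=64, seed=1))
    rng = np.random.default_rng(1)
    prob = model.forward(rng.random((2, 64, 64, 1)), rng.random((2, 64, 64, 1)))
    assert prob.shape == (2, 64, 64, 1)
    assert prob.min() >= 0.0 and prob.max() <= 1.0


def test_parameter_count_matches_hand_tabulation():
    """Layer-by-layer (k*k*c_in + 1) * c_out sum for the default filters."""
    def conv(k, cin, cout):
        return (k * k * cin + 1) * cout

    enc = (conv(3, 1, 32) + conv(3, 32, 32) + conv(3, 32, 64)
           + conv(3, 64, 64) + conv(3, 64, 128))
    blocks = 0
    for z in (32, 32, 64, 64):
        blocks += (conv(1, z, 128)      # feature projection
                   + conv(1, 1, 128)    # weight-map lift
                   + conv(3, 128, 128)  # refine
                   + conv(1, 128, 1))   # gate
    dec = (conv(3, 128 + 128, 64) + conv(3, 64 + 128, 64)
           + conv(3, 64 + 128, 32) + conv(3, 32 + 128, 32))
    head = conv(3, 32, 16) + conv(1, 16, 1)
    expected = enc + blocks + dec + head
    assert expected == 1_120_069
    assert build_model(ModelConfig(seed=0)).n_params == expected


def test_batch_matches_single_item_forward():
    model = build_model(ModelConfig(input_side=32,
                                    encoder_filters=(4, 4, 8, 8, 16),
                                    decoder_filters=(8, 8, 4, 4),
                                    head_filters=4, attention_channels=16,
                                    seed=2))
    rng = np.random.default_rng(2)
    f = rng.random((3, 32, 32, 1)).astype(np.float32)
    w = rng.random((3, 32, 32, 1)).astype(np.float32)
    batch = model.forward(f, w)
    for i in range(3):
        single = model.forward(f[i:i + 1], w[i:i + 1])
        np.testing.assert_allclose(single[0], batch[i], atol=1e-5)


def test_forward_is_deterministic_in_eval_mode(tiny_model):
    rng = np.random.default_rng(3)
    f = rng.random((2, 16, 16, 1)).astype(np.float32)
    w = rng.random((2, 16, 16, 1)).astype(np.float32)
    a = tiny_model.forward(f, w, train=False).copy()
    b = tiny_model.forward(f, w, train=False)
    np.testing.assert_array_equal(a, b)


def test_gating_is_linear_in_gate():
    """O_l = X * Q_l: halving the gate exactly halves the output."""
    rng = np.random.default_rng(4)
    block = WeightedBlock(3, 8, rng)
    x = rng.random((1, 8, 8, 3)).astype(np.float32)
    w = rng.random((1, 4, 4, 1)).astype(np.float32)
    o = block.forward(x, w)
    np.testing.assert_allclose(0.5 * block.last_gate * block._q, 0.5 * o,
                               atol=1e-7)


def test_zeroed_block_weights_give_half_gate():
    """All-zero fusion weights/biases -> pre-activation 0 -> X = 0.5."""
    rng = np.random.default_rng(5)
    block = WeightedBlock(2, 4, rng)
    for layer in block.layers():
        layer.w.value[...] = 0.0
        layer.b.value[...] = 0.0
    x = rng.random((1, 8, 8, 2)).astype(np.float32)
    w = np.zeros((1, 4, 4, 1), np.float32)
    o = block.forward(x, w)
    np.testing.assert_array_equal(block.last_gate, 0.5)
    np.testing.assert_array_equal(o, 0.0)  # Q is zero under zero projection


def test_predict_threshold_extremes_and_missing_map():
    model = build_model(ModelConfig(input_side=32,
                                    encoder_filters=(2, 2, 3, 3, 4),
                                    decoder_filters=(3, 3, 2, 2),
                                    head_filters=2, attention_channels=4,
                                    seed=6))
    rng = np.random.default_rng(6)
    frame = rng.random((32, 32)).astype(np.float32)
    wmap = rng.random((32, 32)).astype(np.float32)
    mask, prob = model.predict(frame, wmap, threshold=0.0)
    assert mask.all()
    mask, _ = model.predict(frame, wmap, threshold=1.0 + 1e-6)
    assert not mask.any()
    with pytest.raises(ValueError):
        model.predict(frame, None)


def test_mismatched_shapes_rejected(tiny_model):
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError):
        tiny_model.forward(rng.random((1, 16, 16, 1)), rng.random((1, 32, 32, 1)))
    with pytest.raises(ValueError):
        tiny_model.forward(rng.random((1, 32, 32, 1)), rng.random((1, 32, 32, 1)))


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    rng = np.random.default_rng(8)
    f = rng.random((1, 16, 16, 1)).astype(np.float32)
    w = rng.random((1, 16, 16, 1)).astype(np.float32)
    before = tiny_model.forward(f, w).copy()
    tiny_model.save(tmp_path / "m.npz")
    loaded = WeightedUNet.load(tmp_path / "m.npz")
    np.testing.assert_array_equal(loaded.forward(f, w), before)
    assert loaded.config == tiny_model.config
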
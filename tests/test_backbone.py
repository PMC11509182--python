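"""Residual 3D-CNN blocks, peephole ConvLSTM, regression head, full network."""

import numpy as np
import pytest

from tcedn.backbone import (BackboneConfig, ConvLSTMCell, RegressionHead,
                            ResidualBlock3d, TCEDNNet, build_network,
                            convlstm_rollout)
from tcedn.nn import Tensor


def zeroed(module):
    for p in module.parameters():
        p.data[:] = 0.0
    return module


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


# --------------------------------------------------------------- residual
def test_zeroed_residual_branch_is_identity_on_nonnegative_input():
    block = ResidualBlock3d(3, 3, rng=np.random.default_rng(0))
    for conv in block.convs:
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    x = np.random.default_rng(1).uniform(0, 1, size=(2, 3, 4, 5, 5))
    out = block(Tensor(x.astype(np.float32)))
    np.testing.assert_allclose(out.data, x, rtol=1e-5, atol=1e-6)


def test_downsampling_shape_contract():
    block = ResidualBlock3d(3, 8, stride=(1, 2, 2), rng=np.random.default_rng(0))
    out = block(Tensor(np.zeros((1, 3, 6, 16, 20), dtype=np.float32)))
    assert out.shape == (1, 8, 6, 8, 10)
    block_t = ResidualBlock3d(8, 8, stride=(2, 2, 2), rng=np.random.default_rng(0))
    out2 = block_t(Tensor(np.zeros((1, 8, 6, 8, 10), dtype=np.float32)))
    assert out2.shape == (1, 8, 3, 4, 5)


def test_conv_layer_parameter_closed_form():
    # one 3->8 conv3d with kernel 3: 8*(3*27) + 8 bias = 656 (+16 BN affine)
    block = ResidualBlock3d(3, 8, n_convs=1, stride=(1, 1, 1),
                            rng=np.random.default_rng(0))
    conv_params = block.convs[0].num_parameters()
    assert conv_params == 8 * 3 * 27 + 8 == 656
    assert conv_params + block.bns[0].num_parameters() == 672


def test_too_small_spatial_extent_raises():
    block = ResidualBlock3d(1, 2, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 1, 0, 4, 4), dtype=np.float32)))


# --------------------------------------------------------------- convlstm
def test_zeroed_cell_fixed_point():
    """All-zero weights and biases: every gate is 0.5, state stays zero."""
    cell = zeroed(ConvLSTMCell(1, 1, (2, 2), rng=np.random.default_rng(0)))
    x = Tensor(np.random.default_rng(2).normal(size=(1, 1, 1, 2, 2)))
    h, (h2, c2) = cell.step(x, cell.zero_state(1))
    np.testing.assert_allclose(h.data, 0.0, atol=1e-12)
    np.testing.assert_allclose(c2.data, 0.0, atol=1e-12)


def test_peephole_hand_evaluation():
    """1x1 spatial, zero weights, C_0 = 1: forget gate halves the cell."""
    cell = zeroed(ConvLSTMCell(1, 1, (1, 1), rng=np.random.default_rng(0)))
    x = Tensor(np.zeros((1, 1, 1, 1, 1)))
    h0, c0 = cell.zero_state(1)
    c0.data[:] = 1.0
    h, (h2, c2) = cell.step(x, (h0, c0))
    # f = sigma(0) = 0.5, C_1 = 0.5, o = 0.5, H_1 = 0.5 * tanh(0.5)
    np.testing.assert_allclose(c2.data, 0.5, atol=1e-12)
    np.testing.assert_allclose(h.data, 0.5 * np.tanh(0.5), rtol=1e-10)
    # with output-gate peephole W_co = 1: o = sigma(0.5)
    cell.Wco.data[:] = 1.0
    h_p, _ = cell.step(x, (Tensor(np.zeros((1, 1, 1, 1, 1))), c0))
    np.testing.assert_allclose(h_p.data, sigmoid(0.5) * np.tanh(0.5), rtol=1e-6)


def test_rollout_single_step_reduction_and_zero_fixed_point():
    cell = zeroed(ConvLSTMCell(1, 2, (2, 3), rng=np.random.default_rng(0)))
    seq = Tensor(np.random.default_rng(3).normal(size=(1, 1, 4, 2, 3)))
    np.testing.assert_allclose(convlstm_rollout(seq, cell).data, 0.0, atol=1e-12)
    one = seq.narrow(2, 0, 1)
    h_roll = convlstm_rollout(one, cell)
    h_step, _ = cell.step(one, cell.zero_state(1))
    np.testing.assert_allclose(h_roll.data, h_step.data, atol=1e-12)
    with pytest.raises(ValueError):
        convlstm_rollout(seq.narrow(2, 0, 0), cell)


def scalar_lstm_oracle(xs, p):
    """Plain peephole-LSTM recurrence on scalars (1 channel, 1x1 spatial)."""
    h = c = 0.0
    for x in xs:
        i = sigmoid(p["wxi"] * x + p["whi"] * h + p["wci"] * c + p["bi"])
        f = sigmoid(p["wxf"] * x + p["whf"] * h + p["wcf"] * c + p["bf"])
        c = f * c + i * np.tanh(p["wxc"] * x + p["whc"] * h + p["bc"])
        o = sigmoid(p["wxo"] * x + p["who"] * h + p["wco"] * c + p["bo"])
        h = o * np.tanh(c)
    return h


def test_rollout_matches_scalar_oracle():
    rng = np.random.default_rng(4)
    cell = ConvLSTMCell(1, 1, (1, 1), kernel=(1, 1), rng=rng, forget_bias=0.0)
    p = {}
    for name in ("Wxi", "Wxf", "Wxc", "Wxo", "Whi", "Whf", "Whc", "Who"):
        val = rng.normal()
        getattr(cell, name).weight.data[:] = val
        p[name.lower()] = val
    for name in ("Wci", "Wcf", "Wco"):
        val = rng.normal()
        getattr(cell, name).data[:] = val
        p[name.lower()] = val
    for name in ("bi", "bf", "bc", "bo"):
        val = rng.normal()
        getattr(cell, name).data[:] = val
        p[name.lower()] = val
    xs = rng.normal(size=3)
    seq = Tensor(xs.reshape(1, 1, 3, 1, 1))
    got = float(convlstm_rollout(seq, cell).data.ravel()[0])
    np.testing.assert_allclose(got, scalar_lstm_oracle(xs, p), rtol=1e-5)


def test_gate_and_hidden_boundedness():
    rng = np.random.default_rng(5)
    cell = ConvLSTMCell(2, 3, (4, 4), rng=rng)
    for pname, par in cell.named_parameters():
        par.data[:] = rng.normal(scale=2.0, size=par.shape)
    seq = Tensor(rng.normal(scale=5.0, size=(2, 2, 6, 4, 4)).astype(np.float32))
    h = convlstm_rollout(seq, cell)
    assert np.all(np.abs(h.data) < 1.0)


def test_state_spatial_mismatch_raises():
    cell = ConvLSTMCell(1, 1, (2, 2), rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        cell.step(Tensor(np.zeros((1, 1, 1, 3, 3))), cell.zero_state(1))


# ------------------------------------------------------------------- head
def test_head_bias_passthrough_and_shape():
    head = zeroed(RegressionHead(4, channels=(3,), output_scale=1.0,
                                 rng=np.random.default_rng(0)))
    head.fc.bias.data[:] = 7.0
    out = head(Tensor(np.random.default_rng(1).normal(size=(4, 4, 1, 3, 3))))
    assert out.shape == (4,)
    np.testing.assert_allclose(out.data, 7.0, rtol=1e-6)


def test_head_final_layer_linearity():
    rng = np.random.default_rng(6)
    head = RegressionHead(2, channels=(3,), output_scale=1.0, rng=rng)
    head.eval()
    x = Tensor(rng.normal(size=(2, 2, 1, 4, 4)).astype(np.float32))
    b = head.fc.bias.data.copy()
    out1 = head(x).data - b
    head.fc.weight.data *= 2.0
    out2 = head(x).data - b
    np.testing.assert_allclose(out2, 2 * out1, rtol=1e-4)


# ------------------------------------------------------------ full network
@pytest.fixture(scope="module")
def tiny_net():
    cfg = BackboneConfig(in_channels=1, stage_channels=(2, 4), blocks_per_stage=1,
                         convlstm_hidden=4, head_channels=(4,),
                         temporal_stride_stages=(1,), seed=0)
    return build_network(cfg, (1, 6, 8, 12))


def test_eval_determinism_and_batch_equivariance(tiny_net):
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 1, size=(3, 1, 6, 8, 12)).astype(np.float32)
    p1 = tiny_net.predict(x)
    p2 = tiny_net.predict(x)
    np.testing.assert_array_equal(p1, p2)
    perm = [2, 0, 1]
    np.testing.assert_allclose(tiny_net.predict(x[perm]), p1[perm], rtol=1e-5)
    # two identical clips produce identical scores
    xx = np.stack([x[0], x[0]])
    pp = tiny_net.predict(xx)
    assert pp[0] == pp[1]


def test_every_parameter_receives_gradient(tiny_net):
    rng = np.random.default_rng(8)
    x = Tensor(rng.uniform(0, 1, size=(2, 1, 6, 8, 12)).astype(np.float32))
    tiny_net.train()
    out = tiny_net(x)
    loss = ((out - Tensor(np.array([5.0, 25.0], dtype=np.float32))) ** 2).mean()
    tiny_net.zero_grad()
    loss.backward()
    missing = [n for n, p in tiny_net.named_parameters()
               if p.grad is None or np.abs(p.grad).sum() == 0]
    # peephole maps start at zero but still sit on the gradient path
    assert missing == [], f"no gradient reached: {missing}"


def test_network_gradient_finite_difference_spot_check(tiny_net):
    """Backprop through the whole model agrees with finite differences."""
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 1, size=(1, 1, 6, 8, 12)).astype(np.float32)
    y = np.array([20.0], dtype=np.float32)
    tiny_net.eval()  # freeze BN statistics so the loss is a clean function

    def loss_value():
        out = tiny_net(Tensor(x))
        return float(((out.data - y) ** 2).mean())

    out = tiny_net(Tensor(x))
    loss = ((out - Tensor(y)) ** 2).mean()
    tiny_net.zero_grad()
    loss.backward()
    params = tiny_net.parameters()
    check = [params[0], params[len(params) // 2], params[-1]]
    for p in check:
        idx = tuple(0 for _ in p.shape)
        g = p.grad[idx]
        eps = 1e-2
        orig = p.data[idx]
        p.data[idx] = orig + eps
        up = loss_value()
        p.data[idx] = orig - eps
        dn = loss_value()
        p.data[idx] = orig
        numeric = (up - dn) / (2 * eps)
        np.testing.assert_allclose(g, numeric, rtol=5e-2, atol=1e-4)


def test_fc_lstm_baseline_wiring():
    cfg = BackboneConfig(in_channels=1, stage_channels=(2, 4), blocks_per_stage=1,
                         convlstm_hidden=4, head_channels=(4,),
                         temporal_stride_stages=(1,), seed=0)
    net = build_network(cfg, (1, 6, 8, 12), use_convlstm=False)
    x = np.random.default_rng(0).uniform(size=(2, 1, 6, 8, 12)).astype(np.float32)
    assert net.predict(x).shape == (2,)
    # the flattened-feature LSTM discards spatial maps: 1x1 cell state
    assert net.recurrent.spatial == (1, 1)


def test_channel_mismatch_raises():
    cfg = BackboneConfig(in_channels=3)
    with pytest.raises(ValueError):
        TCEDNNet(cfg, (1, 6, 8, 12))
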
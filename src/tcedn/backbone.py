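"""Residual 3D-CNN + peephole ConvLSTM backbone with a 2D-CNN regression head.

The fused clip features pass through four residual stages of 3x3x3
convolutions (16 convolution layers in the reference layout: 4 stages x 2
blocks x 2 convolutions), each stage halving the spatial extent and the last
two stages also halving the temporal extent.  A single-layer convolutional
LSTM with peephole connections then rolls over the remaining time steps,

    i_t = sigma(Wxi * X_t + Whi * H_{t-1} + Wci o C_{t-1} + b_i)
    f_t = sigma(Wxf * X_t + Whf * H_{t-1} + Wcf o C_{t-1} + b_f)
    C_t = f_t o C_{t-1} + i_t o tanh(Wxc * X_t + Whc * H_{t-1} + b_c)
    o_t = sigma(Wxo * X_t + Who * H_{t-1} + Wco o C_t + b_o)
    H_t = o_t o tanh(C_t)

(``*`` convolution, ``o`` Hadamard product; the peephole weights have the
hidden-state shape and act element-wise).  The final hidden map H_T feeds a
small 2-D convolutional head ending in global average pooling and one linear
unit; the unit's output is multiplied by ``output_scale`` (the BDI-II range
by default) so the last layer works on an O(1) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm3d, Conv3d, Linear, Module, Parameter, Tensor, no_grad
from .stdwm import STDWM, DiffConfig

__all__ = [
    "BackboneConfig", "ResidualBlock3d", "ConvLSTMCell", "RegressionHead",
    "TCEDNNet", "build_network", "convlstm_rollout",
]


def _ceil_div(n: int, s: int) -> int:
    return (n + s - 1) // s


@dataclass
class BackboneConfig:
    """Architecture hyper-parameters of the severity-regression network.

    The reference layout uses 16 3x3x3 convolution layers (4 stages x 2
    residual blocks x 2 convolutions), stage widths (8, 16, 32, 64), spatial
    stride 2 at each stage entry and temporal stride 2 in the last two
    stages; the widths are calibrated so the full model stays inside the
    lightweight budget of <= 5.08 M parameters and <= 2.85 GFLOPs at the
    reference eye-strip input.
    """

    in_channels: int = 3
    stage_channels: tuple = (8, 16, 32, 64)
    blocks_per_stage: int = 2
    convs_per_block: int = 2
    conv_kernel: tuple = (3, 3, 3)
    temporal_stride_stages: tuple = (2, 3)   # 0-based stage indices
    convlstm_hidden: int = 64
    convlstm_kernel: tuple = (3, 3)
    head_channels: tuple = (32, 16)
    output_scale: float = 63.0
    output_bias_init: float = 0.5
    diff_steps: tuple = (1,)
    diff_fuse_mode: str = "single"
    init_wv: float = 1.0
    init_wd: float = 0.1
    seed: int = 0

    @property
    def num_conv_layers(self) -> int:
        return len(self.stage_channels) * self.blocks_per_stage * self.convs_per_block

    def stage_stride(self, stage: int) -> tuple:
        st = 2 if stage in tuple(self.temporal_stride_stages) else 1
        return (st, 2, 2)

    def trace_shapes(self, input_shape: tuple) -> list:
        """(C, T, H, W) at the input of each stage and after the last stage."""
        C, T, H, W = input_shape
        shapes = [(C, T, H, W)]
        for i, width in enumerate(self.stage_channels):
            sT, sH, sW = self.stage_stride(i)
            T, H, W = _ceil_div(T, sT), _ceil_div(H, sH), _ceil_div(W, sW)
            shapes.append((width, T, H, W))
        return shapes


class ResidualBlock3d(Module):
    """conv-BN-ReLU x (n-1), conv-BN, skip addition, final ReLU.

    A 1x1x1 strided projection aligns the skip path when the channel count
    or stride changes.  With every branch weight at zero and identity BN the
    block is the identity on non-negative inputs.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3),
                 stride=(1, 1, 1), n_convs: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.convs, self.bns = [], []
        for i in range(n_convs):
            s = stride if i == 0 else (1, 1, 1)
            c_in = in_ch if i == 0 else out_ch
            self.convs.append(Conv3d(c_in, out_ch, kernel=kernel, stride=s, rng=rng))
            self.bns.append(BatchNorm3d(out_ch))
        if in_ch != out_ch or tuple(stride) != (1, 1, 1):
            self.proj = Conv3d(in_ch, out_ch, kernel=(1, 1, 1), stride=stride, rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = x
        n = len(self.convs)
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            y = bn(conv(y))
            if i < n - 1:
                y = y.relu()
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class ConvLSTMCell(Module):
    """Single convolutional LSTM cell with peephole connections.

    Gate transforms are same-padded 2-D convolutions applied to maps carried
    as (B, C, 1, H, W); the peephole weights and biases are per-element /
    per-channel parameters of the hidden-state shape.
    """

    def __init__(self, in_ch: int, hidden: int, spatial: tuple,
                 kernel=(3, 3), rng: np.random.Generator | None = None,
                 forget_bias: float = 1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kH, kW = kernel
        k3 = (1, kH, kW)
        self.hidden = hidden
        self.spatial = tuple(spatial)
        mk_x = lambda: Conv3d(in_ch, hidden, kernel=k3, bias=False, rng=rng)
        mk_h = lambda: Conv3d(hidden, hidden, kernel=k3, bias=False, rng=rng)
        self.Wxi, self.Wxf, self.Wxc, self.Wxo = mk_x(), mk_x(), mk_x(), mk_x()
        self.Whi, self.Whf, self.Whc, self.Who = mk_h(), mk_h(), mk_h(), mk_h()
        H, W = self.spatial
        peep = lambda: Parameter(np.zeros((1, hidden, 1, H, W)))
        self.Wci, self.Wcf, self.Wco = peep(), peep(), peep()
        bias = lambda v: Parameter(np.full((1, hidden, 1, 1, 1), v))
        self.bi, self.bf, self.bc, self.bo = bias(0.0), bias(forget_bias), bias(0.0), bias(0.0)

    def zero_state(self, batch: int) -> tuple:
        H, W = self.spatial
        z = np.zeros((batch, self.hidden, 1, H, W), dtype=np.float32)
        return Tensor(z.copy()), Tensor(z.copy())

    def step(self, x: Tensor, state: tuple) -> tuple:
        """One recurrence step; returns (H_t, (H_t, C_t))."""
        h, c = state
        if x.shape[-2:] != h.shape[-2:]:
            raise ValueError("input spatial extent must match the cell state")
        i = (self.Wxi(x) + self.Whi(h) + self.Wci * c + self.bi).sigmoid()
        f = (self.Wxf(x) + self.Whf(h) + self.Wcf * c + self.bf).sigmoid()
        c_new = f * c + i * (self.Wxc(x) + self.Whc(h) + self.bc).tanh()
        o = (self.Wxo(x) + self.Who(h) + self.Wco * c_new + self.bo).sigmoid()
        h_new = o * c_new.tanh()
        return h_new, (h_new, c_new)

    def forward(self, seq: Tensor) -> Tensor:
        return convlstm_rollout(seq, self)


def convlstm_rollout(seq, cell: ConvLSTMCell) -> Tensor:
    """Run the cell over t = 1..T of a (B, C, T, H, W) block; return H_T."""
    seq = seq if isinstance(seq, Tensor) else Tensor(np.asarray(seq, dtype=np.float64))
    T = seq.shape[2]
    if T < 1:
        raise ValueError("empty time axis")
    state = cell.zero_state(seq.shape[0])
    h = state[0]
    for t in range(T):
        x_t = seq.narrow(2, t, 1)
        h, state = cell.step(x_t, state)
    return h


class RegressionHead(Module):
    """2-D conv stack + global average pooling + linear unit -> severity."""

    def __init__(self, in_ch: int, channels=(32, 16), output_scale: float = 63.0,
                 output_bias_init: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.convs, self.bns = [], []
        c_prev = in_ch
        for c in channels:
            self.convs.append(Conv3d(c_prev, c, kernel=(1, 3, 3), rng=rng))
            self.bns.append(BatchNorm3d(c))
            c_prev = c
        self.fc = Linear(c_prev, 1, rng=rng)
        self.fc.bias.data = np.array([output_bias_init], dtype=np.float32)
        self.output_scale = float(output_scale)

    def forward(self, h: Tensor) -> Tensor:
        y = h
        for conv, bn in zip(self.convs, self.bns):
            y = bn(conv(y)).relu()
        pooled = y.mean(axis=(2, 3, 4))          # (B, C)
        z = self.fc(pooled)                       # (B, 1)
        return (z * self.output_scale).reshape(z.shape[0])


class TCEDNNet(Module):
    """Full severity-regression network over aggregated clips.

    ``forward`` consumes a (B, C, T, H, W) block that has already been
    frame-aggregated; the temporal-difference fusion, residual 3-D stages,
    ConvLSTM rollout and regression head run inside the autodiff graph.
    Ablation switches: ``use_stdwm`` removes the motion fusion,
    ``use_convlstm=False`` replaces the convolutional LSTM with a plain
    peephole LSTM on flattened features (spatial structure discarded).
    """

    def __init__(self, cfg: BackboneConfig, input_shape: tuple,
                 use_stdwm: bool = True, use_convlstm: bool = True):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.use_stdwm = use_stdwm
        self.use_convlstm = use_convlstm
        C, T, H, W = input_shape
        if C != cfg.in_channels:
            raise ValueError(
                f"input has {C} channels but config expects {cfg.in_channels}"
            )
        if use_stdwm:
            diff_cfg = DiffConfig(steps=cfg.diff_steps, fuse_mode=cfg.diff_fuse_mode)
            self.stdwm = STDWM((C, T, H, W), diff_cfg,
                               init_wv=cfg.init_wv, init_wd=cfg.init_wd)
        else:
            self.stdwm = None
        self.stages = []
        shapes = cfg.trace_shapes((C, T, H, W))
        c_prev = C
        for i, width in enumerate(cfg.stage_channels):
            stride = cfg.stage_stride(i)
            blocks = []
            for b in range(cfg.blocks_per_stage):
                blocks.append(ResidualBlock3d(
                    c_prev if b == 0 else width, width,
                    kernel=cfg.conv_kernel,
                    stride=stride if b == 0 else (1, 1, 1),
                    n_convs=cfg.convs_per_block, rng=rng))
                c_prev = width
            self.stages.append(blocks)
        c_out, t_out, h_out, w_out = shapes[-1]
        if use_convlstm:
            self.recurrent = ConvLSTMCell(
                c_out, cfg.convlstm_hidden, (h_out, w_out),
                kernel=cfg.convlstm_kernel, rng=rng)
            head_in = cfg.convlstm_hidden
        else:
            # flattened-feature LSTM baseline: a 1x1-kernel ConvLSTM on a
            # (B, C*H*W, T, 1, 1) block is exactly a fully connected
            # peephole LSTM
            self.recurrent = ConvLSTMCell(
                c_out * h_out * w_out, cfg.convlstm_hidden, (1, 1),
                kernel=(1, 1), rng=rng)
            head_in = cfg.convlstm_hidden
        self.final_shape = (c_out, t_out, h_out, w_out)
        self.head = RegressionHead(
            head_in, channels=cfg.head_channels,
            output_scale=cfg.output_scale,
            output_bias_init=cfg.output_bias_init, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        """Backbone features up to (and including) the recurrent rollout."""
        y = x
        if self.stdwm is not None:
            y = self.stdwm(y)
        for blocks in self.stages:
            for block in blocks:
                y = block(y)
        if not self.use_convlstm:
            B, C, T, H, W = y.shape
            y = y.transpose((0, 1, 3, 4, 2)).reshape(B, C * H * W, T, 1, 1)
        return convlstm_rollout(y, self.recurrent)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 5:
            raise ValueError("expected a (B, C, T, H, W) block")
        h_final = self.features(x)
        out = self.head(h_final)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite activations in the regression head")
        return out

    def predict(self, x) -> np.ndarray:
        """Deterministic evaluation-mode predictions as a numpy array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(x)
        finally:
            self.train(was_training)
        return out.data.copy()


def build_network(cfg: BackboneConfig, input_shape: tuple,
                  use_stdwm: bool = True, use_convlstm: bool = True) -> TCEDNNet:
    return TCEDNNet(cfg, input_shape, use_stdwm=use_stdwm, use_convlstm=use_convlstm)
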
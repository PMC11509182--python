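"""Analytic parameter and FLOP accounting for the severity-regression network.

Both quantities are computed in closed form by walking the architecture
configuration layer by layer — no network is instantiated and nothing is
executed.  Conventions:

* Parameters: every trainable element (conv kernels and biases, batch-norm
  affine pairs, the two fusion weight maps, ConvLSTM gate kernels, peephole
  maps and biases, head weights).
* FLOPs: one multiply-accumulate counted as one FLOP (the convention under
  which lightweight video models report "FLOPs"); the 2x-MAC figure is also
  reported.  Pointwise work (frame aggregation, difference/fusion maps, batch
  norm, gate nonlinearities, residual additions) is tallied separately and
  included in the total; it is two orders of magnitude below the
  convolutional MACs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import expected_output_frames
from .backbone import BackboneConfig, _ceil_div

__all__ = ["ComplexityReport", "count_params", "count_flops"]


@dataclass
class ComplexityReport:
    params: int
    macs: int
    pointwise_flops: int
    breakdown: dict = field(default_factory=dict)

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def flops(self) -> int:
        """Total forward FLOPs under the MAC-as-one-FLOP convention."""
        return self.macs + self.pointwise_flops

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    @property
    def gflops_2x(self) -> float:
        """The 2 x MAC accounting some papers use instead."""
        return (2 * self.macs + self.pointwise_flops) / 1e9

    def __str__(self):
        lines = [f"parameters : {self.params:>12,d}  ({self.params_m:.3f} M)",
                 f"MACs       : {self.macs:>12,d}",
                 f"FLOPs      : {self.flops:>12,d}  ({self.gflops:.3f} G, "
                 f"{self.gflops_2x:.3f} G at 2xMAC)"]
        for k, v in self.breakdown.items():
            lines.append(f"  {k:<18s} params={v[0]:>10,d}  macs={v[1]:>12,d}")
        return "\n".join(lines)


def _conv_params(c_in, c_out, kernel, bias=True, bn=True):
    k = int(np.prod(kernel))
    p = c_out * c_in * k + (c_out if bias else 0)
    if bn:
        p += 2 * c_out
    return p


def _conv_macs(c_in, c_out, kernel, out_positions):
    return c_out * c_in * int(np.prod(kernel)) * out_positions


def count_params(cfg: BackboneConfig, input_shape: tuple,
                 use_stdwm: bool = True, use_convlstm: bool = True,
                 learnable_phi: bool = False) -> int:
    """Total trainable parameters for ``cfg`` at the given (C,T,H,W) input."""
    return _account(cfg, input_shape, use_stdwm=use_stdwm,
                    use_convlstm=use_convlstm, learnable_phi=learnable_phi,
                    raw_T=None, window_mode=None).params


def count_flops(cfg: BackboneConfig, input_shape: tuple,
                raw_T: int | None = None, window_mode: str | None = None,
                use_stdwm: bool = True, use_convlstm: bool = True,
                learnable_phi: bool = False) -> ComplexityReport:
    """Forward-pass cost for one clip at the given aggregated input shape.

    If ``raw_T``/``window_mode`` are given, the cost of aggregating the raw
    clip down to ``input_shape[1]`` frames is included.
    """
    return _account(cfg, input_shape, use_stdwm=use_stdwm,
                    use_convlstm=use_convlstm, learnable_phi=learnable_phi,
                    raw_T=raw_T, window_mode=window_mode)


def _account(cfg: BackboneConfig, input_shape: tuple, *, use_stdwm: bool,
             use_convlstm: bool, learnable_phi: bool,
             raw_T: int | None, window_mode: str | None) -> ComplexityReport:
    C, T, H, W = input_shape
    params = 0
    macs = 0
    pointwise = 0
    breakdown = {}

    # frame aggregation (pointwise attention weighting)
    agg_params = 2 * C if learnable_phi else 0
    agg_flops = 0
    if raw_T is not None and window_mode is not None:
        out_T = expected_output_frames(raw_T, window_mode)
        if out_T != T:
            raise ValueError(
                f"aggregating {raw_T} frames ({window_mode}) gives {out_T}, "
                f"but the network input has T={T}")
        per_el = 13  # 2 weight maps (product, scale, norm divide, gate) + blend
        agg_flops = per_el * out_T * C * H * W
        if learnable_phi:
            agg_flops += 4 * raw_T * C * H * W  # scale + shift on both phi maps
    params += agg_params
    pointwise += agg_flops
    breakdown["aggregation"] = (agg_params, agg_flops)

    # temporal-difference fusion
    if use_stdwm:
        n_el = C * T * H * W
        n_steps = len(cfg.diff_steps)
        sw_params = 2 * n_el
        sw_flops = (2 * n_steps + (n_steps - 1) + 3) * n_el  # diffs, mean, fuse
        params += sw_params
        pointwise += sw_flops
        breakdown["stdwm"] = (sw_params, sw_flops)

    # residual 3-D stages
    shapes = cfg.trace_shapes((C, T, H, W))
    c_prev = C
    stage_params = stage_macs = stage_point = 0
    for i, width in enumerate(cfg.stage_channels):
        _, t_o, h_o, w_o = shapes[i + 1]
        out_pos = t_o * h_o * w_o
        for b in range(cfg.blocks_per_stage):
            c_in = c_prev if b == 0 else width
            for j in range(cfg.convs_per_block):
                cj = c_in if j == 0 else width
                stage_params += _conv_params(cj, width, cfg.conv_kernel)
                stage_macs += _conv_macs(cj, width, cfg.conv_kernel, out_pos)
                stage_point += 4 * width * out_pos       # BN affine + ReLU
            if b == 0 and (c_in != width or cfg.stage_stride(i) != (1, 1, 1)):
                stage_params += _conv_params(c_in, width, (1, 1, 1), bn=False)
                stage_macs += _conv_macs(c_in, width, (1, 1, 1), out_pos)
            stage_point += width * out_pos               # skip addition
        c_prev = width
    params += stage_params
    macs += stage_macs
    pointwise += stage_point
    breakdown["3d-cnn"] = (stage_params, stage_macs)

    # recurrent layer
    c_out, t_out, h_out, w_out = shapes[-1]
    hid = cfg.convlstm_hidden
    if use_convlstm:
        kHW = cfg.convlstm_kernel
        in_ch, sp_pos = c_out, h_out * w_out
    else:
        kHW = (1, 1)
        in_ch, sp_pos = c_out * h_out * w_out, 1
    rec_params = (4 * _conv_params(in_ch, hid, kHW, bias=False, bn=False)
                  + 4 * _conv_params(hid, hid, kHW, bias=False, bn=False)
                  + 3 * hid * sp_pos          # peephole maps
                  + 4 * hid)                  # gate biases
    per_step = (4 * _conv_macs(in_ch, hid, kHW, sp_pos)
                + 4 * _conv_macs(hid, hid, kHW, sp_pos))
    rec_macs = per_step * t_out
    rec_point = 13 * hid * sp_pos * t_out     # peepholes, gates, state updates
    params += rec_params
    macs += rec_macs
    pointwise += rec_point
    breakdown["convlstm" if use_convlstm else "fc-lstm"] = (rec_params, rec_macs)

    # regression head
    head_params = head_macs = 0
    c_in = hid
    sp = h_out * w_out if use_convlstm else 1
    for c in cfg.head_channels:
        head_params += _conv_params(c_in, c, (1, 3, 3))
        head_macs += _conv_macs(c_in, c, (1, 3, 3), sp)
        c_in = c
    head_params += c_in + 1                   # linear unit
    head_macs += c_in
    params += head_params
    macs += head_macs
    breakdown["head"] = (head_params, head_macs)

    return ComplexityReport(params=int(params), macs=int(macs),
                            pointwise_flops=int(pointwise), breakdown=breakdown)
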
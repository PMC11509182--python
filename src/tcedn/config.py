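"""Experiment configuration: YAML files mapped onto the dataclasses.

Two configurations ship with the package: ``reference`` (the full eye-strip
geometry used for complexity accounting) and ``scaled`` (the half-width
desk-scale study on synthetic clips).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .aggregation import AggregationConfig
from .backbone import BackboneConfig
from .training import TrainConfig

__all__ = ["InputSpec", "ExperimentConfig", "load_config",
           "reference_config", "scaled_config"]


@dataclass
class InputSpec:
    channels: int = 3
    frame_height: int = 80
    frame_width: int = 270
    frames_per_clip: int = 48


@dataclass
class ExperimentConfig:
    input: InputSpec = field(default_factory=InputSpec)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def aggregated_input_shape(self) -> tuple:
        """Network input (C, T', H, W) after frame aggregation."""
        T = self.input.frames_per_clip
        if self.aggregation.window_mode == "sliding":
            T_out = T - 2
        else:
            T_out = T // 3
        return (self.input.channels, T_out,
                self.input.frame_height, self.input.frame_width)


def _build(doc: dict) -> ExperimentConfig:
    inp = InputSpec(**doc.get("input", {}))
    agg = AggregationConfig(**doc.get("aggregation", {}))
    stdwm = doc.get("stdwm", {})
    bdoc = dict(doc.get("backbone", {}))
    for key in ("stage_channels", "conv_kernel", "temporal_stride_stages",
                "convlstm_kernel", "head_channels"):
        if key in bdoc:
            bdoc[key] = tuple(bdoc[key])
    backbone = BackboneConfig(
        in_channels=inp.channels,
        diff_steps=tuple(stdwm.get("steps", (1,))),
        diff_fuse_mode=stdwm.get("fuse_mode", "single"),
        init_wv=stdwm.get("init_wv", 1.0),
        init_wd=stdwm.get("init_wd", 0.1),
        **bdoc,
    )
    train = TrainConfig(**doc.get("train", {}))
    return ExperimentConfig(input=inp, aggregation=agg,
                            backbone=backbone, train=train)


def load_config(source) -> ExperimentConfig:
    """Load a configuration from a YAML path or a shipped name."""
    if isinstance(source, (str, Path)) and not str(source).endswith((".yaml", ".yml")):
        text = (resources.files("tcedn") / "configs" / f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return _build(yaml.safe_load(text))


def reference_config() -> ExperimentConfig:
    return load_config("reference")


def scaled_config() -> ExperimentConfig:
    return load_config("scaled")
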
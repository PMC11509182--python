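"""Layer primitives: parameter containers, convolutions, batch norm, linear."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Parameter", "Module", "Conv3d", "Conv2d", "BatchNorm3d", "Linear"]


class Parameter(Tensor):
    """A trainable tensor (float32 storage)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, train/eval flag."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _children(obj, prefix):
        """Yield (name, Module-or-Parameter) pairs, recursing through lists."""
        if isinstance(obj, (Module, Parameter)):
            yield prefix, obj
        elif isinstance(obj, (list, tuple)):
            for i, item in enumerate(obj):
                yield from Module._children(item, f"{prefix}.{i}")

    def _named_children(self, prefix: str = ""):
        for name, v in vars(self).items():
            yield from Module._children(v, f"{prefix}{name}")

    def modules(self):
        yield self
        for _, v in self._named_children():
            if isinstance(v, Module):
                yield from v.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self._named_children(prefix):
            if isinstance(v, Parameter):
                yield name, v
            else:
                yield from v.named_parameters(f"{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, m in self._named_modules():
            for bname in getattr(m, "_buffers", {}):
                key = f"{name}{bname}"
                if key in state:
                    m._buffers[bname] = state[key].copy()

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, v in self._named_children(prefix):
            if isinstance(v, Module):
                yield from v._named_modules(f"{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    """Same-padded 3-D convolution with optional stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3),
                 stride=(1, 1, 1), bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kT, kH, kW = kernel
        fan_in = in_ch * kT * kH * kW
        self.stride = tuple(stride)
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kT, kH, kW), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding="same")


class Conv2d(Module):
    """2-D convolution expressed on (B, C, 1, H, W) maps via Conv3d."""

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3), bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, kernel=(1, *kernel), bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class BatchNorm3d(Module):
    """Per-channel batch normalization over (batch, time, height, width).

    Training mode normalizes with batch statistics and updates running
    estimates with momentum 0.1; evaluation mode uses the running estimates.
    The affine map initializes to the identity.
    """

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self._buffers = {
            "running_mean": np.zeros(num_ch, dtype=np.float32),
            "running_var": np.ones(num_ch, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        sh = (1, C, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            ).astype(np.float32)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            ).astype(np.float32)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(sh))
            var = Tensor(self._buffers["running_var"].reshape(sh))
        xhat = (x - mu) / ((var + self.eps).sqrt())
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
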
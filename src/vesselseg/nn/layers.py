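"""Module system built on the autodiff tensors: parameter registration,
train/eval mode, state dicts, and the layers the segmentation network uses.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as F
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "Linear", "BatchNorm2d", "InstanceNorm2d", "LayerNorm", "ReLU",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class; submodules and parameters are discovered by attribute walk."""

    def __init__(self):
        self.training = True

    # -- registration ---------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- serialization --------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, value in vars(self).items():
            if isinstance(value, BatchNorm2d):
                state[f"{name}.running_mean"] = value.running_mean.copy()
                state[f"{name}.running_var"] = value.running_var.copy()
            elif isinstance(value, Module):
                sub = value.state_dict()
                for k, v in sub.items():
                    if k.endswith(("running_mean", "running_var")):
                        state[f"{name}.{k}"] = v
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: {params[name].data.shape} vs {arr.shape}")
                params[name].data = arr.astype(params[name].data.dtype)
            elif name.endswith(("running_mean", "running_var")):
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = getattr(obj, part)
                    if isinstance(obj, (ModuleList, Sequential)) is False and not isinstance(obj, Module):
                        raise KeyError(name)
                setattr(obj, attr, arr.copy())
            else:
                raise KeyError(f"unexpected state entry {name}")

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = m.running_mean.astype(dtype)
                m.running_var = m.running_var.astype(dtype)
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._mods = list(mods)
        for i, m in enumerate(self._mods):
            setattr(self, f"m{i}", m)

    def append(self, m):
        setattr(self, f"m{len(self._mods)}", m)
        self._mods.append(m)

    def __iter__(self):
        return iter(self._mods)

    def __len__(self):
        return len(self._mods)

    def __getitem__(self, i):
        return self._mods[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


def _he_conv(rng: np.random.Generator, cout: int, cin: int, k: int, dtype):
    fan_in = cin * k * k
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype)


class Conv2d(Module):
    """Stride-1, same-padding convolution with odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.weight = Parameter(_he_conv(rng, out_ch, in_ch, kernel, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(1.0 / in_f)
        self.weight = Parameter((rng.uniform(-std, std, (in_f, out_f))).astype(dtype))
        self.bias = Parameter(np.zeros(out_f, dtype=dtype)) if bias else None

    def forward(self, x):
        y = F.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._calibrating = False
        self._calib_n = 0

    def start_calibration(self):
        """Re-estimate running statistics as an exact cumulative average of
        the batch statistics seen until :meth:`stop_calibration`.

        Exponential running averages taken while the weights are still
        moving can drift arbitrarily far from the converged activation
        statistics; recalibrating with frozen weights removes the
        train/eval normalization mismatch.
        """
        self._calibrating = True
        self._calib_n = 0

    def stop_calibration(self):
        self._calibrating = False

    def forward(self, x):
        C = self.gamma.data.shape[0]
        shape = (1, C, 1, 1)
        if self.training:
            if self._calibrating:
                self._calib_n += 1
                m = 1.0 / self._calib_n  # cumulative moving average
            else:
                m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * x.data.mean(axis=(0, 2, 3))).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * x.data.var(axis=(0, 2, 3))).astype(self.running_var.dtype)
            return F.batch_norm(x, self.gamma, self.beta, self.eps)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - Tensor(self.running_mean.reshape(shape))) * Tensor(inv.reshape(shape))
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class InstanceNorm2d(Module):
    """Affine instance normalization over each (sample, channel) plane.

    The small-batch-friendly choice for segmentation: no running
    statistics, no train/eval behaviour gap, no batch coupling.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x):
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class LayerNorm(Module):
    """LayerNorm over the last dimension (token feature axis)."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x):
        return F.layer_norm(x, self.gamma, self.beta, self.eps)
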
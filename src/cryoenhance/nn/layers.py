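"""Neural-network building blocks on top of the autodiff engine.

Follows the familiar Module/Parameter pattern: modules own parameters and
sub-modules, `parameters()` walks the tree, `train()`/`eval()` toggle
dropout and batch-norm statistics.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d, conv_transpose3d_2x, leaky_relu

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Parameter",
    "Linear",
    "Conv3d",
    "ConvTranspose3d2x",
    "BatchNorm3d",
    "InstanceNorm3d",
    "Dropout",
    "LeakyReLU",
    "Adam",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- tree walking ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _children(self):
        return [v for v in vars(self).values() if isinstance(v, Module)]

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- state dict -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float32)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected state entry {name}")
        missing = (set(params) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, f"m{i}")


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self:
            x = m(x)
        return x


def _he_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float32) * np.sqrt(2.0 / fan_in)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_fan_in(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel**3
        self.weight = Parameter(_he_fan_in(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose3d2x(Module):
    """Kernel-2 stride-2 transposed convolution: doubles every spatial edge."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_fan_in(rng, (in_ch, out_ch, 2, 2, 2), in_ch * 8))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d_2x(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1, 1), dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3, 4), keepdims=True)
            self.running_mean += self.momentum * (m.data - self.running_mean)
            self.running_var += self.momentum * (v.data - self.running_var)
        else:
            m = Tensor(self.running_mean)
            v = Tensor(self.running_var)
        xh = (x - m) * (v + self.eps) ** -0.5
        return xh * self.gamma + self.beta


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
            self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.affine = affine

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(2, 3, 4), keepdims=True)
        v = ((x - m) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xh = (x - m) * (v + self.eps) ** -0.5
        if self.affine:
            xh = xh * self.gamma + self.beta
        return xh


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.negative_slope)


class Adam:
    """Adam optimizer (Kingma & Ba) with optional gradient-norm clipping."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params
                                if p.grad is not None))
            scale = min(1.0, self.clip_norm / (total + 1e-12))
        else:
            scale = 1.0
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
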
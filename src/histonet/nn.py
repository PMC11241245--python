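"""Layer modules over the autodiff engine.

Thin, torch-like containers: each layer owns its parameter tensors and
implements ``__call__``; :class:`Module` provides recursive parameter
collection, train/eval mode switching and a flat named state dict for
checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    training: bool = True

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(params[name].data.dtype)
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "buffer" and name in buffers:
                buffers[name][...] = value


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return ad.silu(x)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel_size, stride=1, padding=0, bias=False, rng=None):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ad.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        if self.training:
            out, mu, var = ad.batch_norm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
            return out
        return ad.batch_norm_eval(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.eps
        )


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        w = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=out_features).astype(np.float32),
            requires_grad=True,
        ) if bias else None

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)


class Dropout(Module):
    def __init__(self, p: float = 0.2, seed: int = 0):
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return ad.dropout(x, self.p, self.rng, self.training)
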
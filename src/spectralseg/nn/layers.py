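"""Layer/module abstractions over the autodiff tensor ops."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter discovery walks attributes recursively."""

    training: bool = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Module, Tensor)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, (Module, Tensor)):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield full, value  # frozen params are still serialised
            else:
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, value in self._children():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialisation -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running["mean"].copy()
                state[f"__bn{i}.var"] = m.running["var"].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("__bn"):
                continue
            if name not in params:
                raise KeyError(f"unexpected parameter {name!r} in checkpoint")
            if params[name].data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model {params[name].data.shape}, "
                    f"checkpoint {value.shape}"
                )
            params[name].data = value.astype(params[name].data.dtype).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running["mean"] = state[f"__bn{i}.mean"].copy()
                m.running["var"] = state[f"__bn{i}.var"].copy()


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Stride-1 same-padded convolution with He-normal initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, *, rng: np.random.Generator, dtype=np.float32) -> None:
        k = kernel_size
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """2x2, stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        std = np.sqrt(2.0 / (in_channels * 4))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_channels, out_channels, 2, 2)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2x2(x, self.weight, self.bias)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2x2(x)


class InstanceNorm2d(Module):
    """Affine-free instance normalisation (the default for all blocks)."""

    def __init__(self, num_channels: int, eps: float = 1e-5) -> None:
        self.num_channels = num_channels
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.instance_norm(x, eps=self.eps)


class BatchNorm2d(Module):
    """Batch normalisation with affine terms and running statistics."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        self.gamma = Tensor(np.ones(num_channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, dtype=dtype), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running = {
            "mean": np.zeros(num_channels, dtype=np.float64),
            "var": np.ones(num_channels, dtype=np.float64),
        }

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(x, self.gamma, self.beta, self.running,
                            training=self.training, momentum=self.momentum, eps=self.eps)


class PReLU(Module):
    """PReLU with one learned negative slope (initially 0.25)."""

    def __init__(self, init: float = 0.25, dtype=np.float32) -> None:
        self.slope = Tensor(np.asarray(init, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.prelu(x, self.slope)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01) -> None:
        self.negative_slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.negative_slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(x)


def make_activation(name: str, dtype=np.float32) -> Module:
    if name == "prelu":
        return PReLU(dtype=dtype)
    if name == "leaky_relu":
        return LeakyReLU()
    if name == "relu":
        return ReLU()
    raise ValueError(f"unknown activation {name!r}")


def make_norm(kind: str, channels: int) -> Module:
    if kind == "instance":
        return InstanceNorm2d(channels)
    if kind == "batch":
        return BatchNorm2d(channels)
    raise ValueError(f"unknown normalization {kind!r} (use 'instance' or 'batch')")


class ConvBlock(Module):
    """Two (conv -> norm -> activation) stages, the standard U-Net block."""

    def __init__(self, in_channels: int, out_channels: int, *, activation: str,
                 normalization: str = "instance", rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.net = Sequential(
            Conv2d(in_channels, out_channels, 3, rng=rng, dtype=dtype),
            make_norm(normalization, out_channels),
            make_activation(activation, dtype),
            Conv2d(out_channels, out_channels, 3, rng=rng, dtype=dtype),
            make_norm(normalization, out_channels),
            make_activation(activation, dtype),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)
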
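"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "MaxPool2",
    "Flatten",
    "Sequential",
]


class Module:
    """Base class: parameter registry, train/eval mode, state (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, data: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(data, dtype=np.float32)
        return self._buffers[name]

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for m in self._modules.values():
            m.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data.copy()
        for k, v in self._buffers.items():
            out[prefix + k] = v.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = np.asarray(state[prefix + k], dtype=np.float32).copy()
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = self.register_param(
            "w", rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        )
        self.b = self.register_param("b", np.zeros(n_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
    ):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.w = self.register_param(
            "w", rng.normal(0.0, 0.02, size=(c_out, c_in, k, k)).astype(np.float32)
        )
        self.b = self.register_param("b", np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
    ):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.w = self.register_param(
            "w", rng.normal(0.0, 0.02, size=(c_in, c_out, k, k)).astype(np.float32)
        )
        self.b = self.register_param("b", np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.w, self.b, self.stride, self.pad)


class BatchNorm(Module):
    """Batch normalization over the batch (and spatial axes for 4-D input)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register_param("gamma", np.ones(c, dtype=np.float32))
        self.beta = self.register_param("beta", np.zeros(c, dtype=np.float32))
        self.running_mean = self.register_buffer("running_mean", np.zeros(c))
        self.running_var = self.register_buffer("running_var", np.ones(c))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 4:
            axes, shape = (0, 2, 3), (1, -1, 1, 1)
        else:
            axes, shape = (0,), (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape)
            xn = (x - mu) * Tensor(1.0 / sd)
        return xn * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
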
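"""Module/parameter containers and the layers used by the volumetric models."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batchnorm, conv3d, conv_transpose3d

__all__ = [
    "Parameter", "Module", "Sequential", "Linear", "Conv3d", "ConvTranspose3d",
    "BatchNorm3d", "LeakyReLU", "ReLU", "Sigmoid", "Identity",
    "xavier_uniform", "calculate_gain",
]


def calculate_gain(activation: str, slope: float = 0.2) -> float:
    if activation in ("relu",):
        return float(np.sqrt(2.0))
    if activation in ("leaky_relu",):
        return float(np.sqrt(2.0 / (1.0 + slope**2)))
    if activation in ("tanh",):
        return 5.0 / 3.0
    return 1.0


def xavier_uniform(shape, fan_in, fan_out, gain, rng) -> np.ndarray:
    bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Parameter(Tensor):
    def __init__(self, data):
        from .autograd import default_dtype
        super().__init__(np.asarray(data, dtype=default_dtype()), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_state(self, prefix=""):
        out = {}
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.named_state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_state(prefix=f"{key}.{i}."))
            elif isinstance(v, np.ndarray):  # buffers (BN running stats)
                out[key] = v
        return out

    def load_state(self, state, prefix=""):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                v.data = np.array(state[key], dtype=v.data.dtype)
            elif isinstance(v, Module):
                v.load_state(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
            elif isinstance(v, np.ndarray):
                setattr(self, k, np.array(state[key], dtype=v.dtype))

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @property
    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float64

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Linear(Module):
    def __init__(self, n_in, n_out, rng, gain=1.0):
        super().__init__()
        self.weight = Parameter(xavier_uniform((n_out, n_in), n_in, n_out, gain, rng))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x):
        return x @ self.weight.T + self.bias


class Conv3d(Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, gain=1.0):
        super().__init__()
        fan_in = c_in * kernel**3
        fan_out = c_out * kernel**3
        self.weight = Parameter(
            xavier_uniform((c_out, c_in, kernel, kernel, kernel), fan_in, fan_out, gain, rng)
        )
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, gain=1.0):
        super().__init__()
        fan_in = c_in * kernel**3
        fan_out = c_out * kernel**3
        self.weight = Parameter(
            xavier_uniform((c_in, c_out, kernel, kernel, kernel), fan_in, fan_out, gain, rng)
        )
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm3d(Module):
    """Batch statistics in training mode, running statistics in eval mode.

    Eval mode is an affine (hence linear) per-channel map, which keeps
    path-integral attributions well defined.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        from .autograd import default_dtype
        self.running_mean = np.zeros(channels, dtype=default_dtype())
        self.running_var = np.ones(channels, dtype=default_dtype())
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            axes = (0,) + tuple(range(2, x.data.ndim))
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return batchnorm(x, self.gamma, self.beta, self.eps)
        # eval: affine map with running stats; gamma/beta treated as constants
        # (the encoder is frozen whenever eval mode is used here)
        shape = [1] * x.data.ndim
        shape[1] = -1
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor((self.gamma.data * inv).reshape(shape))
        shift = Tensor((self.beta.data - self.gamma.data * inv * self.running_mean).reshape(shape))
        return x * scale + shift
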
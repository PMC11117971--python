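"""Neural-network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, softmax

__all__ = ["Module", "Conv2d", "Sequential", "ReLU", "NonLocalBlock", "BatchNorm2d"]


class Module:
    """Base class: parameter discovery by attribute walk, torch-style."""

    training = True

    def train_mode(self, flag=True):
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train_mode(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train_mode(flag)
        return self

    def buffers_dict(self, prefix=""):
        out = {}
        for name in getattr(self, "_buffers", ()):
            out[prefix + name] = getattr(self, name)
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                out.update(v.buffers_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.buffers_dict(f"{prefix}{k}.{i}."))
        return out

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self, prefix=""):
        out = {}
        for name in getattr(self, "_buffers", ()):
            out[prefix + name] = np.array(getattr(self, name))
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[prefix + k] = v.data
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{k}.{i}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for name in getattr(self, "_buffers", ()):
            setattr(self, name, np.array(state[prefix + name], dtype=np.float64))
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.array(state[prefix + k], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, pad=None, rng=None, zero_init=False):
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            rng = rng if rng is not None else np.random.default_rng()
            fan_in = c_in * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class BatchNorm2d(Module):
    """Per-channel batch normalization over (batch, height, width).

    Keeps the pre-activation distribution centered — placed before the
    selection sigmoid it prevents the scores from saturating collectively,
    while the learnable shift gives the coverage level a single fast
    control. Inference uses exponential running statistics.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels, eps=1e-5, momentum=0.1, beta_init=0.0,
                 gamma_init=1.0):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.full(channels, float(gamma_init)), requires_grad=True)
        self.beta = Tensor(np.full(channels, float(beta_init)), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return self.gamma.reshape(1, c, 1, 1) * xhat + self.beta.reshape(1, c, 1, 1)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class NonLocalBlock(Module):
    """Embedded-Gaussian self-attention with a residual connection.

    ``y = x + W_z · (softmax(θ(x)ᵀ φ(x)) g(x))`` with θ, φ, g pointwise
    convolutions to ``c // 2`` channels. ``W_z`` is zero-initialized so the
    block is exactly the identity at initialization, which keeps early
    training stable.
    """

    def __init__(self, channels, rng=None):
        inner = max(channels // 2, 1)
        self.inner = inner
        self.theta = Conv2d(channels, inner, 1, rng=rng)
        self.phi = Conv2d(channels, inner, 1, rng=rng)
        self.g = Conv2d(channels, inner, 1, rng=rng)
        self.w_z = Conv2d(inner, channels, 1, zero_init=True)

    def forward(self, x):
        b, c, h, w = x.shape
        n = h * w
        th = self.theta(x).reshape(b, self.inner, n).transpose((0, 2, 1))  # (b,n,i)
        ph = self.phi(x).reshape(b, self.inner, n)  # (b,i,n)
        attn = softmax(th @ ph, axis=2)  # (b,n,n)
        gv = self.g(x).reshape(b, self.inner, n).transpose((0, 2, 1))  # (b,n,i)
        y = (attn @ gv).transpose((0, 2, 1)).reshape(b, self.inner, h, w)
        return x + self.w_z(y)
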
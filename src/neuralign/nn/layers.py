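"""Network building blocks on top of the autograd engine.

Layers hold their parameters as :class:`Tensor` objects; modules expose
``parameters()`` for the optimizer.  Weight initialization is fan-in scaled
("He") Gaussian, drawn from a numpy ``Generator`` so that a seed fully
determines the model.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d, conv3d_1x1, zero_upsample2


class Module:
    def parameters(self) -> list[Tensor]:
        out = []

        def collect(v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    out.append(v)
            elif isinstance(v, Module):
                for item in v.__dict__.values():
                    collect(item)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in self.__dict__.values():
            collect(v)
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv3d(Module):
    """3x3x3 'same' convolution (or 1x1x1 pointwise with ``kernel=1``)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, zero_init: bool = False):
        if kernel not in (1, 3):
            raise ValueError("only kernel sizes 1 and 3 are supported")
        self.kernel = kernel
        fan_in = cin * kernel**3
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        shape = (cout, cin) if kernel == 1 else (cout, cin, 3, 3, 3)
        self.weight = Tensor(scale * rng.standard_normal(shape), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.kernel == 1:
            return conv3d_1x1(x, self.weight, self.bias)
        return conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Stride-2 transposed convolution: zero-stuffing then a 'same' conv.

    Doubles every spatial dimension; kernel size 3.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv3d(cin, cout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(zero_upsample2(x))


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial extent of one volume.

    Training here uses batch size 1, so normalization statistics are always
    the current volume's own spatial moments (deterministic at inference).
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((channels, 1, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class GroupNorm(Module):
    """Group normalization over (channel-group, spatial) slices."""

    def __init__(self, channels: int, group_size: int, eps: float = 1e-5):
        if channels % group_size:
            raise ValueError("channels must be divisible by group size")
        self.group_size = group_size
        self.gamma = Tensor(np.ones((channels, 1, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        c, X, Y, Z = x.data.shape
        g = self.group_size
        xg = x.reshape(c // g, g * X * Y * Z)
        mu = xg.mean(axis=1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = (xc / (var + self.eps).sqrt()).reshape(c, X, Y, Z)
        return self.gamma * xn + self.beta


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
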
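"""Layers for the Siamese volume network, built on :mod:`tomoshot.autodiff`.

Includes the dual squeeze-and-excitation (DuSE) block: a channel-recalibration
branch (global average pool -> bottleneck MLP -> sigmoid gate per channel) and
a spatial-recalibration branch (1x1x1 convolution -> sigmoid gate per voxel),
fused by elementwise addition.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel**3
        self.weight = Parameter(he_normal(rng, (c_out, c_in, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(he_normal(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W, D) -> (B, C): mean of each channel over all voxels."""
    return x.mean(axis=(2, 3, 4))


class GroupNorm(Module):
    """Group normalization over channel groups with per-channel affine.

    Batch-size independent, so train/inference behavior is identical —
    the right normalizer for batches of a handful of volumes.
    """

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w, d = x.shape
        g = self.groups
        xg = x.reshape(b, g, (c // g) * h * w * d)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = (xc / (var + self.eps).sqrt()).reshape(b, c, h, w, d)
        return xn * self.gamma.reshape(1, c, 1, 1, 1) \
            + self.beta.reshape(1, c, 1, 1, 1)


class ChannelSqueezeExcite(Module):
    """Channel gate v_hat = sigmoid(w2 relu(w1 v)), v = spatial mean per channel."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        # the squeeze path is bias-free in the recalibration formulation
        self.fc1.bias.requires_grad = False
        self.fc2.bias.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        v = global_avg_pool(x)                      # (B, C)
        gate = self.fc2(self.fc1(v).relu()).sigmoid()
        b, c = gate.shape
        return x * gate.reshape(b, c, 1, 1, 1)


class SpatialSqueezeExcite(Module):
    """Voxel gate m_hat = sigmoid(w3 * F), w3 a 1x1x1 convolution to 1 channel."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = Conv3d(channels, 1, 1, rng)
        self.conv.bias.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        gate = self.conv(x).sigmoid()               # (B, 1, H, W, D)
        return x * gate


class DuSE(Module):
    """Dual squeeze-and-excitation: elementwise sum of both recalibrations."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        self.cse = ChannelSqueezeExcite(channels, reduction, rng)
        self.sse = SpatialSqueezeExcite(channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cse(x) + self.sse(x)


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
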
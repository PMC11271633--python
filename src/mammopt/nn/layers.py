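"""Neural-network building blocks on top of the autograd engine.

Initialisation is He-style for conv/linear weights, drawn from a caller-
supplied ``numpy.random.Generator`` so that identical seeds give identical
parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "SqueezeExcite",
    "AttentionGate",
]


class Module:
    """Base container; discovers parameters on attributes recursively."""

    def named_params(self, prefix: str = ""):
        out = []
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_params(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_params(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def params(self):
        return [p for _, p in self.named_params()]

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_params()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_params():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            p.data[...] = state[k]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, dilation=self.dilation)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin)
        self.w = Tensor(rng.normal(0.0, std, size=(fin, fout)), requires_grad=True)
        self.b = Tensor(np.zeros(fout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class LayerNorm(Module):
    """Normalisation over the last dimension with learned scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.g + self.b


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation with learned affine.

    Unlike batch norm it keeps no running statistics, so train/eval
    behaviour is identical and fully deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.b = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (N, T, C) tokens."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dh = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        N, T, C = x.shape
        h, dh = self.heads, self.dh

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, T, h, dh).transpose(0, 2, 1, 3)  # (N, h, T, dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(N, T, C)
        return self.proj(out)


class SqueezeExcite(Module):
    """Channel attention: global pool -> bottleneck MLP -> sigmoid gates."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        hidden = max(2, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        z = x.mean(axis=(2, 3))                    # (N, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()  # (N, C)
        return x * s.reshape(N, C, 1, 1)


class AttentionGate(Module):
    """Additive attention gate for U-Net skip connections.

    The decoder feature g (gating signal) and the encoder skip s are
    projected to a common width, summed, and squashed to a single-channel
    spatial gate that multiplies the skip.
    """

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int,
                 rng: np.random.Generator | None = None):
        self.wg = Conv2d(gate_ch, inter_ch, k=1, rng=rng)
        self.wx = Conv2d(skip_ch, inter_ch, k=1, rng=rng)
        self.psi = Conv2d(inter_ch, 1, k=1, rng=rng)

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        a = (self.wg(gate) + self.wx(skip)).relu()
        return skip * self.psi(a).sigmoid()
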
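"""Backbone numerics: residual blocks and channel/spatial attention gates.

The backbone is a bottleneck residual network (conv1×1–BN–ReLU–conv3×3–
BN–ReLU–conv1×1–BN, residual add, ReLU) emitting four feature maps C2–C5
at strides 4/8/16/32.  Three attention operators can be appended after
every residual unit of the third and fourth stages, where semantic
features live:

* **SE** — squeeze-and-excitation: global average pooling to a channel
  descriptor z, then s = σ(W₂ δ(W₁ z)) rescales each channel.
* **GCA** — global-context attention: a spatial softmax of the map itself
  provides pooling weights p (per channel, as this model defines it);
  g_c = Σ p·x_c feeds the same two-layer gate.
* **CBAM** — channel gate from a shared MLP over average- and max-pooled
  descriptors, followed by a spatial gate from a 7×7 convolution over the
  channel-wise average and maximum maps.

All gates multiply the input by factors in (0, 1), so they preserve shape
and never amplify a non-negative activation.  Functional wrappers accept
plain ``(C, H, W)`` numpy arrays; the module classes run on NCHW tensors
and are differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ag
from .autodiff import (BatchNorm2d, Conv2d, Linear, Module, Tensor, as_tensor,
                       no_grad)

ATTENTION_KINDS = ("CBAM", "SE", "GCA")


@dataclass(frozen=True)
class AttentionConfig:
    kind: str = "CBAM"
    reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.kind not in ATTENTION_KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")


@dataclass
class NormParams:
    gamma: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if np.any(np.asarray(self.sigma2) < 0):
            raise ValueError("variance must be non-negative")


# -- functional operators on plain arrays --------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def batch_norm(x: np.ndarray, params: NormParams) -> np.ndarray:
    """Per-channel batch normalisation γ(x−μ)/√(σ²+ε) + β.

    ``x`` has channels on its first axis (C, ...) or (N, C, H, W) with
    per-channel statistics broadcast along the remaining axes.
    """
    x = np.asarray(x, dtype=np.float64)
    c_axis = 1 if x.ndim == 4 else 0
    shape = [1] * x.ndim
    shape[c_axis] = -1
    g = np.reshape(params.gamma, shape)
    b = np.reshape(params.beta, shape)
    mu = np.reshape(params.mu, shape)
    s2 = np.reshape(params.sigma2, shape)
    return g * (x - mu) / np.sqrt(s2 + params.epsilon) + b


def _run_chw(module: Module, x: np.ndarray) -> np.ndarray:
    """Apply an NCHW module to a single (C, H, W) array, eval mode."""
    x = np.asarray(x, dtype=np.float64)
    was_training = module.training
    module.eval()
    with no_grad():
        out = module(Tensor(x[None])).numpy()[0]
    if was_training:
        module.train()
    return out


# -- attention modules ----------------------------------------------------

def _hidden_width(c: int, r: int) -> int:
    return max(1, c // r)


class SEAttention(Module):
    def __init__(self, c: int, reduction: int = 16, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = _hidden_width(c, reduction)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        z = ag.mean(x, axis=(2, 3))  # (N, C) global average pool
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))

    def forward(self, x):
        x = as_tensor(x)
        s = self.channel_weights(x)
        return ag.mul(x, ag.reshape(s, (x.shape[0], x.shape[1], 1, 1)))


class GCAAttention(Module):
    """Global-context gate.  Default pooling: per-channel spatial softmax
    of the map itself; ``shared_context=True`` instead predicts a single
    softmax attention map with a learned 1×1 convolution shared by all
    channels (the form the cited context block uses)."""

    def __init__(self, c: int, reduction: int = 16, shared_context: bool = False,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = _hidden_width(c, reduction)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)
        self.shared_context = shared_context
        self.logit_conv = Conv2d(c, 1, 1, rng=rng) if shared_context else None

    def context(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if self.shared_context:
            logits = ag.reshape(self.logit_conv(x), (N, 1, H * W))
        else:
            logits = ag.reshape(x, (N, C, H * W))
        p = ag.softmax(logits, axis=-1)
        flat = ag.reshape(x, (N, C, H * W))
        return ag.sum_(ag.mul(flat, p), axis=-1)  # (N, C)

    def forward(self, x):
        x = as_tensor(x)
        g = self.context(x)
        w = ag.sigmoid(self.fc2(ag.relu(self.fc1(g))))
        return ag.mul(x, ag.reshape(w, (x.shape[0], x.shape[1], 1, 1)))


class CBAM(Module):
    def __init__(self, c: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = _hidden_width(c, reduction)
        self.fc1 = Linear(c, hidden, rng=rng)  # shared MLP
        self.fc2 = Linear(hidden, c, rng=rng)
        if spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel must be odd")
        self.spatial = Conv2d(2, 1, spatial_kernel,
                              padding=spatial_kernel // 2, rng=rng)

    def channel_gate(self, x: Tensor) -> Tensor:
        avg = ag.mean(x, axis=(2, 3))
        mx = ag.max_(ag.reshape(x, (x.shape[0], x.shape[1], -1)), axis=2)
        mlp = lambda v: self.fc2(ag.relu(self.fc1(v)))
        return ag.sigmoid(ag.add(mlp(avg), mlp(mx)))  # (N, C)

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = ag.mean(x, axis=1, keepdims=True)
        mx = ag.max_(x, axis=1, keepdims=True)
        return ag.sigmoid(self.spatial(ag.concat([avg, mx], axis=1)))  # (N,1,H,W)

    def forward(self, x):
        x = as_tensor(x)
        mc = self.channel_gate(x)
        xp = ag.mul(x, ag.reshape(mc, (x.shape[0], x.shape[1], 1, 1)))
        ms = self.spatial_gate(xp)
        return ag.mul(xp, ms)


def make_attention(c: int, config: AttentionConfig, rng=None) -> Module:
    if config.kind == "SE":
        return SEAttention(c, config.reduction, rng=rng)
    if config.kind == "GCA":
        return GCAAttention(c, config.reduction, rng=rng)
    if config.kind == "CBAM":
        return CBAM(c, config.reduction, config.spatial_kernel, rng=rng)
    raise ValueError(f"unknown attention kind {config.kind!r}")


def se_attention(x: np.ndarray, module: SEAttention) -> np.ndarray:
    """SE gate on a (C, H, W) array."""
    return _run_chw(module, x)


def gca_attention(x: np.ndarray, module: GCAAttention) -> np.ndarray:
    """GCA gate on a (C, H, W) array."""
    return _run_chw(module, x)


def cbam_attention(x: np.ndarray, module: CBAM) -> np.ndarray:
    """CBAM gate on a (C, H, W) array."""
    return _run_chw(module, x)


# -- residual backbone -----------------------------------------------------

class ResidualBlock(Module):
    """Bottleneck unit x_{l+1} = ReLU(F(x_l) + W_s x_l).

    The branch F is conv1×1–BN–ReLU–conv3×3–BN–ReLU–conv1×1–BN; the skip
    W_s is the identity when dimensions match and a strided 1×1 projection
    (plus BN) otherwise.
    """

    def __init__(self, c_in: int, c_mid: int, c_out: int, stride: int = 1,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c_mid)
        self.conv2 = Conv2d(c_mid, c_mid, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_mid)
        self.conv3 = Conv2d(c_mid, c_out, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(c_out)
        self.project = not (c_in == c_out and stride == 1)
        if self.project:
            self.skip_conv = Conv2d(c_in, c_out, 1, stride=stride, bias=False,
                                    rng=rng)
            self.skip_bn = BatchNorm2d(c_out)

    def branch(self, x: Tensor) -> Tensor:
        h = ag.relu(self.bn1(self.conv1(x)))
        h = ag.relu(self.bn2(self.conv2(h)))
        return self.bn3(self.conv3(h))

    def forward(self, x):
        x = as_tensor(x)
        skip = self.skip_bn(self.skip_conv(x)) if self.project else x
        return ag.relu(ag.add(self.branch(x), skip))


def residual_block(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Apply a residual block to a single (C, H, W) array."""
    return _run_chw(block, x)


#: ResNet101 stage layout; the desk-scale default keeps the math but not
#: the depth.
RESNET101_LAYOUT = (3, 4, 23, 3)
TINY_LAYOUT = (1, 1, 2, 1)


class Backbone(Module):
    """Four-stage bottleneck backbone emitting C2–C5 (strides 4/8/16/32).

    When ``attention`` is configured, the chosen gate is appended after
    every residual unit in stages 3 and 4 only.
    """

    def __init__(
        self,
        layout: Sequence[int] = TINY_LAYOUT,
        widths: Sequence[int] = (32, 64, 128, 256),
        attention: AttentionConfig | None = None,
        in_channels: int = 3,
        seed: int = 0,
    ):
        super().__init__()
        if len(layout) != 4 or len(widths) != 4:
            raise ValueError("backbone needs exactly 4 stages")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        stem_c = max(widths[0] // 2, 8)
        self.stem_conv = Conv2d(in_channels, stem_c, 3, stride=2, padding=1,
                                bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(stem_c)
        self.stages: list[list[Module]] = []
        self.attn: list[list[Module]] = []
        c_in = stem_c
        for s, (n_blocks, c_out) in enumerate(zip(layout, widths)):
            c_mid = max(c_out // 4, 4)
            blocks: list[Module] = []
            attns: list[Module] = []
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(ResidualBlock(c_in, c_mid, c_out, stride, rng=rng))
                c_in = c_out
                if attention is not None and s >= 2:
                    attns.append(make_attention(c_out, attention, rng=rng))
            self.stages.append(blocks)
            self.attn.append(attns)

    def forward(self, x) -> dict[str, Tensor]:
        x = as_tensor(x)
        h = ag.relu(self.stem_bn(self.stem_conv(x)))
        h = ag.max_pool2d(h, 2)  # stride 4 total entering stage 1
        out: dict[str, Tensor] = {}
        for s, blocks in enumerate(self.stages):
            for b, block in enumerate(blocks):
                h = block(h)
                if self.attn[s]:
                    h = self.attn[s][b](h)
            out[f"C{s + 2}"] = h
        return out

    def attention_module_count(self) -> list[int]:
        return [len(a) for a in self.attn]


def build_backbone(
    layout: Sequence[int] = TINY_LAYOUT,
    attention: AttentionConfig | None = None,
    widths: Sequence[int] = (32, 64, 128, 256),
    seed: int = 0,
) -> Backbone:
    """Construct a backbone; ``attention=None`` gives the plain residual net."""
    return Backbone(layout=layout, widths=widths, attention=attention, seed=seed)
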
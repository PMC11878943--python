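"""Content-aware upsampling (CARAFE) and the balanced feature pyramid.

CARAFE replaces fixed interpolation in the top-down pathway: a small
encoder predicts, for every output location, a softmax-normalised kernel
over the k_up × k_up source neighbourhood, and the output value is the
corresponding convex reassembly

    y[i, j] = Σ_{m,n}  α[i, j, m, n] · x[m, n],   Σ α = 1 per location.

The balanced pyramid then rescales the fused levels P2'–P5' to a common
reference resolution (P4 by convention), averages them (Integrate),
applies a refinement transform (Refine), and scatters the refined map
back to every level as a residual, yielding the balanced P2–P5; P6 passes
through unchanged for the proposal network.

Border handling: reassembly neighbourhoods use edge replication by
default, so the convex kernels make constants exact fixed points of the
upsampler; zero padding is available for parity with implementations that
pad with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ag
from .autodiff import Conv2d, Module, Tensor, as_tensor

LEVELS_IN = ("C2", "C3", "C4", "C5")
LEVELS_OUT = ("P2", "P3", "P4", "P5", "P6")


@dataclass(frozen=True)
class CarafeParams:
    k_up: int = 5
    k_enc: int = 3
    c_mid: int = 64
    sigma_up: int = 2
    pad_mode: str = "edge"  # "edge" | "zero"

    def __post_init__(self):
        if self.k_up % 2 != 1:
            raise ValueError("k_up must be odd")
        if self.sigma_up < 1:
            raise ValueError("sigma_up must be >= 1")
        if self.pad_mode not in ("edge", "zero"):
            raise ValueError(f"unknown pad_mode {self.pad_mode!r}")


def carafe_reassemble(x, alpha, k_up: int, sigma: int,
                      pad_mode: str = "edge") -> Tensor:
    """Reassemble ``x`` (N,C,H,W) with kernels ``alpha`` (N,k²,σH,σW).

    Output location (i, j) draws from the k_up×k_up neighbourhood of
    source location (⌊i/σ⌋, ⌊j/σ⌋), weighted by its kernel.
    """
    x, alpha = as_tensor(x), as_tensor(alpha)
    N, C, H, W = x.shape
    if alpha.shape[1] != k_up * k_up:
        raise ValueError("alpha second axis must be k_up^2")
    patches = ag.unfold_neighborhoods(x, k_up, pad_mode)  # (N,C,k²,H,W)
    flat = ag.reshape(patches, (N, C * k_up * k_up, H, W))
    up = ag.nearest_resize(flat, (sigma * H, sigma * W))
    up = ag.reshape(up, (N, C, k_up * k_up, sigma * H, sigma * W))
    a = ag.reshape(alpha, (N, 1, k_up * k_up, sigma * H, sigma * W))
    return ag.sum_(ag.mul(up, a), axis=2)


class CarafeUpsample(Module):
    """Learned CARAFE operator: channel compressor + kernel encoder."""

    def __init__(self, c_in: int, params: CarafeParams = CarafeParams(),
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = params
        k2 = params.k_up ** 2
        self.compressor = Conv2d(c_in, params.c_mid, 1, rng=rng)
        self.encoder = Conv2d(
            params.c_mid, params.sigma_up ** 2 * k2, params.k_enc,
            padding=params.k_enc // 2, rng=rng,
        )

    def predict_kernels(self, x: Tensor) -> Tensor:
        """Softmax-normalised kernels, shape (N, k_up², σH, σW)."""
        p = self.params
        N, _, H, W = x.shape
        enc = self.encoder(self.compressor(x))  # (N, σ²k², H, W)
        k2 = p.k_up ** 2
        s = p.sigma_up
        enc = ag.reshape(enc, (N, k2, s, s, H, W))
        enc = ag.transpose(enc, (0, 1, 4, 2, 5, 3))  # (N,k²,H,σ,W,σ)
        enc = ag.reshape(enc, (N, k2, s * H, s * W))
        return ag.softmax(enc, axis=1)

    def forward(self, x):
        x = as_tensor(x)
        alpha = self.predict_kernels(x)
        return carafe_reassemble(x, alpha, self.params.k_up,
                                 self.params.sigma_up, self.params.pad_mode)


def carafe_upsample(x: np.ndarray, module: CarafeUpsample) -> np.ndarray:
    """Apply a CARAFE module to a single (C, H, W) array."""
    from .nn_blocks import _run_chw

    return _run_chw(module, x)


def uniform_kernels(n: int, k_up: int, out_hw: tuple[int, int]) -> np.ndarray:
    """Forced uniform reassembly kernels (each tap weighs 1/k_up²)."""
    k2 = k_up * k_up
    return np.full((n, k2, *out_hw), 1.0 / k2)


def delta_kernels(n: int, k_up: int, out_hw: tuple[int, int]) -> np.ndarray:
    """Forced one-hot center kernels: CARAFE degenerates to nearest-neighbour."""
    k2 = k_up * k_up
    a = np.zeros((n, k2, *out_hw))
    a[:, k2 // 2] = 1.0
    return a


class FPNTopDown(Module):
    """Lateral 1×1 projections plus top-down accumulation: C2–C5 → P2'–P6'.

    The coarser level is upsampled (nearest or CARAFE) to the finer
    level's exact dims and added; P6' is a stride-2 subsampling of P5'.
    """

    def __init__(self, in_channels: Sequence[int], out_channels: int = 64,
                 upsampler: str = "nearest",
                 carafe_params: CarafeParams = CarafeParams(), seed: int = 0):
        super().__init__()
        if len(in_channels) != 4:
            raise ValueError("expected 4 input levels (C2..C5)")
        if upsampler not in ("nearest", "carafe"):
            raise ValueError(f"unknown upsampler {upsampler!r}")
        rng = np.random.default_rng(seed)
        self.upsampler = upsampler
        self.out_channels = out_channels
        self.laterals = [Conv2d(c, out_channels, 1, rng=rng) for c in in_channels]
        if upsampler == "carafe":
            self.carafes = [
                CarafeUpsample(out_channels, carafe_params, rng=rng)
                for _ in range(3)
            ]

    def _upsample(self, x: Tensor, target_hw: tuple[int, int], idx: int) -> Tensor:
        if self.upsampler == "carafe":
            up = self.carafes[idx](x)
            return up[:, :, : target_hw[0], : target_hw[1]]
        return ag.nearest_resize(x, target_hw)

    def forward(self, maps: dict[str, Tensor]) -> dict[str, Tensor]:
        c = [as_tensor(maps[k]) for k in LEVELS_IN]
        laterals = [lat(x) for lat, x in zip(self.laterals, c)]
        pyr = [None] * 4
        pyr[3] = laterals[3]
        for i in (2, 1, 0):
            target = (laterals[i].shape[2], laterals[i].shape[3])
            pyr[i] = ag.add(laterals[i], self._upsample(pyr[i + 1], target, i))
        p6 = ag.subsample2(pyr[3])
        return {"P2": pyr[0], "P3": pyr[1], "P4": pyr[2], "P5": pyr[3], "P6": p6}


def fpn_topdown(maps: dict[str, np.ndarray], module: FPNTopDown) -> dict[str, np.ndarray]:
    """Run the top-down pathway on (C, H, W) arrays; returns P2'..P6'."""
    with ag.no_grad():
        module.eval()
        out = module({k: Tensor(np.asarray(v)[None]) for k, v in maps.items()})
    return {k: v.numpy()[0] for k, v in out.items()}


def resize_to(x: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Deterministic resize: adaptive average pooling down, nearest up."""
    H, W = x.shape[-2], x.shape[-1]
    th, tw = target_hw
    if (H, W) == (th, tw):
        return x
    if H >= th and W >= tw:
        return ag.adaptive_avg_pool(x, target_hw)
    return ag.nearest_resize(x, target_hw)


def bfp_integrate(levels: Sequence[Tensor], reference: int = 2) -> Tensor:
    """Average all levels at the reference level's resolution."""
    if len(levels) < 2:
        raise ValueError("integrate needs at least two levels")
    levels = [as_tensor(l) for l in levels]
    ref_hw = (levels[reference].shape[-2], levels[reference].shape[-1])
    acc = None
    for l in levels:
        r = resize_to(l, ref_hw)
        acc = r if acc is None else ag.add(acc, r)
    return ag.mul(acc, 1.0 / len(levels))


class BFPRefine(Module):
    """Refinement transform on the integrated map.

    Default: a 3×3 convolution (identity-initialisable).  ``kind="nonlocal"``
    uses an embedded-Gaussian non-local block, x + W_z softmax(θᵀφ) g(x).
    """

    def __init__(self, channels: int, kind: str = "conv",
                 identity_init: bool = False, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.kind = kind
        if kind == "conv":
            self.conv = Conv2d(channels, channels, 3, padding=1, rng=rng)
            if identity_init:
                w = np.zeros_like(self.conv.weight.data)
                for c in range(channels):
                    w[c, c, 1, 1] = 1.0
                self.conv.weight.data = w
                self.conv.bias.data[:] = 0.0
        elif kind == "nonlocal":
            self.theta = Conv2d(channels, channels // 2 or 1, 1, rng=rng)
            self.phi = Conv2d(channels, channels // 2 or 1, 1, rng=rng)
            self.g = Conv2d(channels, channels // 2 or 1, 1, rng=rng)
            self.wz = Conv2d(channels // 2 or 1, channels, 1, rng=rng)
            if identity_init:
                self.wz.weight.data[:] = 0.0
                self.wz.bias.data[:] = 0.0
        else:
            raise ValueError(f"unknown refine kind {kind!r}")

    def forward(self, x):
        x = as_tensor(x)
        if self.kind == "conv":
            return self.conv(x)
        N, C, H, W = x.shape
        th = ag.reshape(self.theta(x), (N, -1, H * W))
        ph = ag.reshape(self.phi(x), (N, -1, H * W))
        gx = ag.reshape(self.g(x), (N, -1, H * W))
        attn = ag.softmax(ag.matmul(ag.transpose(th, (0, 2, 1)), ph), axis=-1)
        y = ag.matmul(gx, ag.transpose(attn, (0, 2, 1)))
        y = ag.reshape(y, (N, -1, H, W))
        return ag.add(x, self.wz(y))


def bfp_refine(x: np.ndarray, module: BFPRefine) -> np.ndarray:
    from .nn_blocks import _run_chw

    return _run_chw(module, x)


class CarafeBFP(Module):
    """Full neck: CARAFE top-down pathway, Integrate, Refine, scatter.

    The refined map is resized back to each of P2'–P5' and added
    residually; P6' passes through.  ``reference`` indexes the Integrate
    resolution among (P2', P3', P4', P5'); 2 selects P4.
    """

    def __init__(self, in_channels: Sequence[int], out_channels: int = 64,
                 upsampler: str = "carafe",
                 carafe_params: CarafeParams = CarafeParams(),
                 refine: str = "conv", reference: int = 2, seed: int = 0):
        super().__init__()
        self.topdown = FPNTopDown(in_channels, out_channels, upsampler,
                                  carafe_params, seed=seed)
        self.refiner = BFPRefine(out_channels, kind=refine, seed=seed + 1)
        self.reference = reference

    def forward(self, maps: dict[str, Tensor]) -> dict[str, Tensor]:
        prime = self.topdown(maps)
        levels = [prime[k] for k in ("P2", "P3", "P4", "P5")]
        integrated = bfp_integrate(levels, reference=self.reference)
        refined = self.refiner(integrated)
        out: dict[str, Tensor] = {}
        for k, l in zip(("P2", "P3", "P4", "P5"), levels):
            out[k] = ag.add(l, resize_to(refined, (l.shape[-2], l.shape[-1])))
        out["P6"] = prime["P6"]
        return out


def carafe_bfp(maps: dict[str, np.ndarray], module: CarafeBFP) -> dict[str, np.ndarray]:
    """Run the full neck on (C, H, W) arrays; returns P2..P6."""
    with ag.no_grad():
        module.eval()
        out = module({k: Tensor(np.asarray(v)[None]) for k, v in maps.items()})
    return {k: v.numpy()[0] for k, v in out.items()}
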
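"""Dual-branch feature encoding.

A semantic stream of dilated residual blocks (with a non-local interaction
block at the coarsest level) runs alongside a shallow local stream that
re-injects a Sobel gradient map at every level, so boundary evidence reaches
deep layers directly.  Per level the two streams are blended through a
sigmoid gate computed from their concatenation, giving a convex combination
``F = gamma * S + (1 - gamma) * L`` — the fused map is always elementwise
between the two streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    Parameter,
    Tensor,
    avg_pool2d,
    concat,
    softmax,
    upsample_bilinear,
)

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def sobel_gradient(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(gx^2 + gy^2) with 3x3 Sobel kernels and
    reflect padding.  Non-trainable input preprocessing."""
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    gx = ndimage.correlate(img, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


class ResidualBlock(Module):
    """conv-norm-ReLU-conv-norm plus identity shortcut, shared dilation.

    The second norm's scale is zero-initialized so a freshly built block is
    the (projected) identity, which keeps early training stable.
    """

    def __init__(self, in_ch, out_ch, rng, dilation=1, zero_init_final_norm=True):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, padding=dilation, dilation=dilation)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=dilation, dilation=dilation)
        self.bn2 = BatchNorm2d(out_ch)
        if zero_init_final_norm:
            self.bn2.gamma.data[...] = 0.0
        self.shortcut = (
            Conv2d(in_ch, out_ch, 1, rng, bias=False) if in_ch != out_ch else None
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        s = self.shortcut(x) if self.shortcut is not None else x
        return (h + s).relu()


class NonLocalBlock(Module):
    """Softmax dot-product attention over all spatial positions.

    ``phi`` is a learned 1x1 linear embedding to ``ch // 2`` channels; the
    attention rows are stochastic, so each output pixel is a convex
    combination of input feature vectors.  Quadratic in pixel count, hence
    the spatial cap; with ``prepool`` the map is 2x average-pooled first and
    the result upsampled back.
    """

    def __init__(self, ch: int, rng, max_side: int = 64, prepool: bool = True):
        super().__init__()
        self.phi = Conv2d(ch, max(ch // 2, 1), 1, rng, bias=False)
        self.max_side = max_side
        self.prepool = prepool

    def attention_weights(self, s: Tensor) -> Tensor:
        n, c, h, w = s.shape
        f = self.phi(s).reshape(n, -1, h * w).transpose(0, 2, 1)  # (N, P, C')
        logits = f @ f.transpose(0, 2, 1)
        return softmax(logits, axis=2)

    def forward(self, s: Tensor) -> Tensor:
        n, c, h, w = s.shape
        pooled = False
        x = s
        if max(h, w) > self.max_side:
            if not self.prepool:
                raise ValueError(
                    f"non-local grid {h}x{w} exceeds cap {self.max_side}; "
                    "enable pre-pooling or raise the cap"
                )
            x = avg_pool2d(x, 2)
            pooled = True
        nh, nw = x.shape[2], x.shape[3]
        attn = self.attention_weights(x)
        flat = x.reshape(n, c, nh * nw).transpose(0, 2, 1)  # (N, P, C)
        out = (attn @ flat).transpose(0, 2, 1).reshape(n, c, nh, nw)
        if pooled:
            out = upsample_bilinear(out, h, w)
        return out


class SemanticEncoder(Module):
    """Stem + one dilated residual block per level, 2x pooled between levels,
    non-local attention fused (residually) at the coarsest level."""

    def __init__(self, in_ch, channels, dilations, rng,
                 nonlocal_max_side=64, use_nonlocal=True):
        super().__init__()
        self.stem = Conv2d(in_ch, channels[0], 3, rng, padding=1)
        self.blocks = [
            ResidualBlock(channels[max(i - 1, 0)] if i else channels[0],
                          channels[i], rng, dilation=dilations[i])
            for i in range(len(channels))
        ]
        self.nonlocal_block = (
            NonLocalBlock(channels[-1], rng, max_side=nonlocal_max_side)
            if use_nonlocal
            else None
        )

    def forward(self, x: Tensor) -> list[Tensor]:
        h, w = x.shape[2], x.shape[3]
        n_levels = len(self.blocks)
        if h % 2 ** (n_levels - 1) or w % 2 ** (n_levels - 1):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{n_levels - 1}"
            )
        feats = []
        cur = self.stem(x)
        for i, block in enumerate(self.blocks):
            if i > 0:
                cur = avg_pool2d(cur, 2)
            cur = block(cur)
            feats.append(cur)
        if self.nonlocal_block is not None:
            feats[-1] = feats[-1] + self.nonlocal_block(feats[-1])
        return feats


def pool_gradient_to(grad: Tensor, level_hw: tuple[int, int]) -> Tensor:
    """Average-pool the full-resolution gradient map to a level's grid."""
    h, w = grad.shape[2], grad.shape[3]
    factor = h // level_hw[0]
    if factor * level_hw[0] != h or w // level_hw[1] != factor:
        raise ValueError("gradient map not an integer multiple of level size")
    return avg_pool2d(grad, factor) if factor > 1 else grad


class LocalLevel(Module):
    """Shallow hybrid-dilation block: 3x3 at dilation 1 then 3x3 at dilation
    2, each norm+ReLU, then a 1x1 projection to the semantic channel count."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        mid = max(out_ch // 2, 4)
        self.conv1 = Conv2d(in_ch, mid, 3, rng, padding=1, dilation=1)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, rng, padding=2, dilation=2)
        self.bn2 = BatchNorm2d(mid)
        self.project = Conv2d(mid, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        return self.project(h)


class LocalEncoder(Module):
    """Boundary-aware stream: at every level the (pooled) Sobel gradient map
    is concatenated to the incoming features before the shallow block."""

    def __init__(self, in_ch, channels, rng, use_gradient=True):
        super().__init__()
        self.use_gradient = use_gradient
        g = 1 if use_gradient else 0
        self.levels = [
            LocalLevel((in_ch if i == 0 else channels[i - 1]) + g, channels[i], rng)
            for i in range(len(channels))
        ]

    def forward(self, x: Tensor, grad: Tensor) -> list[Tensor]:
        feats = []
        cur = x
        for i, level in enumerate(self.levels):
            if i > 0:
                cur = avg_pool2d(cur, 2)
            if self.use_gradient:
                g = pool_gradient_to(grad, (cur.shape[2], cur.shape[3]))
                cur = concat([cur, g], axis=1)
            cur = level(cur)
            feats.append(cur)
        return feats


class GateFuse(Module):
    """gamma = sigmoid(1x1 conv on [S, L]); F = gamma*S + (1-gamma)*L."""

    def __init__(self, ch: int, rng):
        super().__init__()
        self.gate = Conv2d(2 * ch, ch, 1, rng)

    def forward(self, s: Tensor, l: Tensor) -> tuple[Tensor, Tensor]:
        if s.shape != l.shape:
            raise ValueError(f"gate_fuse shape mismatch: {s.shape} vs {l.shape}")
        gamma = self.gate(concat([s, l], axis=1)).sigmoid()
        fused = gamma * s + (1.0 - gamma) * l
        return gamma, fused


@dataclass
class FeaturePyramid:
    semantic: list[Tensor]
    local: list[Tensor] | None
    fused: list[Tensor]
    gates: list[Tensor] | None
    grad: Tensor | None


class DualBackbone(Module):
    """Semantic + local encoders with per-level gated fusion.

    Ablation switches: ``dual_branch=False`` drops the local stream entirely
    (fused = semantic); ``gated_fusion=False`` replaces the learned gate with
    a fixed 0.5/0.5 average.
    """

    def __init__(self, in_ch, channels, dilations, rng,
                 dual_branch=True, gated_fusion=True,
                 nonlocal_max_side=64, use_gradient=True):
        super().__init__()
        self.dual_branch = dual_branch
        self.gated_fusion = gated_fusion
        self.semantic = SemanticEncoder(
            in_ch, channels, dilations, rng, nonlocal_max_side=nonlocal_max_side
        )
        if dual_branch:
            self.local = LocalEncoder(in_ch, channels, rng, use_gradient=use_gradient)
            if gated_fusion:
                self.gates = [GateFuse(c, rng) for c in channels]

    def forward(self, x: Tensor, grad: Tensor | None = None) -> FeaturePyramid:
        s_feats = self.semantic(x)
        if not self.dual_branch:
            return FeaturePyramid(s_feats, None, list(s_feats), None, grad)
        if grad is None:
            raise ValueError("dual-branch backbone needs the gradient map")
        l_feats = self.local(x, grad)
        fused, gammas = [], []
        for i, (s, l) in enumerate(zip(s_feats, l_feats)):
            if self.gated_fusion:
                gamma, f = self.gates[i](s, l)
            else:
                gamma, f = None, 0.5 * s + 0.5 * l
            fused.append(f)
            gammas.append(gamma)
        return FeaturePyramid(s_feats, l_feats, fused,
                              gammas if self.gated_fusion else None, grad)
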
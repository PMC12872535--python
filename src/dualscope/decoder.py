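"""Deeply-supervised decoding.

The decoder walks the fused pyramid coarse-to-fine; every stage projects its
feature map through a 1x1 head to class logits (upsampled to full
resolution), and the per-level logits are combined with learnable simplex
weights beta — aggregation happens on pre-softmax logits so one consistent
score space feeds the downstream refinement.  The finest stage additionally
yields a pixel embedding map E(p) (driving the context-adaptive per-pixel
dilation selection) and the feature map the saliency estimator reads.

Argmax decoding breaks ties toward the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    Parameter,
    Tensor,
    concat,
    conv2d,
    softmax,
    upsample_bilinear,
)


def decode_mask(logits) -> np.ndarray:
    """Per-pixel argmax over the class axis (axis 1 for NCHW, axis 0 for
    CHW); ties go to the lowest class index."""
    data = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    axis = 1 if data.ndim == 4 else 0
    return np.argmax(data, axis=axis)


def class_prior(probs: Tensor) -> Tensor:
    """Mean softmax probability per class over the spatial domain, (N, C)."""
    return probs.mean(axis=(2, 3))


class SegHead(Module):
    """1x1 projection to class logits, bilinearly upsampled to full size."""

    def __init__(self, in_ch: int, n_classes: int, rng):
        super().__init__()
        self.proj = Conv2d(in_ch, n_classes, 1, rng)

    def forward(self, feat: Tensor, out_hw: tuple[int, int]) -> Tensor:
        z = self.proj(feat)
        if (z.shape[2], z.shape[3]) != out_hw:
            z = upsample_bilinear(z, *out_hw)
        return z


class HeadAggregator(Module):
    """U = sum_l beta_l Z_l with beta = softmax(scores), uniform init.

    The softmax parameterization keeps beta on the simplex structurally,
    after every optimizer step.
    """

    def __init__(self, n_heads: int):
        super().__init__()
        if n_heads < 1:
            raise ValueError("need at least one head")
        self.scores = Parameter(np.zeros(n_heads, np.float32))

    @property
    def beta(self) -> Tensor:
        e = (self.scores - float(self.scores.data.max())).exp()
        return e / e.sum()

    def forward(self, heads: list[Tensor]) -> Tensor:
        beta = self.beta
        out = beta[0] * heads[0]
        for i in range(1, len(heads)):
            out = out + beta[i] * heads[i]
        return out


class DilationSelector(Module):
    """Two-layer perceptron (1x1 convs) on the embedding map -> 3-way softmax
    over dilation rates {1, 2, 3}.  Soft weights in training; hard argmax
    (lowest index on ties) at inference."""

    def __init__(self, embed_dim: int, rng, hidden: int = 16):
        super().__init__()
        self.fc1 = Conv2d(embed_dim, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, 3, 1, rng)

    def forward(self, emb: Tensor) -> Tensor:
        return softmax(self.fc2(self.fc1(emb).relu()), axis=1)

    @staticmethod
    def hard_select(soft: Tensor | np.ndarray) -> np.ndarray:
        data = soft.data if isinstance(soft, Tensor) else np.asarray(soft)
        return np.argmax(data, axis=1) + 1  # rates are 1-based


class AdaptiveConv(Module):
    """One shared 3x3 weight tensor evaluated at dilations 1, 2, 3; per-pixel
    blend by the selector's soft weights (or a hard one-hot of them).

    Reflect padding keeps the three dilation banks identical on spatially
    constant inputs (borders included), so degenerate selection reduces
    exactly to an ordinary convolution.
    """

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        fan_in = in_ch * 9
        from .nn import he_normal
        from .nn.tensor import reflect_pad2d  # noqa: F401 (used in forward)

        self.weight = Parameter(he_normal(rng, (out_ch, in_ch, 3, 3), fan_in))
        self.bias = Parameter(np.zeros(out_ch, np.float32))

    def forward(self, feat: Tensor, weights: Tensor) -> Tensor:
        from .nn.tensor import reflect_pad2d

        if (feat.shape[2], feat.shape[3]) != (weights.shape[2], weights.shape[3]):
            raise ValueError("dilation weights not aligned with features")
        out = None
        for i, d in enumerate((1, 2, 3)):
            resp = conv2d(reflect_pad2d(feat, d), self.weight, self.bias,
                          dilation=d)
            term = weights[:, i : i + 1] * resp
            out = term if out is None else out + term
        return out

    @staticmethod
    def harden(soft: Tensor) -> Tensor:
        """One-hot of the argmax (lowest index on ties), as a constant."""
        data = soft.data
        hard = np.zeros_like(data)
        idx = np.argmax(data, axis=1)
        n, _, h, w = data.shape
        ni, hi, wi = np.ogrid[:n, :h, :w]
        hard[ni, idx, hi, wi] = 1.0
        return Tensor(hard)


class DecoderStage(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


@dataclass
class LogitBundle:
    head_logits: list[Tensor]  # finest first, full resolution
    beta: Tensor  # (L,) simplex
    logits: Tensor  # aggregated U^(1), (N, C, H, W)
    probs: Tensor  # softmax of the aggregate
    alpha: Tensor  # (N, C) class prior
    embedding: Tensor  # (N, D, H, W)
    dilation_soft: Tensor  # (N, 3, H, W)
    features: Tensor  # finest decoder features (saliency input)


class Decoder(Module):
    """Coarse-to-fine path over the fused pyramid with deep supervision."""

    def __init__(self, channels, n_classes, rng, embed_dim=16,
                 adaptive_head=True, hard_dilation_at_eval=True):
        super().__init__()
        self.n_classes = n_classes
        self.adaptive_head = adaptive_head
        self.hard_dilation_at_eval = hard_dilation_at_eval
        rev = list(reversed(channels))  # coarsest first
        self.stages = [
            DecoderStage(rev[i - 1] + rev[i], rev[i], rng)
            for i in range(1, len(rev))
        ]
        self.heads = [SegHead(c, n_classes, rng) for c in rev]  # coarsest first
        self.aggregator = HeadAggregator(len(rev))
        self.embed_head = Conv2d(channels[0], embed_dim, 1, rng)
        self.selector = DilationSelector(embed_dim, rng)
        if adaptive_head:
            self.adaptive = AdaptiveConv(channels[0], channels[0], rng)
            self.adaptive_bn = BatchNorm2d(channels[0])

    def forward(self, fused: list[Tensor], out_hw: tuple[int, int]) -> LogitBundle:
        rev = list(reversed(fused))  # coarsest first
        cur = rev[0]
        feats = [cur]
        for i, stage in enumerate(self.stages):
            skip = rev[i + 1]
            up = upsample_bilinear(cur, skip.shape[2], skip.shape[3])
            cur = stage(concat([up, skip], axis=1))
            feats.append(cur)

        emb = self.embed_head(cur)
        dil = self.selector(emb)
        if self.adaptive_head:
            if not self.training and self.hard_dilation_at_eval:
                dil_used = AdaptiveConv.harden(dil)
            else:
                dil_used = dil
            cur = self.adaptive_bn(self.adaptive(cur, dil_used)).relu()
            feats[-1] = cur

        head_logits_coarse_first = [
            head(f, out_hw) for head, f in zip(self.heads, feats)
        ]
        logits = self.aggregator(head_logits_coarse_first)
        probs = softmax(logits, axis=1)
        return LogitBundle(
            head_logits=list(reversed(head_logits_coarse_first)),
            beta=self.aggregator.beta,
            logits=logits,
            probs=probs,
            alpha=class_prior(probs),
            embedding=emb,
            dilation_soft=dil,
            features=cur,
        )
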
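"""Contextual Synergy Inference: differentiable post-decoder refinement.

The chain, applied to aggregated logits U and pixel embeddings E:

1. affinity propagation — each (reduced-grid) pixel's logits are replaced by
   a softmax-weighted average over all pixels, weighted by embedding
   similarity ``softmax_q(-||E(p)-E(q)||^2 / tau^2)``;
2. saliency recalibration — a learned saliency map M in (0,1) scales logits
   by ``1 + lambda * M`` (channel-independent, so the per-pixel class
   ranking is never reordered);
3. prior normalization — global class priors alpha_c (mean softmax mass)
   emphasize prevalent classes: ``N_c = (1 + lambda_prior * alpha_c) * U_c``;
4. relational graph propagation — a C x C co-activation graph w
   redistributes logits across classes: ``R_c = sum_j w[c, j] N_j``;
5. boundary sharpening — unsharp masking with a 3x3 box blur (a declared
   stand-in for an otherwise unspecified boundary-enhanced term);
6. three-way fusion — ``theta_1 R + theta_2 N + theta_3 sharp`` with theta
   on the simplex by softmax parameterization, then argmax decoding.

For efficiency the affinity step runs on an average-pooled grid (default
stride 4) and the refined logits are upsampled bilinearly, mirroring the
reduced-resolution strategy the design calls for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import decode_mask
from .nn import (
    Conv2d,
    Dropout2d,
    Module,
    Parameter,
    Tensor,
    avg_pool2d,
    conv2d,
    softmax,
    upsample_bilinear,
)


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def _pairwise_logits(ef: Tensor, tau: float) -> Tensor:
    """Fused -||e_i - e_j||^2 / tau^2 over a (N, P, D) embedding tensor.

    Distances are clamped at zero against floating-point negatives; the
    clamp is ignored in the backward pass (it only ever binds where the
    distance, and hence the gradient, is numerically zero).
    """
    e = ef.data
    sq = (e * e).sum(axis=2, keepdims=True)
    d2 = np.maximum(sq + np.swapaxes(sq, 1, 2) - 2.0 * (e @ np.swapaxes(e, 1, 2)),
                    0.0)
    scale = -1.0 / (tau * tau)
    out = Tensor((d2 * scale).astype(e.dtype), _parents=(ef,))

    def bw(g):
        sym = g + np.swapaxes(g, 1, 2)
        rowsum = sym.sum(axis=2, keepdims=True)
        ef._accum((2.0 * scale) * (e * rowsum - sym @ e))

    out._backward = bw
    return out


def affinity_propagate(
    u: Tensor | np.ndarray,
    e: Tensor | np.ndarray,
    tau: float,
    stride: int = 1,
    max_pixels: int = 4096,
    detail_preserving: bool = True,
) -> tuple[Tensor, Tensor]:
    """Embedding-similarity weighted logit averaging.

    Returns ``(refined logits at full resolution, attention weights)``; the
    attention rows are stochastic, so refined per-channel values stay within
    the input extrema of the reduced grid.

    With ``stride > 1`` the propagation runs on an average-pooled grid.  In
    the default detail-preserving mode the bilinearly upsampled *correction*
    ``up(A U_red - U_red)`` is added to the full-resolution logits, so
    structures smaller than the stride survive refinement; with
    ``detail_preserving=False`` the refined coarse logits are upsampled
    directly.  At stride 1 both modes coincide with the plain propagation.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not isinstance(u, Tensor):
        u = Tensor(u)
    if not isinstance(e, Tensor):
        e = Tensor(e)
    n, c, h, w = u.shape
    if (e.shape[0], e.shape[2], e.shape[3]) != (n, h, w):
        raise ValueError("logits and embeddings not spatially aligned")
    ud = avg_pool2d(u, stride) if stride > 1 else u
    ed = avg_pool2d(e, stride) if stride > 1 else e
    hh, ww = ud.shape[2], ud.shape[3]
    p = hh * ww
    if p > max_pixels:
        raise ValueError(
            f"reduced grid {hh}x{ww} has {p} pixels > cap {max_pixels}; "
            "use a larger stride"
        )
    uf = ud.reshape(n, c, p).transpose(0, 2, 1)  # (N, P, C)
    ef = ed.reshape(n, ed.shape[1], p).transpose(0, 2, 1)  # (N, P, D)
    attn = softmax(_pairwise_logits(ef, tau), axis=2)
    out = (attn @ uf).transpose(0, 2, 1).reshape(n, c, hh, ww)
    if stride > 1:
        if detail_preserving:
            out = u + upsample_bilinear(out - ud, h, w)
        else:
            out = upsample_bilinear(out, h, w)
    return out, attn


def saliency_recalibrate(u_tilde: Tensor, m: Tensor, lam: float) -> Tensor:
    """``U_sal = (1 + lambda * M) * U_tilde``; the scale is positive and
    channel-independent, so argmax per pixel is preserved."""
    if lam < 0:
        raise ValueError("calibration coefficient lambda must be >= 0")
    if lam == 0.0:
        return u_tilde
    return (1.0 + lam * m) * u_tilde


def prior_normalize(u_sal: Tensor, alpha: Tensor, lam_prior: float) -> Tensor:
    """Multiplicative class-prior emphasis ``N_c = (1 + lp * alpha_c) U_c``."""
    if lam_prior < 0:
        raise ValueError("lambda_prior must be >= 0")
    if lam_prior == 0.0:
        return u_sal
    n, c = alpha.shape
    return (1.0 + lam_prior * alpha).reshape(n, c, 1, 1) * u_sal


def build_class_graph(u_sal: Tensor | np.ndarray) -> Tensor:
    """Class co-activation graph w_{ij} = mean_p s_i(p) s_j(p), (N, C, C).

    Symmetric, entries >= 0, total mass sum_{ij} w = 1 exactly (each pixel's
    softmax sums to one)."""
    if not isinstance(u_sal, Tensor):
        u_sal = Tensor(u_sal)
    n, c, h, w = u_sal.shape
    s = softmax(u_sal, axis=1).reshape(n, c, h * w)
    return (s @ s.transpose(0, 2, 1)) / float(h * w)


def sparsify_graph(w, keep_k: int):
    """Keep each row's diagonal plus its ``keep_k`` largest off-diagonal
    entries, then re-symmetrize.  For the symmetric graphs produced by
    :func:`build_class_graph` re-symmetrization reduces to OR-ing the row
    mask with its transpose, which is how the differentiable (Tensor) path
    implements it.  ``keep_k >= C - 1`` is the identity."""
    if keep_k < 1:
        raise ValueError("keep_k must be >= 1")
    data = w.data if isinstance(w, Tensor) else np.asarray(w)
    c = data.shape[-1]
    if keep_k >= c - 1:
        return w
    batched = data.ndim == 3
    mats = data if batched else data[None]
    masks = np.zeros_like(mats, dtype=bool)
    eye = np.eye(c, dtype=bool)
    for b in range(mats.shape[0]):
        off = np.where(eye, -np.inf, mats[b])
        top = np.argsort(-off, axis=1)[:, :keep_k]
        rows = np.repeat(np.arange(c), keep_k)
        mask = np.zeros((c, c), dtype=bool)
        mask[rows, top.ravel()] = True
        masks[b] = mask | mask.T | eye
    masks = masks if batched else masks[0]
    if isinstance(w, Tensor):
        return w * masks.astype(w.dtype)
    return np.where(masks, data, 0.0)


def graph_propagate(n_logits: Tensor, w) -> Tensor:
    """R(p)_c = sum_j w[c, j] N(p)_j — one linear map over channels applied
    at every pixel.  ``w`` may be (C, C) shared or (N, C, C) per image."""
    if not isinstance(w, Tensor):
        w = Tensor(np.asarray(w))
    n, c, h, wid = n_logits.shape
    if w.shape[-1] != c or w.shape[-2] != c:
        raise ValueError(f"graph is {w.shape}, expected trailing ({c}, {c})")
    flat = n_logits.reshape(n, c, h * wid)
    return (w @ flat).reshape(n, c, h, wid)


def _reflect_pad1(x: Tensor) -> Tensor:
    h, w = x.shape[2], x.shape[3]
    ridx = np.concatenate([[1], np.arange(h), [h - 2]])
    cidx = np.concatenate([[1], np.arange(w), [w - 2]])
    return x[:, :, ridx][:, :, :, cidx]


def box_blur3(x: Tensor) -> Tensor:
    """3x3 box blur with reflect padding (constant maps are fixed points)."""
    n, c, h, w = x.shape
    xp = _reflect_pad1(x).reshape(n * c, 1, h + 2, w + 2)
    kernel = Tensor(np.full((1, 1, 3, 3), 1.0 / 9.0, dtype=x.dtype))
    return conv2d(xp, kernel).reshape(n, c, h, w)


def sharpen_logits(u_sal: Tensor, eta: float) -> Tensor:
    """Unsharp masking per channel: ``U + eta * (U - blur3x3(U))``."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta == 0.0:
        return u_sal
    return u_sal + eta * (u_sal - box_blur3(u_sal))


def csi_fuse(r: Tensor, n_logits: Tensor, sharp: Tensor, theta) -> tuple[Tensor, np.ndarray]:
    """theta_1 R + theta_2 N + theta_3 sharp, then argmax decoding."""
    if not isinstance(theta, Tensor):
        theta = Tensor(np.asarray(theta, dtype=r.dtype))
    fused = theta[0] * r + theta[1] * n_logits + theta[2] * sharp
    return fused, decode_mask(fused)


# ---------------------------------------------------------------------------
# module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsiConfig:
    tau: float = 1.0
    lam: float = 0.5
    lam_prior: float = 0.5
    eta: float = 1.0
    stride: int = 4
    keep_k: int | None = None  # default min(C - 1, 4)
    max_pixels: int = 4096
    affinity: bool = True
    saliency: bool = True
    graph: bool = True
    ema_decay: float | None = None  # None: per-image graph
    dropout: float = 0.2

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.lam, self.lam_prior, self.eta) < 0:
            raise ValueError("lam, lam_prior and eta must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


class SaliencyBlock(Module):
    """Two 3x3 convolutions + sigmoid; learned jointly, no pretrained model."""

    def __init__(self, in_ch: int, rng):
        super().__init__()
        mid = max(in_ch // 2, 4)
        self.conv1 = Conv2d(in_ch, mid, 3, rng, padding=1)
        self.conv2 = Conv2d(mid, 1, 3, rng, padding=1)

    def forward(self, feat: Tensor) -> Tensor:
        return self.conv2(self.conv1(feat).relu()).sigmoid()


@dataclass
class CsiState:
    u_tilde: Tensor
    attention: Tensor | None
    saliency: Tensor | None
    u_sal: Tensor
    alpha: Tensor
    n_logits: Tensor
    graph: Tensor | None
    graph_sparse: Tensor | None
    r_logits: Tensor
    sharp: Tensor
    theta: Tensor
    fused: Tensor
    mask: np.ndarray


class CsiModule(Module):
    """The full refinement chain with per-component ablation switches."""

    def __init__(self, feat_ch: int, n_classes: int, cfg: CsiConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.n_classes = n_classes
        self.theta_scores = Parameter(np.zeros(3, np.float32))
        self.saliency_net = SaliencyBlock(feat_ch, rng) if cfg.saliency else None
        self.drop = Dropout2d(cfg.dropout)
        # dataset-wide co-occurrence statistics, exponentially accumulated
        self.running_graph = np.eye(n_classes, dtype=np.float32) / n_classes

    @property
    def theta(self) -> Tensor:
        e = (self.theta_scores - float(self.theta_scores.data.max())).exp()
        return e / e.sum()

    def set_theta(self, values) -> None:
        """Pin the fusion weights (log-parameterized; zeros are floored)."""
        v = np.asarray(values, dtype=np.float64)
        self.theta_scores.data[...] = np.log(np.maximum(v, 1e-12))

    def forward(self, u1: Tensor, emb: Tensor, feat: Tensor, alpha: Tensor) -> CsiState:
        cfg = self.cfg
        if cfg.affinity:
            u_tilde, attn = affinity_propagate(
                u1, emb, cfg.tau, stride=cfg.stride, max_pixels=cfg.max_pixels
            )
        else:
            u_tilde, attn = u1, None

        if cfg.saliency and self.saliency_net is not None:
            m = self.saliency_net(self.drop(feat))
            u_sal = saliency_recalibrate(u_tilde, m, cfg.lam)
        else:
            m, u_sal = None, u_tilde

        n_logits = prior_normalize(u_sal, alpha, cfg.lam_prior)

        if cfg.graph:
            w = build_class_graph(u_sal)
            keep_k = cfg.keep_k if cfg.keep_k is not None else min(self.n_classes - 1, 4)
            if cfg.ema_decay is not None:
                if self.training:
                    batch = w.data.mean(axis=0)
                    d = cfg.ema_decay
                    self.running_graph[...] = d * self.running_graph + (1 - d) * batch
                w_used = Tensor(self.running_graph.copy())
            else:
                w_used = w
            w_sparse = sparsify_graph(w_used, keep_k)
            r = graph_propagate(n_logits, w_sparse)
        else:
            w, w_sparse, r = None, None, n_logits

        sharp = sharpen_logits(u_sal, cfg.eta)
        fused, mask = csi_fuse(r, n_logits, sharp, self.theta)
        return CsiState(
            u_tilde=u_tilde,
            attention=attn,
            saliency=m,
            u_sal=u_sal,
            alpha=alpha,
            n_logits=n_logits,
            graph=w,
            graph_sparse=w_sparse,
            r_logits=r,
            sharp=sharp,
            theta=self.theta,
            fused=fused,
            mask=mask,
        )
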
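"""Full segmentation network: dual backbone -> deeply-supervised decoder ->
contextual synergy refinement, with every component behind a switch."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .backbone import DualBackbone, FeaturePyramid, sobel_gradient
from .csi import CsiConfig, CsiModule, CsiState
from .decoder import Decoder, LogitBundle, decode_mask
from .nn import Module, Tensor


@dataclass(frozen=True)
class ArchConfig:
    in_channels: int = 1
    n_classes: int = 3
    channels: tuple[int, ...] = (16, 32, 64, 128)
    dilations: tuple[int, ...] = (1, 1, 2, 2)
    embed_dim: int = 16
    nonlocal_max_side: int = 64
    dual_branch: bool = True
    gated_fusion: bool = True
    use_gradient_channel: bool = True
    backbone_dropout: float = 0.1
    csi: CsiConfig = field(default_factory=CsiConfig)
    use_csi: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != len(self.dilations):
            raise ValueError("channels and dilations must have equal length")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def desk_scale(n_classes: int = 3, seed: int = 0, **overrides) -> "ArchConfig":
        """Compact profile for CPU-scale experiments on 64x64 phantoms."""
        base = ArchConfig(
            n_classes=n_classes,
            channels=(8, 16, 32),
            dilations=(1, 2, 2),
            embed_dim=8,
            # finer refinement grid: at 64x64, structures close to the
            # default stride are erased by pooled propagation
            csi=CsiConfig(tau=0.5, stride=2),
            seed=seed,
        )
        return replace(base, **overrides) if overrides else base


@dataclass
class ModelOutput:
    pyramid: FeaturePyramid
    bundle: LogitBundle
    csi: CsiState | None
    final_logits: Tensor
    mask: np.ndarray


class DualScopeNet(Module):
    def __init__(self, cfg: ArchConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = DualBackbone(
            cfg.in_channels,
            cfg.channels,
            cfg.dilations,
            rng,
            dual_branch=cfg.dual_branch,
            gated_fusion=cfg.gated_fusion,
            nonlocal_max_side=cfg.nonlocal_max_side,
            use_gradient=cfg.use_gradient_channel,
        )
        self.decoder = Decoder(
            cfg.channels, cfg.n_classes, rng, embed_dim=cfg.embed_dim
        )
        self.csi_module = (
            CsiModule(cfg.channels[0], cfg.n_classes, cfg.csi, rng)
            if cfg.use_csi
            else None
        )
        from .nn import Dropout2d

        self.backbone_drop = Dropout2d(cfg.backbone_dropout)

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        self.backbone_drop.rng = rng
        if self.csi_module is not None:
            self.csi_module.drop.rng = rng

    def forward(self, images: np.ndarray) -> ModelOutput:
        """``images``: (N, H, W) or (N, 1, H, W) float array in [0, 1]."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        grad = None
        if self.cfg.dual_branch:
            grad = np.stack([sobel_gradient(im[0]) for im in x])[:, None]
            grad = Tensor(grad.astype(np.float32))
        pyramid = self.backbone(Tensor(x), grad)
        fused = [self.backbone_drop(f) for f in pyramid.fused]
        bundle = self.decoder(fused, (x.shape[2], x.shape[3]))
        if self.csi_module is not None:
            state = self.csi_module(
                bundle.logits, bundle.embedding, bundle.features, bundle.alpha
            )
            final = state.fused
        else:
            state, final = None, bundle.logits
        return ModelOutput(
            pyramid=pyramid,
            bundle=bundle,
            csi=state,
            final_logits=final,
            mask=decode_mask(final),
        )

    def predict_mask(self, images: np.ndarray, use_csi: bool = True) -> np.ndarray:
        """Inference helper: argmax mask, optionally skipping refinement."""
        self.eval()
        self.set_dropout_rng(None)
        out = self.forward(images)
        if use_csi or out.csi is None:
            return out.mask
        return decode_mask(out.bundle.logits)
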
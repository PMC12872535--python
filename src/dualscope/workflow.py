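"""Training, prediction and ablation orchestration.

Runs are pure functions of their configuration and seeds: data generation,
parameter initialization, batch sampling, augmentation and dropout all draw
from separate named seeds, and deterministic mode replays bit-identically.
Every artifact (checkpoint, log, report) embeds the configuration hash and
the seeds that produced it.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .csi import CsiConfig
from .decoder import decode_mask
from .metrics import aggregate_reports, evaluate_pair
from .model import ArchConfig, DualScopeNet, ModelOutput
from .nn import AdamW, Tensor, avg_pool2d, cosine_lr, softmax
from .objectives import (
    LossConfig,
    affinity_loss,
    embedding_discriminability,
    relational_consistency_loss,
    saliency_focal_loss,
    smoothed_cross_entropy,
    total_loss,
)
from .phantoms import ArtifactConfig, AugmentConfig, LabeledImage, apply_artifacts, augment


@dataclass(frozen=True)
class RunConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 1e-4
    label_smoothing: float = 0.1
    patience: int = 10  # early stop on validation foreground Dice
    eval_every: int = 1  # validate every N epochs
    class_balanced: bool = True
    tta: str = "none"  # none | five_crop
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    augment_enabled: bool = True
    # auxiliary terms ramp linearly from 0 over the first epochs: early
    # predicted labels are near-random and a full-strength pairwise pull
    # collapses the embedding space before segmentation structure exists
    aux_warmup_epochs: int = 2
    data_seed: int = 0
    model_seed: int = 0
    train_seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")
        if self.tta not in ("none", "five_crop"):
            raise ValueError("tta must be 'none' or 'five_crop'")

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def full_scale_protocol(**overrides) -> "RunConfig":
        """The full-scale regime (100 epochs, batch 64); a named profile
        for large images — not the desk-scale default."""
        base = dict(epochs=100, batch_size=64)
        base.update(overrides)
        return RunConfig(**base)


def check_disjoint_splits(*ident_lists: list[str]) -> None:
    """Hard error on any image shared between splits (leakage guard)."""
    seen: dict[str, int] = {}
    for k, idents in enumerate(ident_lists):
        for ident in idents:
            if ident in seen and seen[ident] != k:
                raise ValueError(f"split leakage: image {ident!r} appears in "
                                 f"splits {seen[ident]} and {k}")
            seen[ident] = k


def split_dataset(images: list[LabeledImage], fractions=(0.7, 0.1, 0.2),
                  seed: int = 0):
    """Shuffle and split image-level; returns (train, val, test)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    n_train = int(round(fractions[0] * len(images)))
    n_val = int(round(fractions[1] * len(images)))
    tr = [images[i] for i in order[:n_train]]
    va = [images[i] for i in order[n_train:n_train + n_val]]
    te = [images[i] for i in order[n_train + n_val:]]
    check_disjoint_splits([x.ident for x in tr], [x.ident for x in va],
                          [x.ident for x in te])
    return tr, va, te


def _sampling_weights(images: list[LabeledImage], n_classes: int) -> np.ndarray:
    """Inverse-frequency weights by the rarest class present per image."""
    presence = np.zeros((len(images), n_classes), dtype=bool)
    for i, im in enumerate(images):
        presence[i, np.unique(im.mask)] = True
    freq = presence.mean(axis=0)
    weights = np.ones(len(images))
    for i in range(len(images)):
        present = np.flatnonzero(presence[i])
        weights[i] = 1.0 / max(freq[present].min(), 1e-6)
    return weights / weights.sum()


def _downsample_labels(mask: np.ndarray, stride: int) -> np.ndarray:
    return mask[:, ::stride, ::stride] if stride > 1 else mask


def compute_losses(model: DualScopeNet, out: ModelOutput, masks: np.ndarray,
                   cfg: LossConfig, rng: np.random.Generator,
                   ramp: float = 1.0) -> tuple[Tensor, dict]:
    """Assemble every enabled loss term for one batch.

    ``ramp`` in [0, 1] scales the auxiliary term weights (warm-up); the
    supervised cross-entropy terms are never scaled.
    """
    if ramp < 1.0:
        cfg = replace(cfg,
                      w_affinity=cfg.w_affinity * ramp,
                      w_focal=cfg.w_focal * ramp,
                      w_relational=cfg.w_relational * ramp,
                      w_embedding=cfg.w_embedding * ramp)
    terms: dict[str, Tensor] = {}
    terms["final_ce"] = smoothed_cross_entropy(out.final_logits, masks,
                                               cfg.label_smoothing)
    if len(out.bundle.head_logits) > 1:
        ds_terms = [smoothed_cross_entropy(z, masks, cfg.label_smoothing)
                    for z in out.bundle.head_logits]
        ds_sum = ds_terms[0]
        for t in ds_terms[1:]:
            ds_sum = ds_sum + t
        terms["deep_supervision"] = ds_sum / float(len(ds_terms))

    state = out.csi
    stride = model.cfg.csi.stride if state is not None else 4
    emb_red = avg_pool2d(out.bundle.embedding, stride) if stride > 1 else out.bundle.embedding
    if cfg.use_predicted_labels:
        red_logits = avg_pool2d(out.final_logits, stride) if stride > 1 else out.final_logits
        pair_labels = decode_mask(red_logits).reshape(-1)
    else:
        pair_labels = _downsample_labels(masks, stride).reshape(-1)
    gt_red = _downsample_labels(masks, stride).reshape(-1)

    if state is not None and model.cfg.csi.affinity:
        terms["affinity"] = affinity_loss(emb_red, pair_labels, cfg.margin,
                                          cfg.lambda_a, cfg.pair_cap, rng)
    sal = state.saliency if state is not None and state.saliency is not None \
        else Tensor(np.ones((masks.shape[0], 1) + masks.shape[1:], np.float32))
    terms["focal"] = saliency_focal_loss(out.final_logits, sal, masks,
                                         cfg.gamma_focal)
    if state is not None and model.cfg.csi.graph:
        terms["relational"] = relational_consistency_loss(
            state.n_logits, state.r_logits, cfg.kl_eps
        )
    _, _, emb_loss = embedding_discriminability(emb_red, gt_red, cfg.margin_mu,
                                                cfg.pair_cap, rng)
    terms["embedding"] = emb_loss
    if (cfg.w_saliency_sup > 0 and state is not None
            and state.saliency is not None):
        from .objectives import boundary_band_target, saliency_supervision_loss

        terms["saliency_sup"] = saliency_supervision_loss(
            state.saliency, boundary_band_target(masks)
        )
    return total_loss(terms, cfg)


@dataclass
class TrainResult:
    model: DualScopeNet
    history: list[dict]
    best_epoch: int
    best_val_dice: float
    manifest: dict


def per_image_reports(model: DualScopeNet, images: list[LabeledImage],
                      use_csi: bool = True, batch_size: int = 8,
                      tta: str = "none") -> list[tuple[str, "object"]]:
    """(ident, SegReport) per image, in dataset order."""
    out = []
    for lo in range(0, len(images), batch_size):
        chunk = images[lo:lo + batch_size]
        x = np.stack([im.image for im in chunk])
        if tta == "five_crop":
            masks = np.stack([
                decode_mask(predict_five_crop(model, im.image[None], use_csi=use_csi)[0])
                for im in chunk
            ])
        else:
            masks = model.predict_mask(x, use_csi=use_csi)
        for im, pred in zip(chunk, masks):
            out.append((im.ident,
                        evaluate_pair(pred, im.mask, model.cfg.n_classes,
                                      spacing_mm=im.pixel_size_mm)))
    return out


def evaluate_model(model: DualScopeNet, images: list[LabeledImage],
                   use_csi: bool = True, batch_size: int = 8,
                   tta: str = "none") -> dict:
    """Dataset-level aggregate of the per-image reports."""
    reports = [rep for _, rep in per_image_reports(model, images, use_csi,
                                                   batch_size, tta)]
    agg = aggregate_reports(reports)
    agg["use_csi"] = use_csi
    return agg


def train(arch: ArchConfig, run: RunConfig, train_set: list[LabeledImage],
          val_set: list[LabeledImage], out_dir: str | None = None,
          log_every_epoch: bool = True) -> TrainResult:
    check_disjoint_splits([x.ident for x in train_set], [x.ident for x in val_set])
    arch = replace(arch, seed=run.model_seed)
    model = DualScopeNet(arch)
    opt = AdamW(model.parameters(), lr=run.lr, weight_decay=run.weight_decay)
    rng = np.random.default_rng(run.train_seed)
    loss_cfg = replace(run.loss, label_smoothing=run.label_smoothing)

    n = len(train_set)
    steps_per_epoch = max(math.ceil(n / run.batch_size), 1)
    total_steps = steps_per_epoch * run.epochs
    weights = (_sampling_weights(train_set, arch.n_classes)
               if run.class_balanced else np.full(n, 1.0 / n))

    history: list[dict] = []
    best_val, best_epoch, best_state = -np.inf, -1, model.state_dict()
    step = 0
    for epoch in range(run.epochs):
        model.train()
        epoch_terms: dict[str, list[float]] = {}
        for _ in range(steps_per_epoch):
            idx = rng.choice(n, size=min(run.batch_size, n), replace=True, p=weights)
            batch = []
            for i in idx:
                im = train_set[i]
                if run.augment_enabled:
                    im = augment(im, run.augment, rng)
                batch.append(im)
            x = np.stack([im.image for im in batch])
            y = np.stack([im.mask for im in batch]).astype(np.int64)
            model.set_dropout_rng(rng)
            out = model(x)
            warmup_steps = run.aux_warmup_epochs * steps_per_epoch
            ramp = min(1.0, step / warmup_steps) if warmup_steps else 1.0
            loss, logged = compute_losses(model, out, y, loss_cfg, rng, ramp=ramp)
            model.zero_grad()
            loss.backward()
            opt.lr = cosine_lr(run.lr, step, total_steps)
            opt.step()
            step += 1
            for k, v in logged.items():
                epoch_terms.setdefault(k, []).append(v)

        row = {"epoch": epoch, "lr": opt.lr}
        row.update({f"loss_{k}": float(np.mean(v)) for k, v in epoch_terms.items()})
        for i, b in enumerate(model.decoder.aggregator.beta.data):
            row[f"beta_{i}"] = float(b)
        if model.csi_module is not None:
            for i, t in enumerate(model.csi_module.theta.data):
                row[f"theta_{i}"] = float(t)

        if (epoch + 1) % run.eval_every == 0 or epoch == run.epochs - 1:
            val = evaluate_model(model, val_set, use_csi=True)
            row["val_foreground_dice"] = val["mean_foreground_dice"]
            if val["mean_foreground_dice"] > best_val + 1e-12:
                best_val = val["mean_foreground_dice"]
                best_epoch = epoch
                best_state = model.state_dict()
            elif epoch - best_epoch >= run.patience:
                history.append(row)
                break
        history.append(row)

    model.load_state_dict(best_state)
    manifest = {
        "arch_fingerprint": arch.fingerprint(),
        "run_hash": run.config_hash(),
        "seeds": {"data": run.data_seed, "model": run.model_seed,
                  "train": run.train_seed},
        "best_epoch": best_epoch,
        "best_val_dice": best_val,
        "n_train": len(train_set),
        "n_val": len(val_set),
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        np.savez(os.path.join(out_dir, "checkpoint.npz"), **model.state_dict())
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        if log_every_epoch and history:
            keys = sorted({k for row in history for k in row})
            with open(os.path.join(out_dir, "training_log.csv"), "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=keys)
                writer.writeheader()
                writer.writerows(history)
    return TrainResult(model, history, best_epoch, best_val, manifest)


def load_checkpoint(path: str, arch: ArchConfig) -> DualScopeNet:
    model = DualScopeNet(arch)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


# ---------------------------------------------------------------------------
# prediction with test-time augmentation
# ---------------------------------------------------------------------------

def _forward_probs(model: DualScopeNet, x: np.ndarray, use_csi: bool) -> np.ndarray:
    out = model(x)
    logits = out.final_logits if (use_csi or out.csi is None) else out.bundle.logits
    return softmax(logits, axis=1).data


def predict_five_crop(model: DualScopeNet, images: np.ndarray,
                      crop_frac: float = 0.875, use_csi: bool = True) -> np.ndarray:
    """Average softmax maps over four corner crops plus the center crop.

    Each crop's probability map is reinserted into a zero canvas at its
    origin and the accumulation normalized by per-pixel coverage.
    """
    model.eval()
    model.set_dropout_rng(None)
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    n, _, h, w = x.shape
    div = 2 ** (len(model.cfg.channels) - 1)
    ch = int(crop_frac * h) // div * div
    cw = int(crop_frac * w) // div * div
    if ch > h or cw > w or ch < div or cw < div:
        raise ValueError(f"crop {ch}x{cw} incompatible with image {h}x{w}")
    origins = [(0, 0), (0, w - cw), (h - ch, 0), (h - ch, w - cw),
               ((h - ch) // 2, (w - cw) // 2)]
    acc = np.zeros((n, model.cfg.n_classes, h, w), np.float64)
    cover = np.zeros((h, w), np.float64)
    for oy, ox in origins:
        probs = _forward_probs(model, x[:, :, oy:oy + ch, ox:ox + cw], use_csi)
        acc[:, :, oy:oy + ch, ox:ox + cw] += probs
        cover[oy:oy + ch, ox:ox + cw] += 1.0
    return acc / cover


def predict(model: DualScopeNet, images: np.ndarray, tta: str = "none",
            use_csi: bool = True) -> np.ndarray:
    """Masks for a batch; ``tta='five_crop'`` averages five crop predictions."""
    model.eval()
    model.set_dropout_rng(None)
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    if tta == "none":
        return model.predict_mask(x, use_csi=use_csi)
    if tta == "five_crop":
        return decode_mask(Tensor(predict_five_crop(model, x, use_csi=use_csi)))
    raise ValueError(f"unknown tta mode {tta!r}")


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_SWITCHES = ("dual_branch", "gated_fusion", "csi.affinity",
                     "csi.saliency", "csi.graph")


def apply_switch(arch: ArchConfig, name: str) -> ArchConfig:
    """Return a config with one named component disabled."""
    if name == "dual_branch":
        return replace(arch, dual_branch=False)
    if name == "gated_fusion":
        return replace(arch, gated_fusion=False)
    if name.startswith("csi."):
        key = name.split(".", 1)[1]
        if key not in ("affinity", "saliency", "graph"):
            raise ValueError(f"unknown switch {name!r}; valid: {ABLATION_SWITCHES}")
        return replace(arch, csi=replace(arch.csi, **{key: False}))
    raise ValueError(f"unknown switch {name!r}; valid: {ABLATION_SWITCHES}")


def ablate(arch: ArchConfig, run: RunConfig, switches: list[str],
           train_set: list[LabeledImage], val_set: list[LabeledImage],
           test_set: list[LabeledImage], out_csv: str | None = None) -> list[dict]:
    """Train/evaluate the full model plus one variant per removed switch.

    All runs share seeds and splits; rows are variant name + test metrics.
    """
    for s in switches:
        apply_switch(arch, s)  # validates names up front
    rows = []
    variants = [("full", arch)] + [(f"w/o {s}", apply_switch(arch, s))
                                   for s in switches]
    for name, cfg in variants:
        result = train(cfg, run, train_set, val_set)
        agg = evaluate_model(result.model, test_set, use_csi=True)
        row = {"variant": name,
               "mean_foreground_dice": agg["mean_foreground_dice"],
               "accuracy": agg["accuracy"],
               "macro_f1": agg["macro_f1"],
               "best_epoch": result.best_epoch}
        rows.append(row)
    if out_csv:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows


# ---------------------------------------------------------------------------
# robustness harness
# ---------------------------------------------------------------------------

def robustness_curve(model: DualScopeNet, images: list[LabeledImage],
                     sigmas=(0.0, 0.05, 0.1), seeds=(0, 1, 2)) -> list[dict]:
    """Mean foreground Dice under increasing Gaussian corruption, averaged
    over noise seeds (sigma = 0 reuses the clean images untouched)."""
    rows = []
    for sigma in sigmas:
        dices = []
        for seed in seeds:
            cfg = ArtifactConfig(noise_sigma=sigma, seed=seed)
            rng = np.random.default_rng(seed)
            corrupted = [apply_artifacts(im, cfg, rng) for im in images]
            agg = evaluate_model(model, corrupted, use_csi=True)
            dices.append(agg["mean_foreground_dice"])
        rows.append({"sigma": sigma,
                     "mean_foreground_dice": float(np.mean(dices)),
                     "per_seed": [float(d) for d in dices]})
    return rows
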
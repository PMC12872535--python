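"""Training objectives.

The composite loss is a weighted sum of:

* label-smoothed cross-entropy on the final fused logits;
* per-head label-smoothed cross-entropy (deep supervision);
* an affinity contrastive term on pixel embeddings — same-(predicted-)label
  pairs are pulled together, different-label pairs pushed beyond a margin;
* a saliency-weighted focal loss (reduces to saliency-weighted CE at
  gamma = 0, and to plain CE with unit saliency);
* a KL consistency term between pre- and post-graph-propagation
  distributions;
* an embedding discriminability term (intra-class compactness plus a margin
  hinge on class-mean separation — the hinge replaces maximizing raw
  inter-class distance, which is unbounded).

Quadratic all-pairs sums are replaced by capped pair sampling; exhaustive
evaluation remains available for oracle comparison on tiny grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, log_softmax, softmax


@dataclass(frozen=True)
class LossConfig:
    margin: float = 3.0  # embedding margin m; keep m >~ 3*tau (see methods)
    lambda_a: float = 1.0  # inter-class balance inside the affinity loss
    gamma_focal: float = 2.0  # focusing exponent (set empirically)
    kl_eps: float = 1e-8
    label_smoothing: float = 0.1
    margin_mu: float = 3.0  # hinge margin on class-mean distances
    pair_cap: int = 1024  # sampled pairs per class per batch
    w_deep_supervision: float = 0.4  # per auxiliary head
    w_affinity: float = 0.1
    w_focal: float = 1.0
    w_relational: float = 0.1
    w_embedding: float = 0.05
    w_saliency_sup: float = 0.0  # optional boundary supervision of M
    w_final_ce: float = 1.0
    use_predicted_labels: bool = True  # affinity pairs from predictions, not GT

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.gamma_focal < 0 or self.lambda_a < 0:
            raise ValueError("gamma_focal and lambda_a must be >= 0")
        if self.kl_eps <= 0:
            raise ValueError("kl_eps must be > 0")
        if not (0.0 <= self.label_smoothing < 1.0):
            raise ValueError("label smoothing must be in [0, 1)")


def _flatten_embeddings(emb: Tensor) -> Tensor:
    """(N, D, H, W) -> (N*H*W, D); 2D inputs pass through."""
    if emb.ndim == 2:
        return emb
    n, d, h, w = emb.shape
    return emb.transpose(0, 2, 3, 1).reshape(n * h * w, d)


def _pair_indices(labels: np.ndarray, cap: int, rng: np.random.Generator,
                  exhaustive: bool):
    p = labels.shape[0]
    if exhaustive:
        i, j = np.triu_indices(p, k=1)
        return i, j
    classes = np.unique(labels)
    n_pairs = int(cap) * len(classes)
    i = rng.integers(0, p, size=n_pairs)
    j = rng.integers(0, p, size=n_pairs)
    keep = i != j
    return i[keep], j[keep]


def affinity_loss(
    emb: Tensor,
    labels: np.ndarray,
    margin: float,
    lambda_a: float,
    pair_cap: int = 1024,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> Tensor:
    """Contrastive regularizer over pixel-embedding pairs.

    ``labels`` are whatever the caller supplies — predicted labels in the
    default training configuration, ground truth behind the config flag.
    """
    e = _flatten_embeddings(emb)
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != e.shape[0]:
        raise ValueError("labels and embeddings disagree in pixel count")
    if labels.shape[0] < 2:
        warnings.warn("affinity loss needs >= 2 pixels; returning 0")
        return Tensor(np.zeros((), dtype=e.dtype))
    if rng is None:
        rng = np.random.default_rng(0)
    i, j = _pair_indices(labels, pair_cap, rng, exhaustive)
    same = (labels[i] == labels[j]).astype(e.dtype)
    diff = (e.take_rows(i) - e.take_rows(j)) ** 2
    d2 = diff.sum(axis=1)
    d = (d2 + 1e-12) ** 0.5
    hinge = (margin - d).relu() ** 2
    per_pair = Tensor(same) * d2 + lambda_a * Tensor(1.0 - same) * hinge
    return per_pair.mean()


def saliency_focal_loss(
    logits: Tensor,
    saliency: Tensor | np.ndarray,
    labels: np.ndarray,
    gamma: float,
) -> Tensor:
    """-sum_p M(p) (1 - p_true)^gamma log p_true / sum_p M(p).

    Normalization by the saliency mass decouples the loss scale from image
    size; with M = 1 and gamma = 0 this is exactly mean cross-entropy.

    The saliency map enters as a stop-gradient weight: if M could lower this
    loss directly it would learn to zero out hard pixels, a degenerate
    optimum.  M still trains through the recalibration pathway (and through
    optional boundary supervision).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    m = saliency.detach() if isinstance(saliency, Tensor) else Tensor(np.asarray(saliency))
    n, c = logits.shape[0], logits.shape[1]
    onehot = np.moveaxis(np.eye(c, dtype=logits.dtype.type)[labels], -1, 1)
    logp = log_softmax(logits, axis=1)
    logp_true = (logp * onehot).sum(axis=1, keepdims=True)
    if gamma == 0.0:
        per_pixel = -logp_true
    else:
        p_true = (softmax(logits, axis=1) * onehot).sum(axis=1, keepdims=True)
        per_pixel = -((1.0 - p_true) ** gamma) * logp_true
    mass = float(m.data.sum())
    if mass <= 0:
        warnings.warn("zero saliency mass; focal loss is 0")
        return Tensor(np.zeros((), dtype=logits.dtype))
    return (m * per_pixel).sum() / mass


def relational_consistency_loss(n_logits: Tensor, r_logits: Tensor,
                                eps: float) -> Tensor:
    """Pixel-averaged KL( softmax(N) || softmax(R) + eps )."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    p_log = log_softmax(n_logits, axis=1)
    p = softmax(n_logits, axis=1)
    r = softmax(r_logits, axis=1)
    if eps > 0:
        log_r = (r + eps).log()
    else:
        log_r = log_softmax(r_logits, axis=1)
    kl = (p * (p_log - log_r)).sum(axis=1)
    return kl.mean()


def embedding_discriminability(
    emb: Tensor,
    labels: np.ndarray,
    margin_mu: float = 1.0,
    pair_cap: int = 1024,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, float, Tensor]:
    """Intra-class pair compactness + hinged inter-class mean separation.

    Returns ``(D_intra, D_inter, loss)`` where D_intra is the mean squared
    distance over (sampled) same-class pairs, D_inter the summed squared
    distances between class means, and the loss D_intra plus the margin
    hinge on every class-mean pair.
    """
    e = _flatten_embeddings(emb)
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if rng is None:
        rng = np.random.default_rng(0)

    # intra-class compactness over sampled pairs, mean-normalized
    intra_terms = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        if exhaustive:
            ii, jj = np.triu_indices(len(idx), k=1)
            i, j = idx[ii], idx[jj]
        else:
            n_pairs = min(pair_cap, len(idx) * (len(idx) - 1) // 2)
            i = idx[rng.integers(0, len(idx), size=n_pairs)]
            j = idx[rng.integers(0, len(idx), size=n_pairs)]
            keep = i != j
            i, j = i[keep], j[keep]
            if len(i) == 0:
                continue
        intra_terms.append((((e.take_rows(i) - e.take_rows(j)) ** 2).sum(axis=1)).mean())
    if intra_terms:
        d_intra = intra_terms[0]
        for t in intra_terms[1:]:
            d_intra = d_intra + t
        d_intra = d_intra / float(len(intra_terms))
    else:
        d_intra = Tensor(np.zeros((), dtype=e.dtype))

    # class means via masked averaging (differentiable)
    means = []
    for c in classes:
        mask = (labels == c).astype(e.dtype)[:, None]
        means.append((e * mask).sum(axis=0) / float(mask.sum()))

    # one term per unordered class pair
    d_inter_val = 0.0
    hinge_total = Tensor(np.zeros((), dtype=e.dtype))
    for a in range(len(means)):
        for b in range(a + 1, len(means)):
            d2 = ((means[a] - means[b]) ** 2).sum()
            d_inter_val += float(d2.data)
            dist = (d2 + 1e-12) ** 0.5
            hinge_total = hinge_total + (margin_mu - dist).relu() ** 2
    loss = d_intra + hinge_total
    return float(d_intra.data), d_inter_val, loss


def boundary_band_target(masks: np.ndarray, radius: int = 2) -> np.ndarray:
    """Binary band around foreground class boundaries, (N, 1, H, W).

    Optional supervision target for the saliency map: clinically the
    ambiguous zones are organ edges, so M is encouraged toward 1 on a
    ``radius``-pixel band around every foreground boundary and 0 elsewhere.
    """
    from scipy import ndimage

    masks = np.asarray(masks)
    bands = np.zeros(masks.shape, np.float32)
    structure = ndimage.generate_binary_structure(2, 1)
    for i, m in enumerate(masks):
        edges = np.zeros(m.shape, dtype=bool)
        for c in np.unique(m):
            if c == 0:
                continue
            region = m == c
            edges |= region ^ ndimage.binary_erosion(region, structure, border_value=0)
        bands[i] = ndimage.binary_dilation(edges, structure, iterations=radius)
    return bands[:, None]


def saliency_supervision_loss(m: Tensor, target: np.ndarray) -> Tensor:
    """Binary cross-entropy pulling the saliency map toward a boundary band."""
    t = np.asarray(target, dtype=m.dtype.type)
    eps = 1e-7
    clipped = m * (1.0 - 2.0 * eps) + eps
    ll = Tensor(t) * clipped.log() + Tensor(1.0 - t) * (1.0 - clipped).log()
    return -ll.mean()


def smoothed_cross_entropy(logits: Tensor, labels: np.ndarray,
                           smoothing: float) -> Tensor:
    """Mean cross-entropy against (1 - eps) one-hot + eps/C targets."""
    c = logits.shape[1]
    onehot = np.moveaxis(np.eye(c, dtype=logits.dtype.type)[labels], -1, 1)
    target = (1.0 - smoothing) * onehot + smoothing / c
    logp = log_softmax(logits, axis=1)
    return -(Tensor(target) * logp).sum(axis=1).mean()


def total_loss(terms: dict[str, Tensor], cfg: LossConfig) -> tuple[Tensor, dict]:
    """Weighted sum of the enabled terms.

    ``terms`` maps term names (``final_ce``, ``deep_supervision``,
    ``affinity``, ``focal``, ``relational``, ``embedding``) to scalar
    tensors; missing terms are skipped.  All-zero weights are a
    configuration error.
    """
    weights = {
        "final_ce": cfg.w_final_ce,
        "deep_supervision": cfg.w_deep_supervision,
        "affinity": cfg.w_affinity,
        "focal": cfg.w_focal,
        "relational": cfg.w_relational,
        "embedding": cfg.w_embedding,
        "saliency_sup": cfg.w_saliency_sup,
    }
    if all(v == 0 for v in weights.values()):
        raise ValueError("all loss weights are zero")
    total = None
    logged: dict[str, float] = {}
    for name, term in terms.items():
        if name not in weights:
            raise KeyError(f"unknown loss term {name!r}")
        logged[name] = float(term.data)
        if weights[name] == 0:
            continue
        contrib = weights[name] * term
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no weighted loss terms supplied")
    logged["total"] = float(total.data)
    return total, logged
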
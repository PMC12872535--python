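# Methods

## Problem and model

`dualscope` segments 2D grayscale images into C classes (background plus
organ-like structures) with a dual-branch encoder–decoder followed by a
differentiable refinement stage, and evaluates everything on synthetic
CT-like phantoms with known ground truth.

**Dual-branch encoding.** A *semantic* stream of dilated residual blocks
(conv–norm–ReLU–conv–norm plus identity shortcut, one block per level, 2×
average pooling between levels) captures large-scale context; a non-local
attention block — softmax dot-product attention over all positions of a
learned linear embedding φ to half the channel count — is applied at the
coarsest level only, where the quadratic cost is trivial (an optional 2×
pre-pool covers coarse grids above 64 px per side). A *local* stream of
shallow hybrid-dilation blocks (3×3 at dilation 1 then 2) receives the
Sobel gradient magnitude of the input, average-pooled to each level's
resolution and concatenated to that level's input, so boundary evidence
propagates directly to depth. Per level the streams are blended by a
sigmoid gate γ = σ(1×1 conv on [S, L]) as F = γ·S + (1−γ)·L; the fused map
is elementwise within the two streams' envelope by construction. The
encoder "alignment" and decoder "fusion" gates are one block type
instantiated per level — the two formulations are algebraically identical.

**Deeply-supervised decoding.** The decoder walks the fused pyramid
coarse-to-fine (upsample ×2, concatenate skip, 3×3 conv–norm–ReLU). Each
stage has a 1×1 head to class logits, upsampled to full resolution; the
per-level logits are combined with learnable simplex weights β (softmax of
free scores, uniform initialization). Aggregation operates on *pre-softmax
logits*: the refinement stage consumes logits, so one consistent score
space runs through the whole pipeline, and the convexity of the weighted
sum is preserved. The finest stage also produces a pixel embedding map
E(p) (1×1 head, D = 16 by default, 8 in the compact profile) from which a
two-layer perceptron predicts a per-pixel dilation rate d(p) ∈ {1,2,3};
the final decoder convolution shares one 3×3 weight tensor across the
three dilation rates and blends the responses per pixel — softly while
training (differentiable), hard argmax at inference with lowest-index
tie-break. Masks are always argmax over channels with lowest-index
tie-break.

**Contextual synergy refinement (CSI).** Post-decoder, fully
differentiable:

1. *Affinity propagation*: Ũ(p) = Σ_q softmax_q(−‖E(p)−E(q)‖²/τ²) U(q) on
   a stride-s average-pooled grid (s = 4 default, grid capped at 4096
   pixels).
2. *Saliency recalibration*: U_sal = (1 + λ·M)·Ũ with M ∈ (0,1) from a
   two-conv + sigmoid block on the finest decoder features. The factor is
   positive and channel-shared, so per-pixel class ranking is untouched;
   its effect flows through softmax confidence and the losses.
3. *Prior normalization*: N_c = (1 + λ_prior·α_c)·U_sal,c with α the
   spatial mean softmax probability (one prior, one scaling site).
4. *Graph propagation*: w_ij = mean_p s_i(p)s_j(p) from the softmax of
   U_sal (symmetric, total mass exactly 1); per row the top-k off-diagonal
   entries plus the diagonal survive sparsification; R = w·N per pixel.
   Per-image graphs by default; an exponential-moving-average graph
   approximating dataset-wide co-occurrence is available.
5. *Sharpening*: unsharp masking U_sal + η(U_sal − box₃ₓ₃(U_sal)) with a
   reflect-padded box blur (a documented stand-in for an otherwise
   undefined boundary-enhanced term).
6. *Fusion*: θ₁R + θ₂N + θ₃·sharp with θ a 3-way softmax of free scores.

### Reduced-grid reinsertion

The refinement runs at reduced resolution, but *how* the result returns to
full resolution is a free design choice. Upsampling the refined coarse
logits directly erases structures smaller than the stride: on the phantom
benchmark this costs the small adjacent class ~0.1 Dice and is the single
largest source of refinement harm. The default is therefore
detail-preserving reinsertion: the bilinearly upsampled *correction*
up(A·U↓ − U↓) is added to the full-resolution logits. At stride 1 this is
algebraically the plain propagation; under the neutral configuration
(τ→0, separated embeddings) it is exactly the identity. The direct mode
remains available (`detail_preserving=False`).

### Choosing the contrastive margin relative to τ

The affinity attention mixes classes whenever cross-class embedding
distances are comparable to τ. For a rare class occupying P₁ of P reduced
pixels, cross-class mass overwhelms within-class mass unless
(P−P₁)·exp(−d²/τ²) ≪ P₁; with P ≈ 256 and P₁ ≈ 10 this requires d ≳ 3τ.
The contrastive margin (m, and the class-mean hinge m_μ) defaults to 3.0;
the compact profile pairs it with τ = 0.5 and stride 2 (m/τ = 6, so
trained embeddings give cross-class attention weight ≈ e⁻³⁶ and
propagation averages within classes, which is the stated purpose of the
stage). With the generic choice m = τ = 1 the refinement systematically
erased the small class; with this scaling it improves both Dice and
fragmentation over the unrefined decoder on the phantom benchmark.

## Losses

Total = smoothed CE on the final fused logits (ε = 0.1) + mean per-head
smoothed CE (deep supervision, weight 0.4) + affinity contrastive term
(0.1) + saliency-weighted focal (1.0, γ = 2) + relational KL (0.1) +
embedding discriminability (0.05), each weight config-exposed. Notes:

- *Pair sampling* (cap 1024 pairs per class per batch, on the stride-s
  grid) replaces exact O(|Ω|²) sums; unit tests compare the exhaustive
  mode against brute-force loops.
- *Affinity pairs* use predicted labels by default (ground truth behind a
  flag).
- *Focal loss* is normalized by saliency mass so its scale is independent
  of image size, and M enters as a stop-gradient weight: a trainable M
  inside its own weighting is minimized by suppressing hard pixels. M
  still learns through the recalibration path, plus optional boundary-band
  supervision (binary CE toward a 2 px band around foreground boundaries,
  weight 0 by default).
- *Auxiliary warm-up*: the affinity, focal, relational and embedding
  weights ramp linearly from 0 over the first 2 epochs. At initialization
  predictions are near-uniform, so the contrastive terms see almost no
  different-label pairs and act as pure attraction, collapsing the
  embedding space before any segmentation structure exists; warmed up,
  the same terms behave as intended. This was the difference between the
  rare class never being learned and reaching Dice ≈ 0.85.
- *Embedding term*: intra-class compactness (mean squared distance over
  sampled same-class pairs) plus a margin hinge on class-mean distances —
  maximizing raw inter-class distance is unbounded. The inter-class sum
  counts each unordered pair once.
- *Dropout*: 0.1 on fused backbone features, 0.2 inside CSI.

## Training protocol

AdamW (weight decay 10⁻⁴) under cosine decay to 5% of the base rate;
batches drawn with replacement, class-balanced by inverse frequency of the
rarest class present per image; augmentation (flips, ±15° rotation, ±10%
scaling, coarse elastic deformation with 16 px control spacing, intensity
jitter) applied on the fly; early stopping on validation foreground Dice
with patience 10; the best-validation checkpoint is retained. Splits are
image-level and checked disjoint (overlap is a hard error). Deterministic
end to end: data, model-init, sampling/augmentation/dropout randomness sit
behind three named seeds, and repeated runs are bit-identical.

Two architecture profiles: the library default (4 levels, channels
16/32/64/128, dilations 1/1/2/2, D = 16) and a compact profile
(`ArchConfig.desk_scale()`: 3 levels, 8/16/32, D = 8, refinement stride 2
with τ = 0.5) used by the end-to-end tests and the acceptance script,
with 64×64 phantoms, 200 train / 50 val / 50 test, batch 8, learning
rate 3·10⁻³, 16 epochs, validation every 2 epochs — the training length
is set so the slowest-converging variant (the full model) has plateaued,
and the problem sizes keep a full run around four minutes on one CPU
core while reaching foreground Dice ≳ 0.9.

## Synthetic phantoms

Each phantom is piecewise-constant intensity plus Gaussian noise (σ = 0.05
default) on a 64×64 grid: background 0.25; class 1 a large bright ellipse
(intensity 0.70, semi-axis 12–18 px) always present; class 2 a smaller
low-contrast ellipse (0.55, 7–11 px) grown overlapping class 1 and carved
back, guaranteeing a shared ambiguous boundary; optional further classes
(capsules/blobs) appear with configurable occurrence probability. This
reproduces the difficulty profile of pelvic organ contouring — a
well-contrasted dominant structure, an adjacent low-contrast neighbour,
small rare structures — in its simplest form. Clinical artifacts are
modeled as multiplicative intensity scaling, then 1-D uniform motion blur
along one axis, then additive Gaussian noise (noise last matches
acquisition physics), clipped to [0,1]; the zero-strength configuration
is a bit-exact no-op.

What the phantoms do *not* model: Hounsfield calibration, texture,
partial-volume effects, 3D continuity, scanner/protocol shift. Passing
the end-to-end tests therefore demonstrates that the architecture,
refinement and losses function as specified and can learn low-contrast
adjacent and rare structures — not clinical-grade performance.

## Numerical choices

- All computation is float32 (float64 in gradient tests); the autodiff
  core is a minimal reverse-mode engine over NumPy arrays (im2col
  convolutions, transposed-convolution input gradients, matrix-form
  bilinear resampling), gradient-checked against central differences.
- Batch norm: batch statistics in training, running averages (momentum
  0.1) at inference; the residual blocks zero-initialize the final norm
  scale so fresh blocks start as (projected) identities.
- Argmax ties always break to the lowest class index; the dilation
  selector inherits the same rule.
- Affinity distances are clamped at 0 before the softmax (guarding
  floating-point negatives); hinge distances add 10⁻¹² inside the square
  root to keep the gradient finite at coincident pairs.
- KL consistency uses ε = 10⁻⁸ inside the log; at P = R the bias is
  bounded by ε·C.
- Dice with both masks empty reports 1.0 with an `undefined` flag; HD95
  with an empty surface reports NaN with a flag; macro averages skip
  flagged classes. HD95 is the default (max-Hausdorff behind a flag);
  components are 4-connected (8 behind a flag).

## Known limitations

- The class-co-occurrence graph (unnormalized co-activation) inherently
  down-weights rare classes in the propagated logits R; the relational KL
  and the learned fusion weights θ limit, but do not remove, this bias.
- Non-local attention and affinity propagation are quadratic in (coarse)
  pixel count; caps raise errors rather than silently degrade.
- The saliency map is only weakly identified without boundary
  supervision; enabling the supervision term concentrates it on organ
  boundaries.
- CPU-only by construction; the compact profile is sized for desk-scale
  experiments, not clinical images.
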
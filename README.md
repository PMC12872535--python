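# dualscope

Dual-branch, attention-fused 2D segmentation with a contextual-synergy
refinement stage, built for organ-at-risk–style contouring problems and
exercised entirely on synthetic CT-like phantoms.

## Who this is for

Researchers who want a fully inspectable, CPU-scale implementation of a
dual-stream segmentation architecture — semantic context in one encoder,
gradient-driven boundary detail in the other, sigmoid-gated fusion per
level, deep supervision, and a differentiable post-decoder refinement
(pixel-affinity propagation, saliency recalibration, class-prior scaling,
class co-occurrence graph propagation, unsharp boundary enhancement,
learned three-way fusion). Every equation-level operation is unit-tested
against brute-force oracles, and the synthetic phantom generator
reproduces the difficulty profile of pelvic CT contouring (a large
well-contrasted structure, an adjacent low-contrast neighbour sharing an
ambiguous boundary, small rare structures) so the whole pipeline is
verifiable without clinical data.

## The model in brief

Per level l the two encoder streams are blended by a learned gate

    gamma^(l) = sigmoid(G([S^(l), L^(l)])),   F^(l) = gamma*S + (1-gamma)*L

Per-level 1×1 heads give logits Z^(l); the final score map is the simplex
combination U = sum_l beta_l Z^(l) (beta = softmax of learned scores).
The refinement then computes, from U and the pixel embeddings E,

    affinity:  U~(p)    = sum_q softmax_q(-||E(p)-E(q)||^2 / tau^2) U(q)
    saliency:  U_sal    = (1 + lambda * M) * U~
    prior:     N_c      = (1 + lambda_p * alpha_c) * U_sal,c
    graph:     R        = w N,   w_ij = mean_p s_i(p) s_j(p)
    fusion:    theta_1 R + theta_2 N + theta_3 sharpen(U_sal)

followed by argmax decoding (ties to the lowest class index). Training
combines label-smoothed cross-entropy (final + per-head deep
supervision), an embedding contrastive affinity loss, a saliency-weighted
focal loss, a relational KL consistency term and an embedding
discriminability term. See `docs/methods.md` for assumptions, parameter
defaults and design rationale.

## Worked example

```python
import numpy as np
from dualscope import ArchConfig, PhantomSpec, RunConfig, generate_dataset
from dualscope.workflow import train, evaluate_model

data = generate_dataset(PhantomSpec(seed=11), 300)   # 64x64, 3 classes
train_set, val_set, test_set = data[:200], data[200:250], data[250:300]

result = train(ArchConfig.desk_scale(seed=7),
               RunConfig(epochs=16, lr=3e-3, eval_every=2,
                         model_seed=7, train_seed=7),
               train_set, val_set)
report = evaluate_model(result.model, test_set, use_csi=True)
print(round(report["mean_foreground_dice"], 3))
print([round(d, 3) for d in report["dice_per_class"]])
```

On one CPU core this trains in a few minutes and prints

```
0.941
[0.998, 0.986, 0.896]
```

— the mean Dice over the two foreground structures on the 50 held-out
phantoms, then per-class Dice (background, the large bright ellipse, the
small low-contrast neighbour; the last is the hard class by
construction). `evaluate_model(..., use_csi=False)` scores the same
checkpoint without the refinement stage, and
`dualscope.workflow.robustness_curve` sweeps Gaussian-noise corruption.

The same functionality is scriptable:

```bash
dualscope phantom generate --spec spec.yaml --n 200 --seed 17 --out data/
dualscope train --config run.yaml --data data/manifest.json --val val/manifest.json --out ckpt/
dualscope evaluate --checkpoint ckpt/ --data test/manifest.json --out report.json
dualscope refine --arrays arrays.npz --out refined/ --no-graph   # standalone CSI
dualscope ablate --config run.yaml ... --switch dual_branch --switch csi.affinity
```

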
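# leafdx

Classification of nutrient deficiencies from leaf images with a dual-track
deep network, built for plant-phenotyping researchers who need a tested,
CPU-runnable reference implementation of the architecture and its training
protocol.

Coffee-leaf nutrient deficiencies (B, Ca, Fe, Mg, Mn, N, P, K, multiple,
healthy) show up as a mix of global discoloration and fine local structure.
The model decouples the two:

* **Track 1** — MobileNetV3-Large features followed by a
  *multi-convolutional shape-aware kernel* (MCSK) block: a shape
  convolution (patch `P` split as `P_B = m(P)`, `P_S = P − m(P)`,
  re-weighted and convolved) in parallel with an attention-augmented
  convolution, each refined by a ghost module and a split convolution, then
  fused by selective-kernel convolution and spatial group-wise enhancement.
* **Track 2** — a *hierarchical shuffled group attention network* (HSGAN):
  push–pull stem `relu(k∗x) − α·relu(−k∗x)`, four dual-pipeline blocks
  (pointwise + depthwise-separable ∥ 5×5 + local group attention) with
  channel shuffle, topped by efficient channel attention
  `ω = σ(Conv1D_k(GAP(x)))` with `k` derived from the channel count.
* **Fusion** — concatenation → multidimensional collaborative attention
  (channel/height/width branches, averaged: `F″ = ⅓(F′_C + F′_H + F′_W)`)
  → spatial pyramid pooling → dropout → dense → logits.

Training follows the tuned protocol: Adam, learning rate 1e-4, weight decay
1e-4, batch 16, cross-entropy, cosine annealing
`η(t) = η_min + ½(η_max−η_min)(1+cos(πt/T))`, stratified 60:20:20 splits
and 5-fold cross-validation; metrics are confusion-matrix derived
accuracy/precision/recall/F1 (macro and weighted).

Everything runs on NumPy through a small bundled autodiff engine — no GPU
framework required.  A seeded synthetic leaf-image generator (class-specific
chlorosis/necrosis motifs) makes the entire pipeline testable without any
dataset download; real datasets are read from the standard
one-directory-per-class image layout.

## Worked example

```python
import numpy as np
from leafdx import (DualTrackNet, ModelConfig, SyntheticSpec, TrainConfig,
                    generate_synthetic, evaluate, nn, train, count_parameters)

# 80 synthetic leaves, 10 classes, fully seeded
train_ds = generate_synthetic(SyntheticSpec(num_per_class=8, image_size=96, seed=0))
held_ds  = generate_synthetic(SyntheticSpec(num_per_class=4, image_size=96, seed=1))

nn.manual_seed(0)
model = DualTrackNet(ModelConfig(input_size=96, spp_levels=(1, 2)))
print(f"{count_parameters(model)/1e6:.2f} M parameters")

model, history = train(model, train_ds, None, TrainConfig(epochs=5, seed=0))
print("train accuracy:", evaluate(model, train_ds).accuracy)
print("held-out accuracy:", evaluate(model, held_ds).accuracy)
```

prints (exact numbers from this seeded run):

```
8.98 M parameters
train accuracy: 0.9125
held-out accuracy: 0.875
```

i.e. five seeded epochs on 80 images reach 91% training accuracy and 88%
on a held-out synthetic split (chance is 10%) — a desk-scale sanity check
of the full two-track pipeline, not a field-accuracy claim.

The standalone MobileNetV3-Large baseline reproduces its published size:

```python
from leafdx import build_backbone, count_parameters
print(round(count_parameters(build_backbone(num_classes=1000)) / 1e6, 2))  # 5.48
```

## Command line

```sh
leafdx synth --out data/synthetic --seed 0        # synthetic dataset on disk
leafdx train --data data/synthetic --variant full # train one variant
leafdx ablate --data data/synthetic               # all four ablation variants
leafdx cv --data data/synthetic --k 5             # stratified 5-fold CV
leafdx eval --checkpoint runs/full.npz --data data/synthetic
leafdx info --variant full                        # parameter/MAC accounting
```

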
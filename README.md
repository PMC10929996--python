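# coretr

Automatic delineation of the gross tumor volume (GTV) in lung CT is a
bottleneck of radiotherapy planning: manual contouring takes a physician
on the order of fifteen minutes per patient, and adaptive replanning
multiplies that cost. `coretr` implements a hybrid deep-learning
segmentation framework for this task — a convolutional encoder with residual
blocks, a deformable transformer for long-range context, and an upsampling
decoder — together with everything needed to run and evaluate it end to end:
HU preprocessing, patch-based training with nine augmentations,
sliding-window whole-volume inference, Dice/Hausdorff evaluation with a
single- vs multiple-tumor split, and a synthetic lung-phantom generator so
the whole pipeline is testable with no clinical data.

It is aimed at medical-image-analysis researchers who want a transparent,
dependency-light reference implementation of this architecture family: the
network runs on a small numpy reverse-mode autodiff core included in the
package (no GPU framework required), so every operation — deformable
attention included — is plain, inspectable array code.

## The model

An input patch `X` (H×W×D, HU-normalized) is processed at two resolutions:
a shallow CNN (5 Conv-IN-ReLU layers + 6 residual stages) sees the
2×-upsampled patch to preserve positional detail, while a deep CNN (same
stem, 9 residual blocks) sees the 2×-downsampled patch for semantic
context. A multi-scale feature pyramid fuses the maps `F_{i,j}` of branch
*i* at scale *j* additively:

    F'_{i,j} = Conv1×1×1(F_{i,j}) + Upsample×2(F'_{i,j-1}) + Upsample×2(F'_{i+1,j})

propagating top-down within each branch and from the low-resolution branch
into the high-resolution one. The coarsest scales are flattened into tokens
with a sinusoidal 3D positional encoding,

    PoE(pos, 2k) = sin(pos·v_k),  PoE(pos, 2k+1) = cos(pos·v_k),
    v_k = 1 / 10000^(2k/(C/3))  per axis,

and processed by stacked DeTrans layers: deformable self-attention (each
query attends to a small set of learned continuous sampling locations per
head and scale — cost linear in sequence length), a feed-forward network,
layer normalization and skip connections. The decoder reshapes tokens back
to grids and upsamples with transpose convolutions, merging encoder skips,
to voxel-wise logits. Evaluation uses the Dice overlap
`2|X∩Y|/(|X|+|Y|)` and the symmetric Hausdorff distance (plus HD95) in
physical millimetres.

See `docs/methods.md` for assumptions, defaults, and design decisions.

## Worked example

Generate phantoms, train a reduced model, and evaluate:

```python
import numpy as np
from coretr import (ModelConfig, TrainConfig, phantom_dataset, preprocess,
                    sliding_window_predict, dice_score, hausdorff_distance)
from coretr.train_infer import train

ranges = {"dims": (32, 32, 32), "radius_mm": (4.0, 7.5), "noise_sd": 0.0,
          "spacing_choices": [(2.0, 2.0, 2.0)], "n_tumors_choices": (1,)}
data = [(preprocess(v), s) for v, s, _ in phantom_dataset(5, ranges, seed=7)]

cfg = ModelConfig.tiny()          # 16^3 patches, reduced width/depth
tc = TrainConfig(epochs=200, patches_per_volume=4, augment=False,
                 val_fraction=0.0, seed=1, val_interval=5, train_dice_stop=0.9)
ckpt = train(data, tc, cfg)
model = ckpt.build_model()
for i, (vol, gt) in enumerate(data):
    pred = sliding_window_predict(vol, model, overlap=0.5)
    print(f"case {i}: Dice {dice_score(pred, gt):.3f}  "
          f"HD {hausdorff_distance(pred, gt, gt.spacing):.2f} mm")
```

Output (about 8 minutes on one CPU; training stops early once the
training-set Dice passes 0.9, here after 70 epochs):

```
case 0: Dice 0.988  HD 2.00 mm
case 1: Dice 0.973  HD 2.00 mm
case 2: Dice 0.936  HD 2.00 mm
case 3: Dice 0.952  HD 2.00 mm
case 4: Dice 0.918  HD 2.83 mm
```

The model has memorized its five training phantoms (Dice near 1, boundary
error around one voxel at 2 mm spacing) — the standard smoke test that the
architecture, loss, optimizer and inference tiling are wired correctly.

There is also a CLI:

```bash
coretr phantom --n-cases 10 --seed 1 --out data/
coretr train --config cfg.yaml --data data/ --ckpt model.ckpt
coretr predict --ckpt model.ckpt --in data/case_000_ct.nii.gz --out pred.nii.gz
coretr evaluate --pred preds/ --gt gts/ --report report.json
```

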
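# asdnet

Kidney and kidney-tumor segmentation of abdominal CT, implemented as a
tested Python library: a dual-encoder/single-decoder U-Net variant with
attention blocks, the accompanying CT slice-preparation pipeline, the
combined BCE–Dice training objective, the standard overlap metrics, and
a phantom generator so every component runs at desk scale on one CPU —
no dataset download, no GPU.

## Who this is for

Researchers and students who want a readable, fully testable reference
implementation of this family of segmentation architecture — asymmetric
convolution blocks, concurrent spatial/channel squeeze-and-excitation
(scSE) gates, dense dilated blocks, an atrous spatial pyramid pooling
(ASPP) bridge, and a removed top skip connection — together with the CT
preprocessing conventions (Hounsfield windowing, slice filtering,
flip/rotate augmentation) used to train it.

## The model

Two parallel encoders over five scales: a plain convolutional path
(two 3×3 conv+BN+ReLU per level, 2×2 max pooling) and an attention path
(per level: ASCO block → DDEC block → scSE gate), interconnected level
by level.  An ASPP bridge sits at the bottleneck; a single decoder
upsamples with 2×2 transposed convolutions and skip connections from the
attention encoder — except at full resolution, where the top skip is
removed.  Training minimises

    L = ½·L_BCE + L_Dice,
    L_BCE  = −mean_i [ y_i ln p_i + (1−y_i) ln(1−p_i) ],
    L_Dice = 1 − (2 Σ y_i p_i + ε) / (Σ y_i² + Σ p_i² + ε),

and evaluation reports IoU = TP/(TP+FP+FN), DSC = 2TP/(2TP+FP+FN),
recall and precision.  The ASCO block's parallel 3×3 + 3×1 + 1×3
branches are algebraically one fused 3×3 convolution; the test suite
holds the implementation to that identity.

The network runs on `asdnet.nn`, a compact numpy tensor library with
reverse-mode autodiff (im2col convolution, batch norm, max/transposed
pooling, Adam) written for this package and verified against finite
differences and scipy.

## Worked example

```python
import numpy as np
from asdnet.synthetic_data import desk_spec, generate_dataset
from asdnet.network import ASDNet, NetworkConfig
from asdnet.runtime import TrainConfig, train, evaluate

ds = generate_dataset(desk_spec(seed=1), n_volumes=10, task="kidney")
print(ds.counts())                      # {'train': 72, 'val': 8, 'test': 6}

model = ASDNet(NetworkConfig(base_channels=8), seed=3)
history, best = train(model, ds.splits["train"], ds.splits["val"],
                      TrainConfig(epochs=30, seed=3))
print(round(history.best_val_dsc, 3))   # 0.968

model.load_state_dict(best)
table, agg = evaluate(model, ds.splits["test"])
print({k: round(v, 3) for k, v in agg["pooled"].items()})
```

The run above (about four minutes on one CPU core) trains the reduced
network on ten synthetic phantom volumes and reaches a validation DSC of
0.968 on the kidney task: the phantom kidneys are bright ellipses, so a
correct implementation should segment them nearly perfectly, and this
number is the package's desk-scale competence check rather than a claim
about clinical CT.  On the harder tumor task the dual-encoder network
scores around 0.57 versus 0.47 for a plain U-Net of matched width
trained identically.

The same pipeline is available from the shell:

```bash
asdnet synth --n 10 --out cases/ --seed 1 --shape 16,64,64
asdnet preprocess --cases cases/ --task kidney --window -200:500 --out slices/ --seed 1
asdnet train --manifest slices/manifest_kidney.csv --seed 3 --out run/
asdnet evaluate --model run/ --manifest slices/manifest_kidney.csv --out run/eval/
```

## Layout

```
src/asdnet/
  nn/               numpy autodiff tensor + CNN layers + Adam
  preprocessing.py  HU windowing, slicing, filtering, augmentation, NIfTI/PNG I/O
  blocks.py         scSE gate, ASCO, DDEC, ASPP, kernel-fusion oracle
  network.py        ASDNet assembly, plain U-Net baseline, predict/save/load
  objectives.py     BCE, Dice, combined loss; confusion counts and metrics
  synthetic_data.py phantom volume and dataset generation
  runtime.py        training loop, evaluation, configs
  experiments.py    canonical desk-scale experiments
  cli.py            asdnet {synth,preprocess,train,predict,evaluate}
```
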
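# glottisqc

Automatic quality assessment for binary glottis segmentations from
high-speed videolaryngoscopy (HSV).

## The problem

Segmenting the glottis — the opening between the vocal folds — is the
first step of almost every quantitative HSV analysis. Segmentation
networks fail silently: a few corrupted frames in a multi-thousand-frame
recording can distort downstream vibratory features and, in clinical
use, lead to misdiagnosis. Checking frames by hand is not realistic at
HSV frame rates, so the failed segmentations must be found automatically
— *without* ground truth, from just the frame and the candidate mask.

`glottisqc` treats this as regression-then-thresholding. A two-channel
residual convolutional network receives the grayscale frame and the
candidate segmentation and predicts the segmentation's IoU
(intersection over union) against the unknown ground truth,

    IoU = TP / (TP + FP + FN),

and the predicted score ŷ is thresholded at a fixed acceptance level
*t* = 0.6: scores at or above *t* are **accepted**, those below are
**declined** as failed. Because no labeled failure data exist, the
package also ships two generators of exactly-labeled failures:

* a **knowledge-driven perturbation procedure**: six randomized mask
  corruption operators (rotation, dilation, erosion, breaking, copying,
  ellipse insertion) are applied to a ground-truth mask until its IoU
  reaches a target drawn from a 6-bin score distribution biased toward
  borderline cases near *t*;
* an **augmentation-intensity ramp**: a pluggable segmenter is fed
  frames corrupted at intensity `amp` (rotations, gamma, brightness /
  contrast, Gaussian noise, all scaled linearly by `amp`), and its
  increasingly wrong outputs are harvested as failures.

Training uses a threshold-aware loss family. With y the true IoU and ŷ
the prediction,

    Loss_bn = mean[ max(0, ŷ−t)·max(0, t−y) + max(0, t−ŷ)·max(0, y−t) ]
    Loss_ft = mean[ max(0, t−y) · |ŷ − y| ]
    Loss    = λ0·MSE(y, ŷ) + (1−λ0)·( λ1·Loss_bn + (1−λ1)·Loss_ft )

`Loss_bn` punishes only predictions on the wrong side of the threshold;
`Loss_ft` concentrates fidelity on truly failed segmentations (y < t),
where an accurate score matters most.

Everything is exercised on synthetic laryngoscopy *phantoms* — dark,
roughly elliptical glottal openings between brighter vocal-fold regions
on a textured, noisy background, including closed-glottis (empty-mask)
cases — so the whole pipeline is testable and reproducible without
clinical data. A trained clinical segmenter can be plugged into the same
interfaces.

## Worked example

```bash
python examples/train_quality_model.py
```

trains the width-reduced regressor on 600 perturbed phantom samples
(128 total phantoms at 48 px) for 8 epochs and prints, e.g.:

```
held-out MSE       : 0.0796   (squared error of predicted IoU)
held-out accuracy  : 0.765   (accept/decline at t=0.6)
specificity        : 0.688   (true-accept rate)
sensitivity        : 0.817   (failure-detection rate)
MAE on failed cases: 0.212   (stratum with true IoU < 0.6)
```

(This quick demo is deliberately small; the full desk-scale study in
`scripts/acceptance.py` trains on 2000 samples for 15 epochs and reaches
markedly better numbers.)

The accuracy is the fraction of segmentations whose accept/decline call
matches the one the true IoU would give; sensitivity is the rate at
which truly failed segmentations (IoU < 0.6) are caught. Other examples
(`examples/*.py`) demonstrate phantom generation, the perturbation
procedure, the augmentation ramp and the loss landscape; each prints a
few numbers and a line on what they mean.

The same functionality is scriptable from a shell:

```bash
glottisqc generate --n 200 --out pairs --seed 1 --size 64
glottisqc perturb --manifest pairs/manifest.csv --out scored --seed 2 --samples-per-pair 4
glottisqc train --manifest scored/manifest.csv --loss-preset Balanced --epochs 15 \
    --width-multiplier 0.25 --out model.npz
glottisqc predict --checkpoint model.npz --frame pairs/frame_00000.png \
    --mask pairs/mask_00000.png
```

## Layout

| Module | Role |
| --- | --- |
| `glottisqc.phantom` | synthetic frame/ground-truth phantom generator |
| `glottisqc.metrics` | masks, IoU, confusion/ROC/interval metrics |
| `glottisqc.perturb` | six corruption operators + target-IoU procedure |
| `glottisqc.degrade` | augmentation ramp + pluggable/reference segmenter |
| `glottisqc.losses` | threshold-aware loss family and published presets |
| `glottisqc.model` | two-channel residual regressor, training, checkpoints |
| `glottisqc.evaluation` | reports, ablation grids, threshold sweeps |
| `glottisqc.studies` | canned desk-scale experiments over the pipeline |
| `glottisqc.nn` | minimal NumPy conv-net stack with explicit backprop |

See `docs/methods.md` for the scientific and numerical details.
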
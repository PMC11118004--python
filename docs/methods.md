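# Methods

This note documents the models, procedures and numerical choices behind
`glottisqc`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions were
made.

## 1. Task and conventions

Given a grayscale laryngoscopy frame `F ∈ [0,1]^{H×W}` and a candidate
binary segmentation `S` of the glottis, the package predicts the IoU of
`S` against the (unknown) ground truth `G`,

```
IoU(S, G) = |S ∩ G| / |S ∪ G| = TP / (TP + FP + FN),
```

and classifies the segmentation as accepted iff the predicted score is
at least the acceptance threshold `t = 0.6` (equality accepts).

Two limit conventions are fixed so closed-glottis frames have defined
labels: if both masks are empty the IoU is 1.0 (a correct "nothing to
segment" call); if exactly one is empty it is 0.0. IoU is volatile for
very small masks — a known limitation of overlap metrics, inherited
here.

The **positive class** of the accept/decline classifier is the *failed*
segmentation (true IoU < t). Sensitivity is therefore the
failure-detection rate and specificity the true-accept rate. This is a
documented package convention: the sensitivity/specificity orientation
is ambiguous in parts of the surrounding literature, and the task is
failure *detection*, which makes "failed" the natural event of interest.

## 2. Synthetic phantoms

The phantom generator produces frame/ground-truth pairs with the
structure that matters to quality assessment — co-variation of a dark,
roughly elliptical opening with its mask — and nothing more.

Geometry: the opening is a rotated super-ellipse (exponent uniform in
[1.7, 2.8], aspect ratio 0.2–0.5, near-vertical orientation ±20°) with
a low-amplitude radial perturbation (three sinusoids, amplitude ≤ 0.06).
The shape is deliberately *not* a plain ellipse, so the
ellipse-insertion corruption operator cannot trivially reproduce ground
truth. The shape scale is driven by bisection until the mask area
fraction falls inside `opening_area_range` (default 1–8 % of the image),
which is therefore guaranteed exactly for every non-empty mask. With
probability `closed_probability` (default 0.2) the glottis is closed:
the mask is empty and the frame shows only a thin dark fold seam.

Rendering: a bright fold corridor (default gray 0.55) around the
opening, a darker surround (0.72 × fold brightness), the opening at
gray 0.15, smoothed with a σ=1 Gaussian; plus smoothed-noise texture
(correlation length 8 px, amplitude 0.05) and i.i.d. Gaussian pixel
noise (σ = 0.03). Frames are quantized to the 8-bit grid at generation
time so PNG round trips are bit-exact.

What the phantoms do **not** model: anatomical detail, specular
highlights, motion blur, interlacing artifacts, color, or temporal
structure. Passing tests on phantoms therefore demonstrates that the
pipeline's machinery is correct and that the learning problem is
solvable when frame and mask co-vary as in real data — not that a model
trained on phantoms transfers to clinical recordings. For clinical use
the same code paths are run on real frame/mask manifests.

## 3. Perturbation procedure

Six operators corrupt a ground-truth mask; each emulates a
characteristic segmentation failure:

| operator | effect | area class |
| --- | --- | --- |
| rotate | shape kept, position implausible (about the centroid, NN resampling) | either |
| dilate | over-segmentation, smoothed contours (elliptical element, 3–9 px) | never decreases |
| erode | under-segmentation, irregular contours (3–9 px) | never increases |
| break | holes / missing fragments (1–4 random disks, radius 2–10 px) | never increases |
| copy | displaced, rescaled duplicate unioned in (offset 5–40 % of side, scale 0.5–1.5) | never decreases |
| ellipse | glottis-like spurious component (axes 4–16 % of side) | never decreases |

A target IoU is drawn by first picking one of six bins over [0, 1]
(default edges 0, .1, .3, .5, .7, .9, 1 with probabilities .10, .15,
.20, .30, .15, .10) and then sampling uniformly inside it. The default
bin weights put the most mass on borderline scores around the 0.6
threshold; empirically the achieved-score distribution has mean ≈ 0.51
and standard deviation ≈ 0.27, i.e. a borderline-focused corpus.

Each iteration visits the operators in random order, applies each with
its own Bernoulli probability `p` (defaults: rotate .3, dilate .5,
erode .5, break .4, copy .2, ellipse .2) to the *current* candidate, and
recomputes the IoU after every application. The loop stops when the IoU
is within `target_tolerance` (0.05) of the target; if it falls below
`target − tolerance` (perturbations are not invertible) the procedure
restarts from the pristine mask, up to `max_restarts` (5) times, after
which the state closest to the target wins. On an empty ground truth the
ellipse operator's selection probability is multiplied by
`ellipse_on_empty_boost` (4), emulating spurious segmentations of a
closed glottis; only IoU 0 or 1 is achievable there.

The stored label is **always the exactly recomputed IoU** of the
returned candidate, never the sampled target, so label integrity is
unconditional: overshoot and fallback only distort the *distribution*
of scores, never a label. Bin fidelity is asserted statistically: per
bin, the achieved-IoU count inside the tolerance-widened bin must be at
least `n·p − 3σ` and the count inside the tolerance-narrowed bin at most
`n·p + 3σ` (binomial σ). Distribution checks are run on non-empty
ground truths at the 256 px default grid, where operator granularity is
fine relative to the tolerance; at very small grids (≤ 48 px) single
morphological steps can move the IoU by more than the tolerance and the
achieved distribution spreads correspondingly.

## 4. Augmentation-ramp degradation

The second failure source feeds augmented frames to a pluggable
segmenter (any `frame -> mask` callable). Base ranges at `amp = 1`:
in-plane rotation ±10°, out-of-plane view rotations ±5°, gamma 80–120,
brightness ±20 %, contrast ±20 %, Gaussian noise variance 0.10–0.50 (on
[0,1] frames). Each range's deviation from its neutral point is scaled
linearly by `amp` and clipped to a physically sensible domain (gamma
exponent > 0, brightness shift capped at ±0.8, contrast factor kept
positive); `amp = 0` is a no-op. Two approximations are documented
choices: the out-of-plane rotations are rendered as small affine shears
(true 3-D camera geometry is not recoverable from 2-D frames), and the
linear scaling law about each neutral point is the simplest ramp
consistent with "multiply the intensity by `amp`".

The bundled `reference_segmenter` is deliberately weak: Gaussian smooth
(σ = 1.5), fixed absolute dark threshold (0.28), binary opening, largest
connected component, fill holes. Its fixed threshold makes it brittle
under brightness/gamma shifts — exactly the failure behavior to harvest.
On clean phantoms it reaches mean IoU ≈ 0.6; at `amp = 1` ≈ 0.2; at
`amp = 7` below 0.1. Candidate masks are labeled against the *clean*
ground truth and stored with the *clean* frame: only segmentations vary
across the corpus, so a quality model cannot extract novel glottis
appearance from the failure data.

## 5. Losses

With `y` the true IoU, `ŷ` the raw prediction and batch-mean reduction:

```
Loss_bn(y, ŷ) = mean_i[ max(0, ŷi−t)·max(0, t−yi) + max(0, t−ŷi)·max(0, yi−t) ]
Loss_ft(y, ŷ) = mean_i[ max(0, t−yi) · |ŷi − yi| ]
Loss          = λ0·MSE + (1−λ0)·( λ1·Loss_bn + (1−λ1)·Loss_ft )
```

`Loss_bn` is zero exactly when every sample's prediction is on the
correct side of `t` (boundary values contribute zero through the
`max(0,·)` factors); `Loss_ft` is zero exactly when all `y ≥ t`. The
`|ŷ−y|` factor is the per-sample absolute error, so the gated mean is
taken once — the only reading under which the loss surface over
`(y, ŷ)` is well defined pointwise. Mixture weights are applied after
reduction. Predictions are *not* clamped inside the loss (clamping
would zero gradients); scores are clamped to [0, 1] at reporting time
only. Analytic subgradients are used at the kinks `ŷ = t` and `ŷ = y`,
taking the one-sided derivative from the zero region.

`preset_grid()` exposes the ten published (λ0, λ1) settings under their
published labels. One caveat is deliberately preserved: in the mixture
formula λ1 weights `Loss_bn`, so the label "Only Lossf" (λ0=0, λ1=1)
resolves to the pure boundary term under the formula as printed. The
pairs are reproduced verbatim; code that needs a term *by meaning*
should construct `LossParams` directly (as the loss-shaping study does:
fidelity-weighted = (0.25, 0), boundary-only = (0, 1)).

## 6. Quality model and training

Architecture: an 18-layer residual regressor — 7×7/stride-2 stem,
batch norm, ReLU, 3×3/stride-2 max pool, four stages of two basic
blocks with widths 64/128/256/512 × `width_multiplier` (projection
shortcuts on downsampling), global average pooling, one linear output,
no output activation. Input is `(2, H, W)`: the frame and the candidate
mask as a {0, 1} float channel. The stack is implemented directly on
NumPy (im2col convolutions, explicit backward passes, float32
throughout), which keeps the package dependency-light and the
arithmetic deterministic on CPU.

Training: Adam (β1 0.9, β2 0.999), learning rate 1e-4 under a
triangular cyclic scheduler (base 1e-5, peak = the configured rate,
cycle 4 epochs — the bounds are a package choice, configurable), batch
size 18, Kaiming fan-in initialization, gradient clipping at global
norm 1, light augmentation (joint flips and ±15° rotations on both
channels; gamma/brightness/contrast/noise on the frame only — geometric
transforms are applied jointly precisely so the IoU label stays valid
up to raster error). Model selection is by lowest validation MSE on a
split carved from the *training* data (15 % by default): selecting on
the test set, as is sometimes done, leaks test information, so this
package deliberately does not. Early stopping: from epoch 20 on, stop
once the best validation model is more than 10 epochs old. Non-finite
losses abort with epoch/batch context. Runs are deterministic under a
fixed seed (data order, augmentation draws, initialization); the only
caveat would be a nondeterministic BLAS, which does not affect the
single-threaded reductions used here.

Desk-scale defaults used by the studies and the acceptance script:
48 px phantoms, `width_multiplier = 0.25` (~0.7 M parameters),
2000/500 train/test samples, 15 epochs — sized so one training run
completes in about two minutes on one CPU core while still reaching
held-out MSE ≈ 0.03 and accuracy ≈ 0.85 at `t = 0.6`. A full-scale
clinical replication would instead use 256 px inputs,
`width_multiplier = 1`, and ~10^5-frame corpora.

## 7. Evaluation battery

`evaluate` reports MSE/MAE, accuracy, specificity and sensitivity at
the acceptance threshold, ROC points (one per inference threshold on a
101-point grid; declaring "failed" when the score falls below the
inference threshold, so TPR and FPR are non-decreasing along the grid;
undefined rates are NaN, never silent zeros) and per-interval MAE /
accuracy over true-IoU bins (deciles by default — the interval binning
is a package choice). `threshold_sweep_plot_data` traces accuracy over
inference thresholds, always including the target threshold, to check
whether the best inference threshold aligns with it.
`ablation_run` trains one model per (loss setting, data source) cell —
sources: `model_failures`, `procedure`, and `both` (their
concatenation) — on a shared corpus with shared seeds and returns a
table sorted by accuracy descending. Stratified evaluation, where used,
augments a test set with procedure samples toward uniform per-bin
counts.

## 8. Known limitations

* IoU is the sole quality metric; boundary- and region-aware metrics,
  error localization, and learned quality metrics are out of scope.
* Phantom realism is intentionally minimal (see §2); results on
  phantoms bound the machinery, not clinical transfer.
* The perturbation operators' parameter ranges are package defaults
  spanning mild-to-severe corruption; all are configurable.
* At very small grids the morphological step size limits how precisely
  a target IoU can be hit; labels remain exact regardless.
* The reference segmenter is a deliberately weak baseline, not a
  clinically meaningful one; plug in a trained network for realistic
  failure harvesting.
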
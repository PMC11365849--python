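# Methods

## The pipeline

`sinussl` implements a four-stage, label-efficient training scheme for
classifying maxillary-sinus (MS) volumes as normal or anomalous:

1. **Unsupervised anomaly detection (UAD).** A 3D convolutional autoencoder
   `A(·)` is trained with mean per-voxel L1 loss to reconstruct *normal* MS
   volumes only (no augmentation). Because the autoencoder never sees
   lesions, it reconstructs the typical normal anatomy and fails on
   anomalous structure.
2. **Residual generation.** For every volume `x` in an unlabelled pool, the
   residual `r = |x − A(x)|` is computed voxel-wise. Since `x` and `A(x)`
   both live in [0, 1] (inputs are min–max normalized, the decoder ends in a
   sigmoid), `r ∈ [0, 1]` as well. An optional 3D median filter (default
   kernel 5, reflect borders) removes speckle. The filtered residual acts as
   a *pseudo segmentation mask*: high values concentrate where the volume
   deviates from normal anatomy.
3. **Self-supervised pretraining (SSL).** A U-Net-style network — a
   ResNet18-type 3D encoder `E(·)` (four downsampling stages, basic blocks,
   channel widths 64/128/256/512 scaled by a width factor) and a mirrored
   decoder `D(·)` with trilinear upsampling and skip connections — is
   trained to predict each volume's residual from the volume itself, with
   binary cross-entropy on the soft targets. The encoder is thereby forced
   to learn features that *localize* anomalies without any human labels.
4. **Fine-tuning.** The decoder is discarded; `E(·)` plus a fresh MLP head
   (global average pooling → hidden → 2 logits) is trained end-to-end with
   cross-entropy on a class-stratified fraction of the labelled training
   set. The checkpoint with the lowest validation loss is kept. Metrics are
   AUROC, average precision (AUPRC, anomalous class positive) and F1 at the
   argmax threshold, aggregated over folds as mean ± Student-t 95% CI.

The package also ships the surrounding plumbing: centroid-based cube
extraction from cranial volumes, lateral flipping of right-side volumes,
per-volume [0, 1] normalization, patient-grouped stratified K-fold
splitting, and nested label-fraction subsampling.

## Network stack

No GPU tensor library is used: the layers (3D convolution, batch
normalization, leaky ReLU, trilinear upsampling, linear, global average
pooling) are implemented directly on numpy with hand-written backward
passes (`sinussl.nn`). Convolution iterates over the k³ kernel offsets,
each contributing one BLAS tensordot of a strided input view with a
(C_in, C_out) weight slice; the backward pass applies the adjoint scatter.
Trilinear upsampling is realized as separable 1D interpolation matrices, so
its backward pass is the exact transpose. Every layer passes
finite-difference gradient checks at double precision (`tests/test_networks.py`);
training runs in float32, which keeps the memory-bound convolution passes
fast on one CPU. Optimizers: Adam, AdamW (decoupled weight decay), SGD with
momentum, and a layerwise-adaptive (LARS-style) wrapper used for
large-batch pretraining; the warmup-plus-cosine learning-rate schedule is a
closed-form function of the epoch.

Determinism: all parameter initialization, shuffling, augmentation and
phantom synthesis flow from explicit `numpy.random.Generator` seeds; two
runs with the same root seed produce byte-identical result tables.

## Synthetic phantoms

Real cohort data cannot ship with the package, so every stage is exercised
on 3D sinus phantoms: a cube of bright soft tissue (intensity 0.65), a
roughly ellipsoidal dark air cavity (0.05) whose centre and semi-axes are
jittered ±6% per draw, a thin mucosal lining shell (0.45, thickness 1.5
voxels), and clipped additive Gaussian noise (σ = 0.03). Anomalous phantoms
add one lesion: a bright blob (0.85) attached to the cavity wall and
protruding inward (polyp/cyst-like, radius 12–18% of the cube edge), or a
locally thickened lining (an inward shell over one cap of the cavity).
Ground-truth lesion masks are retained, hidden from the models, and used
only for evaluation. Geometry and noise are pure functions of the seed:
the anomalous phantom of a seed equals the normal phantom of that seed
outside the lesion voxels.

What the phantoms emulate: the normal/anomalous contrast mechanism the
residual pipeline exploits — an anomaly is a localized intensity structure
inside or at the cavity. What they do not emulate: FLAIR contrast physics,
anatomical variability of real sinuses, multi-lesion volumes, registration
artifacts, or clinically calibrated lesion-size distributions. Passing the
synthetic benchmark therefore demonstrates that the pipeline's mechanics
work (residuals localize lesions; residual-predicting features transfer),
not that clinical performance figures would be reproduced.

## Scale profiles

The `full` profile holds the full-scale training conditions (64³ volumes;
autoencoder bottleneck 512; encoder widths 64–512; SSL via
layerwise-adaptive optimization at peak LR 0.2, 500 epochs, 20-epoch linear
warmup then cosine decay, batch 256; fine-tuning with AdamW at constant
1e-4, 100 epochs, batch 16; fivefold CV). It is not runnable in minutes on
a CPU and exists as the documented configuration target.

The `desk` profile is the package's own scaled-down study, used by the test
suite and the reproduction script:

| knob | desk value | rationale |
|---|---|---|
| phantom edge | 16 voxels (32 for the UAD study) | CPU minutes budget |
| autoencoder | stages (16, 32, 64), latent 128 at 16³; (8, 16, 32, 32), latent 64 at 32³ | preserves the full-scale 16× edge compression (64³ → 4³) |
| encoder width factor | 1/8 (widths 8/16/32/64) | parameter count scales with the volume |
| SSL | BCE, 18 epochs, warmup 2, peak 1e-3, batch 8, Adam | at batch ≤ 8 the layerwise-adaptive optimizer is unstable, so the Adam-family fallback is the desk default |
| fine-tune | 30 epochs, AdamW 1e-3, batch 8, hidden 64 | constant-rate policy kept; rate raised because desk runs take ~100× fewer steps |
| labelled / unlabelled pool | 100 + 100 / 80 (anomaly rate 0.5) | smallest sizes at which the paired contrasts are stable |
| residual median kernel | 5 | same post-processing at both scales |

Choices that mattered and why:

* **Compression ratio, not stage count, is preserved.** A four-stage
  autoencoder at 16³ collapses the bottleneck to 1³, over-compressing so
  heavily that training-set size no longer influences residual quality; at
  three stages the 16³ phantom study reproduces the expected ordering
  (residual separation AUROC ≈ 0.99 with the full normal pool vs ≈ 0.9 with
  20% of it).
* **Median kernel 5 in the residual stage.** With weaker smoothing the
  residuals of a *poorly* trained autoencoder retain input structure and act
  as a generic autoencoding target, which is itself a useful pretext task —
  masking the benefit of a better normal model. The kernel-5 filter removes
  that speckle so the lesion-localization signal dominates, which is the
  mechanism the pipeline is built on.
* **Augmentation during fine-tuning is load-bearing at desk scale.** With
  ≤ 10 labelled training volumes and batch normalization, the random
  affine/flip/noise policy (each applied with probability 0.5) is the
  difference between memorization and generalization.

## Numerical and design details

* **Residual definition**: absolute difference, no thresholding and no
  renormalization before SSL (values are already valid BCE targets;
  renormalizing would amplify noise on near-perfect reconstructions).
* **BCE on soft targets**: predictions pass through a sigmoid; inputs to
  the log are clamped to [1e-7, 1 − 1e-7], with the clamp excluded from the
  gradient.
* **Normalization edge case**: a constant volume min–max-normalizes to all
  zeros rather than dividing by zero.
* **Crop semantics**: half-open, 0-based cube `[c − e/2, c + e/2)` per
  axis; a crop that exceeds the cranial grid raises instead of padding or
  clamping, because silently shifted anatomy would corrupt the normal model.
* **Laterality**: "horizontal" flip is axis 0 of the cube by convention;
  the axis is an argument for data in other orientations.
* **Patient grouping**: a patient is stratified as anomalous if any of
  their MS volumes is anomalous; all volumes of a patient land in exactly
  one of train/validation/test, asserted on every split.
* **Label-fraction subsetting**: per class, volumes are grouped by patient,
  patients are drawn in a seeded random order, and exactly
  round-half-up(fraction · n_class) volumes are taken as a prefix — so
  subsets are *nested* across fractions for a fixed seed, which lowers the
  variance of learning-curve sweeps.
* **Ties in AUROC** count one half; AUPRC is step-wise average precision
  without interpolation; F1 is computed on the anomalous class at the
  argmax of the two logits.
* **CI method**: mean ± t(n−1, 0.975) · sd/√n over folds, recorded as
  `student_t` in the output metadata.
* **SSL checkpointing**: 10% of the pairs are held out and the parameters
  with the lowest held-out loss are returned, mirroring the
  lowest-validation-loss selection used in fine-tuning.
* **Median filter borders**: edge-repeating reflection, so dark frame
  artifacts cannot become spurious SSL targets.
* **Provenance**: every model state carries
  `random_init → cae_trained → ssl_pretrained → finetuned`, and stage
  functions refuse inputs at the wrong stage; checkpoints embed config,
  provenance and training history in a versioned single-file format.

## Known limitations

* The numpy layer stack is single-threaded BLAS-bound; the `full` profile
  is documented but not practical without a GPU tensor library backend.
* Phantom simplicity caps how far conclusions transfer: the classification
  task is intrinsically easier than clinical MS anomaly grading, so
  absolute metric values on phantoms exceed what the method reports on
  cohort data and should not be compared to them.
* The CAE-fraction ablation's downstream effect is small relative to
  seed noise at desk scale; it is assessed as a three-seed mean (the
  residual-quality ordering it rests on is large and consistent).
* Batch normalization statistics are computed per training batch; at batch
  size 1 the conv-layer statistics remain well-defined (they pool over
  voxels) but classification heads should use batch size ≥ 2.
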
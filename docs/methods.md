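# Methods

## The problem

Image-based cytometry profiles cells by their label-free morphology:
bright-field (BF) intensity and quantitative phase (QPI, proportional to
dry-mass density).  Data acquired in different sessions carry *batch
effects* — laser-power drift, photodetection noise, defocus, microfluidic
distortion — that confound biological signal and break integrated analysis
across acquisition days.  This package implements a batch-aware generative
profiling method: a conditional GAN translates BF images into QPI while a
*morphology distillator* — a set of frozen batch and cell-type classifiers
acting on the network's 1-D bottleneck profile and on its output image —
steers training so batch information is removed and biological information
preserved.

## Model

**Backbone.** The generator is an encoder–bottleneck–decoder network.  The
encoder stacks stride-2 convolutions (kernel 4, batch norm from the second
level, leaky rectifier); a dense layer condenses the final feature map into
a 1-D bottleneck vector — the *morphological profile* (default 256
dimensions; the desk-scale studies here use 64).  A dense layer and
transposed convolutions reconstruct and contrast-translate the image, with
optional skip concatenations from encoder levels above the bottleneck
resolution (the bottleneck-resolution skip is omitted so the profile cannot
be bypassed wholesale; the skips that remain are exactly why image-level
classifiers are also needed).  A patch-level discriminator on (BF,
candidate-QPI) pairs provides the adversarial term.  In autoencoder mode the
target equals the input and no contrast translation is learned.

**Pre-training.** The generator objective is
`W_gen * MSE(prediction, target) + W_dis * BCE(D(fake), real)` with
`W_gen : W_dis = 100 : 1` (the reconstruction term is mean-square error;
the 100:1 ratio follows the convention for this architecture family).  The
discriminator minimizes the usual real/fake binary cross-entropy.  The
profiles and images of this stage are the *no-CytoMAD* stage.

**Distillation.**  Four classifier groups are pre-trained on the
no-CytoMAD profiles/images and then frozen:

* M mini batch-classifiers over equal contiguous segments of the profile
  (default M = 4), dense 75/50/25 with rectifier and softmax;
* one cell-type classifier over the full profile (same architecture);
* convolutional batch and cell-type classifiers on the output image
  (5 blocks of convolution + batch norm + leaky rectifier + max-pool).

Further generator training minimizes

```
L_total = L_GAN + L_cnn + L_nn
L_GAN   = W_gen*L_gen  + W_dis*L_dis
L_cnn   = W_Bcnn*L_Bcnn + W_Ccnn*L_Ccnn    (image-level classifiers)
L_nn    = W_Bnn*L_Bnn  + W_Cnn*L_Cnn       (bottleneck classifiers)
```

The type terms (`L_Ccnn`, `L_Cnn`) are cross-entropies against the true
labels; the batch terms are, by default, **confusion losses**: the
cross-entropy of the frozen batch classifier's output against the uniform
distribution over K batches, `-(1/K) * sum_k log p_k`.  This choice keeps
every weight nonnegative and the composite literally a weighted sum; it is
bounded below by `ln K` and minimized exactly when the classifier cannot
tell batches apart.  How the batch terms enter the published composite is
not derivable from the loss equations alone, so a gradient-reversal-style
alternative (`batch_loss="negated"`, negated cross-entropy against the true
batch) is provided; neither option is asserted to be the original authors'.

Only generator and discriminator parameters are updated; the classifier
parameters are frozen (audited by SHA-256 hashes in the test suite).  Every
`retrain_interval_epochs` the *batch* classifiers (minis and image-level)
are re-fitted on the current generator outputs — warm-started from their
existing parameters for a small budget (default 20 epochs) — and re-frozen.
Type classifiers are never retrained.  Weak labels (e.g. sample origin,
tumor-biopsy versus blood) are ordinary metadata columns, so the two-stage
strategy for heterogeneous samples — distill on an auxiliary weak-label
task, checkpoint, continue on the downstream label set — needs no special
types; the CLI exposes it via `--type-column` plus checkpointing.

**Default weights.** `W_gen=100, W_dis=1, W_Bnn=20, W_Cnn=5,
W_Bcnn=W_Ccnn=2`.  The bottleneck batch-confusion term carries the heaviest
classifier weight because its gradient vanishes as the frozen classifiers
become confused — without the extra weight and frequent adversary refreshes
the generator fools the frozen classifiers while leaving batch information
linearly recoverable by a freshly trained one.  The image-level terms stay
light: when the translation targets are the clean (pre-photometric) QPI,
the output images retain little batch signal, and a heavy image-level
confusion term buys little batch removal at a large cost in reconstruction
fidelity.  For the same vanishing-gradient reason the desk-scale studies
refit the batch classifiers every epoch; with long training and large data
the published every-10-epochs schedule is the default.

## Neural-network layer

All networks run on a small in-package numpy toolkit (`cytomad.nn`):
reverse-mode autodiff tensors with the conv/transposed-conv/dense/batch-norm
operations these architectures need, Adam (lr 2e-4, beta1 0.5), fused
numerically-stable losses.  Everything is float32, CPU-only, and exactly
reproducible for a fixed seed within a platform: every stochastic component
(parameter init, minibatch order, noise draws) takes a seeded generator and
nothing touches an unseeded global state.  Gradients of every operation are
verified against central differences in the test suite.

## Synthetic data

The generator emulates what a multi-modal imaging flow cytometer yields at
the single-cell level, not the instrument itself:

* **QPI**: a parabolic elliptical dry-mass-density cap (`peak_phase` at the
  center, 0 at the boundary) plus a Gaussian-random-field texture (white
  noise blurred to a stated correlation length), clipped to [0, 1],
  background exactly 0.
* **BF**: the deterministic attenuation map `1 - 0.9*QPI` with mild
  smoothing — so BF→QPI is a well-posed, learnable mapping at desk scale.
* **Batch effects**, applied per acquisition batch:
  `clip(gain * blur(shear(x)) + offset + stripes + noise, 0, 1)` — gain and
  offset model illumination drift, Gaussian `psf_sigma` blur models defocus,
  additive Gaussian noise models photodetection noise, sinusoidal stripes
  model high-spatial-frequency pickup, and a shear warp models microfluidic
  image distortion.  The mask is warped by the same geometric transform.
* **Translation targets**: by default the *pre-photometric* QPI (geometric
  warp retained) is stored per cell, giving the backbone a well-defined
  batch-invariant target; `target="distorted"` switches to the observed QPI
  (on a real instrument the ground-truth QPI itself carries batch
  character).
* **Marker labels** (e.g. EpCAM+/EpCAM+Vim+/EpCAM-Vim-) are drawn from
  type-conditional probabilities, emulating fluorescence-gated ground truth
  without simulating fluorescence.

Reference study conditions (`default_sim_config`): two cell types that
differ in size (radius 7 vs 11 px), peak phase (0.50 vs 0.75) and texture,
imaged in three batches — one near-clean, two with opposite gain/offset
drifts (1.15/+0.08 and 0.85/−0.06), defocus blur (0.8 and 1.2 px), noise
(0.02/0.03), small shear (±0.05) and faint stripes.  Images are 32 px for
the studies, 64 px for the translation benchmark; real instruments resolve
a 45 µm field at higher pixel counts, which only scales compute.

What the generator does **not** model: organelle-level structure, optics of
time-stretch imaging, phase retrieval, cell-cycle or density-dependent
morphology correlations, intra-batch drift.  Passing tests therefore show
that the machinery behaves as specified under controlled, injectable batch
effects — not that any particular accuracy transfers to instrument data.

## QC

Segmentation: Otsu threshold, foreground polarity chosen as the side with
the higher mean absolute deviation from the image-border median,
morphological closing (radius 2), hole filling, largest connected
component.  Focus factors per channel over mask pixels: gradient energy
(mean squared Sobel magnitude), Laplacian variance, masked intensity
variance, 64-bin masked entropy (bits), mask area.  Gates are absolute or
percentile bounds; percentiles are resolved once on the dataset being
gated, making gating idempotent under the resolved absolute bounds.

## Biophysical features

An 84-entry registry in three tiers: bulk (mask geometry and integrated
quantities — area, circularity `4*pi*A/P^2`, dry mass = integrated phase x
calibration, ...), global (masked-intensity statistics per channel, radial
mass distribution, intensity-weighted centroid displacement normalized by
the equivalent radius), and local (statistics of derived texture maps:
64-level local-entropy map with a radius-3 disk, a multi-scale
second-derivative ridge/fiber map, the residual of a 2nd-order polynomial
surface fit within the mask ("fit texture"), gradient-magnitude maps, and
masked gray-level co-occurrence contrast at pixel offsets 1–4 on 32 absolute
gray levels — `DMDContrast1..4` on QPI).  Co-occurrence contrast is computed
in-package because only pixel pairs entirely inside the mask may contribute;
off-the-shelf implementations cannot mask pairs.  The exact formulas of the
named texture features are repo definitions behind a `formula_id`
indirection, so a different catalog convention can be swapped in without API
changes.  Calibration defaults to 1.0 (normalized units); a physical
phase-to-mass constant gives dry mass in pg.

Orientation is reported with an `undefined` flag when eccentricity < 0.05.
Zero-variance inputs yield 0 for skewness/kurtosis and contrast rather than
NaN.

## Evaluation

* **Cell-region SSIM**: per-pixel SSIM map (11x11 Gaussian window, sigma
  1.5, K1=0.01, K2=0.03, dynamic range 1, population covariance), averaged
  over mask pixels; a `global` mode evaluates the formula once on the
  masked population.  **Cell-region RMSE**: root-mean-square error over
  mask pixels.
* **Batch distance**: per-feature absolute difference of batch means; for
  more than two batches, the mean over unordered batch pairs.
  **Correction ratio**: `(before - after)/before`; 0 with an `undefined`
  flag when `before < 1e-12`; always at most 1.
* **Hold-out-batch classification**: train the stated classifier (dense
  75/50/25 for vectors, 5-block CNN for images, 100 epochs by default) on
  selected batches only, evaluate on every cell of the unseen batches.
* **Cohen's d** with the pooled ddof-1 standard deviation; **subpopulation
  z-scores** against overall mean/SD.
* **Sample-level AUC**: cell profiles ensemble-averaged per sample,
  logistic regression; the point estimate is the leave-one-sample-out ROC
  AUC and the bootstrap (default 1000 draws) resamples samples with
  replacement, scoring out-of-bag samples, so chance labels honestly give
  ~0.5.  Single-class draws are redrawn, counted and capped.
* **2-D embedding** delegates to UMAP; since visual batch mixing is not
  assertable, a quantitative companion — mean fraction of each point's 15
  nearest embedded neighbors sharing its batch — accompanies it.

## Desk-scale study sizes

The reference studies use 40 cells per type per batch at 32 px for the
distillation study (15 pre-training + 30 distillation epochs, adversary
refit every 3 epochs, classifiers trained 30 epochs), ~250 pairs at 64 px
and 20 epochs for the translation benchmark, and 100 cells per type per
batch for the end-to-end demo.  These sizes were chosen so the whole suite
runs on one CPU core in minutes while every directional effect (MSE
decrease, SSIM gain over an untrained model, batch-accuracy drop, positive
photometric correction ratio, preserved within-batch type accuracy) has
margin.

## Known limitations

* At desk scale the distillation outcome depends on initialization and data
  draw: the composite objective trades reconstruction fidelity against
  batch confusion, and the measured batch-classifier accuracy drop varies
  with seed.  The packaged study conditions and schedules give a consistent
  direction; cherry-picking is avoided by fixing all seeds in tests and in
  the acceptance script.
* SSIM on translated images is modest at these tiny training budgets; the
  published instrument-scale figures (~0.93–0.95 after GPU-scale training
  on >10^5 cells) are not reproducible at this scale and are not targets of
  the test suite.
* The confusion-vs-negated batch-loss choice is a documented open question,
  not a claim about the original implementation.
* The synthetic BF↔QPI relation is far simpler than real contrast physics;
  translation difficulty is correspondingly lower.
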
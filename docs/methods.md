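# Methods

## Problem setting

Two OCT volume-scan presets image the same anatomy with different
quality/coverage trade-offs. The *Macular Cube* preset averages 9 repeated
B-scans per tomogram over a 20°×20° patch (25 slices); the *Seven Lines*
preset averages 25 B-scans over a 30°×5° strip (7 slices). More averaging
suppresses speckle — the dominant quality factor in coherent imaging — so
the presets differ visually although the tissue is the same. The package
learns the mapping between the two visual styles from *unpaired* sets of
B-scans, in both directions, and validates the conversions with
referenceless quality metrics and a separability experiment.

## Speckle phantom model

Clinical data of this kind is typically private, so the package ships a
generator whose outputs carry the statistics that matter to the method:

* **Anatomy**: a stack of smooth layer interfaces (sinusoid perturbations on
  a tilted/curved quadratic base), strictly ordered in depth, with constant
  mean backscatter per layer, brightest bands mid-depth as in retinal
  cross-sections. The region above the first interface is a dark,
  tissue-free background (vitreous analogue). No pathology, motion or
  vendor post-processing is modelled.
* **Speckle**: fully developed speckle, i.e. per-look intensity =
  reflectivity × i.i.d. unit-mean exponential noise. An L-look image is the
  per-pixel mean of L independent looks, so a homogeneous region has
  `ENL = mean²/variance = L` before any compression. This is the standard
  coherent-imaging intensity model; the source setting names speckle and the
  look counts but no noise law, so the canonical one is used.
* **Log compression** (display realism): `y = log(1 + 50·I) / log(1 + 50)`,
  applied after averaging, default on. ENL calibration is always checked on
  pre-compression intensities, where `ENL = L` holds exactly.
* **Intensity range**: images are normalised to [0, 1]; 8-bit grayscale PNG
  on disk with a CSV manifest (path, preset, provenance, seed, auto-derived
  ROI/background rectangles) and a JSON mirror.

Default preset profiles: `macular_cube` = 9 looks, 25 slices, 20°×20°;
`seven_lines` = 25 looks, 7 slices, 30°×5°. Slice counts and field angles
are metadata only; all computation acts on single B-scans. Datasets are
unpaired by default (independent anatomies per preset); a paired mode exists
for controlled comparisons only.

What passing tests on phantoms does *not* show: fidelity to real retinal
texture, pathology robustness, or scanner-specific artefacts. The phantoms
isolate exactly one axis — speckle statistics as a function of look count —
plus enough anatomical structure for the contrastive loss to anchor on.

## Translation model

The generator is a residual encoder–decoder: stem convolution → two
stride-2 downsampling stages → n residual blocks (encoder) → two
nearest-upsample+conv stages → output convolution with tanh head (decoder);
instance normalisation throughout; images enter in [0, 1] and are internally
rescaled to [−1, 1]. Encoder layers are indexed atomically from the input
(0 = input), so taps {0, 4, 8, 12, 16} address the input, the first and
second downsampling stages and two residual blocks of the 9-block backbone.
The discriminator is a 3-stage patch critic (16-px receptive field).

Losses:

* Adversarial: the minimax value function
  `E log D(y) + E log(1 − D(G(x)))` with the non-saturating generator form,
  or — the default — its least-squares variant with targets 1/0. The
  least-squares form is the conventional, more stable choice for this
  architecture family; the logarithmic form is implemented literally and
  exercised by the loss unit tests.
* Patchwise contrastive: per tap and per sampled location, a two-layer MLP
  head projects the feature column to an embedding (unit-normalised — at
  τ = 0.07 the softmax is only meaningful on unit vectors); the query from
  the translated image is classified against the same-location positive and
  the other S−1 locations of the same original image ((N+1)-way
  cross-entropy with log-sum-exp stabilisation). Negatives are internal to
  the image; no external negative bank.
* Generator objective: `L_GAN + 0.5·(λ_X·NCE + λ_Y·NCE_Y)` with
  λ_X = λ_Y = 1; the `NCE_Y` term runs target-class images through G as an
  identity-style regulariser.

Training (full scale): Adam(β₁ = 0.5, β₂ = 0.999), lr 2e-4 constant for 200
epochs then linearly decayed to 0 at epoch 400; inputs resized to 286 and
randomly cropped to 256 with horizontal flips; checkpoints every 20 epochs
(20 in total); per-epoch means of the six loss series (G_GAN, D_real,
D_fake, G, NCE, NCE_Y) logged to CSV. One master seed fans out to
initialisation, shuffling, cropping and patch sampling; a non-finite loss
aborts with a diagnostic.

Desk scale (`TrainingConfig.desk`): 64×64 phantoms, width-16 generator with
3 residual blocks and a 3×3 stem, taps (0, 4, 8, 10, 12) — the indices 12/16
of the 9-block backbone do not exist at 3 blocks, so the two res-block taps
that do exist are used — embedding dim 64, 64 patches/layer, batch 1 (as in
the full-scale recipe; at this scale the added optimiser updates per epoch
matter for convergence), a width-32 patch critic (a weaker critic stops
resolving speckle statistics and lets the noisy-preset generator converge to
over-smooth backgrounds), and 12 epochs with checkpoints every 2. These
sizes form a single-CPU working point; they reproduce the *direction* of the
published effects, not their magnitude.

Conversion pads arbitrary input sizes by reflection to the generator's
stride multiple (4) and crops back; outputs are clipped to [0, 1] and tagged
`provenance=synthetic` with the target preset. Inputs below 16 px per side
are rejected.

## Quality assessment and checkpoint selection

* `ENL = x̄²_BG / s²_BG` and `CNR = (x̄_ROI − x̄_BG) / s_BG`, both with the
  n−1 variance denominator (the convention is recorded so results are
  bit-reproducible). Constant regions raise explicit undefined-metric
  errors. ENL/CNR are invariant to positive rescaling, CNR also to offsets.
* NSS score: the 36-feature vector of the BRISQUE family — generalised
  Gaussian fit (shape, variance) of the MSCN coefficients plus asymmetric
  generalised Gaussian fits (shape, mean, left/right variance) of four
  orientation pairwise products, at two scales. MSCN uses a 7×7 Gaussian
  window (σ = 7/6) and C = 1/255 on [0, 1] images; GGD/AGGD shapes are
  moment-matched on an α-grid [0.2, 10] with step 0.001. The feature-to-score
  regressor is pluggable; the shipped default is a **synthetic** linear
  ridge regression trained at run time on phantom images with graded look
  counts, targeting `100/√looks` so that lower = better. A linear model is
  used because checkpoint-generated images can fall outside the training
  feature distribution, where kernel regressors collapse to a constant while
  a linear one remains monotone in the speckle-sensitive features. It ranks
  speckle-driven quality only and is not a substitute for perceptual scores
  on natural images.
* Checkpoint selection: every checkpoint converts a probe set, the mean
  score per checkpoint forms a table, and the selected epoch is the argmin
  (`lowest`, clean-preset-generating model) or argmax (`highest`,
  noisy-preset-generating model), ties to the earliest epoch.
* Distribution summaries report sample mean, sample sd and adjusted
  Fisher–Pearson skewness (0 for constant samples by convention).

## Separability experiment

A preset classifier is trained on original images only: 60/20/20 split with
val = ⌊0.2n⌋, test = ⌊0.2n⌋, remainder to train (1034 → 622/206/206),
classes balanced within each split to ≤1 image by largest-remainder
allocation; per-image min-max normalisation; horizontal flips as the only
augmentation; weights taken from the epoch with minimal validation loss
(full curves retained). The default backbone is a ~6k-parameter 3-stage CNN
trained on the package's own engine — the experiment's logic, not backbone
capacity, is under test, and the 9-vs-25-look contrast is separable nearly
perfectly at this size. Converted images are then classified; the report
carries the fraction assigned to the target preset and confusion counts
(positives = target class; the synthetic design has no TN/FP, so
specificity is undefined).

## Numerical and engineering choices

* All networks run on `octpt.nn`, a reverse-mode autodiff engine over NumPy:
  conv2d as im2col + BLAS matmul with a hand-written backward, nearest
  upsampling, instance norm composed from primitives, Adam with bias
  correction. Gradients are verified against central differences in the test
  suite. Training switches the engine to float32 for throughput; analysis
  paths default to float64.
* Determinism: every stochastic step derives from `numpy.random.default_rng`
  seeded from one master seed; identical configs and seeds reproduce
  byte-identical manifests (timings are written to a separate file).
* Degenerate inputs fail loudly: crossing layer boundaries, non-positive
  reflectivities, out-of-range pixels, constant regions (ENL/CNR/NSS),
  vanilla-mode scores outside (0, 1), empty image sets, too-small images,
  oversubscribed patch sampling.

## Known limitations

* The phantom reflects speckle statistics, not retinal texture; quality and
  separability results on phantoms bound what the pipeline can show about
  clinical images.
* The desk-scale GAN is far below the published capacity/schedule; only the
  sign of the ENL shift and above-chance target-preset classification are
  asserted, not published accuracies or score distributions.
* The synthetic NSS scorer orders speckle severity; BIQI/NIQE and
  pretrained perceptual scorers are out of scope.
* Single-channel 2-D B-scans only; no DICOM handling, no volume context.
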
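# Methods

## Problem and model

Crop mapping is treated as per-pixel semantic segmentation of a single-date
multispectral reflectance raster into three crop classes (corn = 0,
rice = 1, soybean = 2) with −1 marking unlabeled pixels. The model input is
not the raw 10-band stack but a 3-channel raster derived from it:
12 spectral features (the 10 bands plus NDVI and EVI, with NIR taken from
band 8, red from band 4 and blue from band 2) are z-scored per feature over
all pixels, projected onto their first three principal components, and
min–max scaled per channel to [0, 1].

The network is an encoder–decoder:

- **Backbone.** A ResNet-style trunk: a 7×7/2 convolution to 64 channels
  plus a 3×3/2 max-pool (stage 0), then three stages of basic two-conv
  residual blocks at 64, 128 and 256 channels with strides 1, 2, 2. Two tap
  points feed the decoder: stage 0's output (1/4 resolution, 64 channels)
  and stage 3's output (1/16 resolution, 256 channels). For a 256×256×3
  input these are 64×64×64 and 16×16×256. The channel plan is fixed by
  those published tap shapes rather than by any stock ResNet50 layout
  (whose 1/16-resolution stage would be 1024-wide); the trunk is therefore
  described as ResNet-style, not as ResNet50. The `full` preset uses
  (3, 4, 6) blocks per stage; `reduced` halves them to (2, 2, 3) for
  desk-scale training while preserving both tap shapes.
- **Receptive-field block (RFB).** Four branches over the high-level tap:
  (1) an identity shortcut projected by a 1×1 convolution to the fusion
  width; (2) a 3×3 convolution followed by a dilated 3×3 at rate 1;
  (3, 4) two 3×3 convolutions followed by dilated 3×3 at rates 3 and 5.
  Branches 2–4 keep the input width (256), are concatenated (768) and fused
  by a 3×3 convolution, then added to the projected shortcut and passed
  through ReLU. Every dilated convolution uses padding = rate·(kernel−1)/2,
  the unique solution of the convolution size formula for output = input,
  so spatial size is preserved throughout. The source description never
  states the rates of branches 3 and 4; (3, 5) follows the convention of
  the original receptive-field-block design and is configurable. The
  element-wise addition of a 256-channel identity to a 768-channel fusion
  requires the 1×1 shortcut projection; this is the only consistent reading
  of the published widths.
- **Decoder.** Three 3×3 convolutions reduce 768 → 512 (the reduction
  happens at the first convolution; doing it stepwise is equally consistent
  with the published shapes), a 4× bilinear upsampling to 1/4 resolution,
  concatenation with the low-level tap (512 + 64 = 576), three 3×3
  convolutions to 256, a second 4× bilinear upsampling to full resolution,
  four 3×3 convolutions, and a 1×1 convolution with softmax over classes.
  Upsampling is parameter-free bilinear interpolation (half-pixel-center
  convention); the published description does not name an operator.
- Every convolution except the classifier is followed by batch
  normalization and ReLU; the source is silent on normalization and
  activation placement.
- An ASPP block (four parallel dilated 3×3 convolutions, concatenated and
  1×1-fused) is provided as a drop-in alternative to the RFB for ablation.

## Training

Adam with learning rate 0.001, 120 epochs and batch size 16 are the
published defaults; the loss is categorical cross-entropy averaged over
non-ignore pixels (masked pixels contribute neither loss nor gradient —
the published work does not name a loss, and masked cross-entropy is the
standard softmax-segmentation pairing). No learning-rate schedule or early
stopping. Repeated runs differ only in seed; summaries report mean ±
sample standard deviation per metric across five repeats by default.

Two choices were added for stable from-scratch training on short
schedules, both standard practice:

- the final batch-norm scale of each residual branch is zero-initialised,
  so every block starts as (a projection of) the identity;
- before any inference-mode evaluation, batch-norm running statistics are
  recomputed exactly over (up to 32 patches of) the training set
  ("precise BN"). Momentum-tracked running averages lag badly within a
  few hundred optimisation steps and otherwise leave eval-mode accuracy
  far below train-mode accuracy.

The CNN engine itself is NumPy throughout (float32, NCHW): convolution via
im2col and BLAS matmul, col2im via per-kernel-tap slice adds, bilinear
up/down-projection as two separable dense linear maps. All layers carry
hand-written backward passes validated against central differences in the
test suite. Everything is deterministic given the seeds.

## Tiling and plot-aware splitting

Training samples are square patches (published size 256, desk-scale tests
use 64) cut on a sliding window with 50% overlap by default; scenes
smaller than one tile are reflection-padded. Augmentation is limited to
label-preserving flips and 90° rotations applied identically to input and
label. Scene-level inference averages overlapping per-tile softmax maps
and takes the per-pixel argmax.

Train/validation splitting operates on plots (fields), not patches: plot
ids are randomly partitioned by the requested fractions, and each side
receives the patches overlapping its plots with every other pixel's label
masked to ignore. No plot contributes labeled pixels to both sides. Input
reflectance of other plots remains visible as spatial context — the same
situation as testing on a sub-area of one co-registered scene — so the
guarantee is against supervision leakage, not against shared unlabeled
context.

## Synthetic scenes

The generator emulates the structure this pipeline assumes about
agricultural scenes: a Voronoi tessellation of random seed points produces
contiguous polygonal plots with sharp boundaries; each plot is a single
crop (or unlabeled background rendered with a bare-soil spectrum); pixel
spectra are the class's mean 10-band signature plus i.i.d. Gaussian noise
(optionally spatially smoothed). Label boundaries coincide exactly with
plot boundaries. The default signatures are vegetation-like (low blue/red,
red-edge rise, NIR plateau, moderate SWIR) with corn and soybean
deliberately closer to each other than either is to rice, mirroring the
corn/soybean confusion reported on real imagery; the default noise level
is signature_sd = 0.02 (≈2% reflectance within-field variability, a
realistic single-date magnitude).

What the generator does **not** emulate: mixed boundary pixels, phenology
and multi-temporal signals, spatially correlated atmospheric or
illumination effects, clouds/shadows, within-field management gradients.
Passing tests therefore demonstrate that the machinery (features, tiling,
optimisation, evaluation) is correct and that the architecture can learn
plot-structured spectral classes — not that real-scene accuracies are
reproduced.

## Desk-scale test conditions

The learnability check trains the `reduced` backbone with narrower fusion
and decoder widths (rfb_out_channels = 128, decoder_channels = (96, 64) —
both configurable) on 64×64 patches from one 192×192 scene with 20 plots,
30 epochs, batch size 2, learning rate 0.001, evaluating scene-level
predictions on held-out plots. Batch size 2 rather than 16 gives the short
schedule enough optimisation steps; the learning rate is unchanged.

The noise level for this check is signature_sd = 0.005. The reason is an
information bound, not network quality: PCA compression of 12 features to
3 channels discards most of the deliberately small corn–soybean
separation, and a per-pixel linear classifier on the 3-channel input caps
at ≈0.91 overall accuracy at sd = 0.02, ≈0.95 at 0.01 and ≈0.99 at 0.005
(measured with scikit-learn logistic regression on generated scenes). At
0.005 the input supports near-perfect pixel classification, so the check
measures the network and training machinery rather than the PCA
information floor.

## Numerical and degenerate-input conventions

- NDVI/EVI: zero-denominator pixels yield 0 and a mask flag; outputs are
  finite everywhere.
- PCA: deterministic sign (each component's largest-magnitude loading made
  positive); zero-variance features get unit scale with a warning;
  full-SVD solver for reproducibility.
- Min–max scaling maps a constant channel to 0.5.
- Metrics: per-class accuracy is producer's accuracy (recall); classes
  with no truth pixels are flagged NaN and excluded from summaries; MIoU
  averages over classes present in truth or prediction (0/0 excluded);
  kappa is NaN when expected agreement is 1.
- Convolution size formula errors on non-positive outputs (dilated kernel
  larger than the padded input).
- Baseline hyperparameter search scores candidates on a validation split
  by default; `select_on="test"` reproduces selection on the test set as
  published, at the cost of the known optimistic bias.
- GeoTIFF I/O writes genuine GeoTIFF georeference tags (pixel scale and
  tie point) and a JSON description carrying CRS, band roles and nodata;
  band order on disk may be arbitrary when a role mapping is supplied.

## Known limitations

- No pretrained backbone weights: training is always from scratch (an
  optional load hook would require externally supplied checkpoints).
- Transposed-convolution upsampling is declared in the config surface but
  not implemented; bilinear is the only mode.
- The NumPy engine is single-process and unsuited to full-scale (120
  epoch, 256² patch) training; published real-data accuracies are out of
  reach without the original scene and ground truth, which were never
  deposited.
- Per-scene PCA means component orientation can differ between scenes;
  models trained on one scene's projection do not transfer to another
  scene's projection without fixing the transform.
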
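# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations of `hist-st`, in the order the pipeline
runs.

## Spot-grid transform

The hex-to-dense mapping is stored 0-based internally: a spot at array row
`r`, column `c` occupies cell `(r, c // 2)`, which equals the 1-based rule
`(r + 1, phi(r, c))` with `phi = c/2 + 1` on even rows and `(c + 1)/2` on
odd rows. All serialized grids carry a JSON sidecar naming the convention.
Cell collisions raise an error rather than overwrite: on a valid hex
lattice the map is injective, so a collision implies corrupted input.
Spots flagged out-of-tissue are dropped before mapping. Legacy rectangular
ST arrays bypass the parity transform (`hex_transform=False`) and pass
`(row, col)` through unchanged; this pass-through is this package's
extension and is only exercised on rectangular inputs.

Padding appends two all-blank rows at the *bottom* (high row indices) of
the 78-row grid; the choice of edge is a convention, fixed here so indices
of real spots never shift. Expression and label grids pad with zeros;
feature maps pad with the blank-patch feature vector (see below). The
blank rows are marked invalid and excluded from spot-level evaluation.

## Count normalization

Counts are normalized per spot to a fixed library size (default 10,000)
followed by natural `log1p` — the log-normalization convention of the
Seurat ecosystem that upstream ST processing uses. The scale factor is an
argument. All-zero spots are left at zero with a warning rather than
raising: they occur in real data and carry no usable signal either way.

## Spatially variable gene selection

Moran's I uses binary, row-wise k-nearest-neighbour weights (k = 15, no
row normalization, asymmetry allowed). Coordinates are array-space hex
coordinates scaled so all six hex neighbours sit at distance 1 — pixel
coordinates would make the neighbourhood depend on scanner resolution.
k-NN ties are broken by ascending spot index via a stable lexicographic
sort, so the weight matrix is reproducible to the bit.

P-values default to the analytic z test under the normality null
(E[I] = −1/(N−1), the classical variance formula), one-sided for positive
autocorrelation: it is deterministic and fast at 4,992 spots. A
permutation mode (`(1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`) is available.
Panel thresholds are median I > 0.4 (strict inequality) and p < 0.01
across samples; "across all samples" is ambiguous for the p criterion, so
the default pairs the median p with the median I, and a strict
every-sample mode sits behind `p_mode="all"`. Genes with zero variance
score `I = nan, p = 1` and can never be selected. Panel order is
descending median I, ties by name — deterministic under sample and gene
reordering.

## Image preprocessing

Patches are square crops centered on spot pixel centers; the side is 30 px
in high-resolution-image mode or `round(scale_factor × fiducial diameter)`
in WSI mode (the scale factor is a required configuration value — it is
dataset-specific). Border crops are zero-padded. Patches are resized
bilinearly (half-pixel-center convention) to 224² and normalized with the
ImageNet channel constants.

The feature extractor is a pluggable interface: one normalized patch in, a
fixed-length vector out, bit-deterministic. The shipped `StubExtractor`
summarizes a patch by channel means/standard deviations, a 6 × 6 block-mean
thumbnail per channel and mean gradient magnitudes, then applies a fixed
seeded Gaussian projection to the output dimension (default 768). It is a
real, deterministic feature map adequate for synthetic data; it does not
model H&E staining or cell morphology, so performance numbers obtained with
it say nothing about real-tissue accuracy — only that the surrounding
machinery (cropping, assembly, training, evaluation) works. Cells without
spots, and the two pad rows, hold the extractor's response to an all-blank
patch rather than zeros, so "blank tissue" is represented consistently at
the feature level.

WSI tiling pads the image to a 5:4 aspect ratio with white pixels
(blank-tissue background), centered — the patch side is
`ceil(max(H/80, W/64))`, guaranteeing coverage for non-divisible sizes —
then cuts 80 × 64 = 5,120 square tiles row-major. The manifest records the
patch side and pad offsets, making the padded canvas exactly
reconstructable. The N-segment high-resolution mode splits the image into
N × N blocks (`linspace` edges, so blocks differ by at most one pixel) and
tiles each block independently; predictions stitch to (80N) × (64N).

## Prediction network

Encoder: five levels (64, 128, 256, 512, 1024 channels by default), two
`ReLU(BN(Conv3×3, stride 1, pad 1))` blocks per level, 2 × 2 max pooling
between levels; on 80 × 64 input the bottleneck is 1024 × 5 × 4 and the
skips are 80×64 … 10×8. The bottleneck runs a ConvMixer: seven repeats of
a depthwise 7 × 7 (pad 3) convolution with batch norm, ReLU and a residual
connection, followed by a pointwise convolution with batch norm and ReLU.

The multi-scale attention gate (MSAG) on each skip applies three parallel
convolutions — pointwise, 3 × 3 (pad 1), and 3 × 3 dilated (pad 2,
dilation 2), each batch-normalized — to the sum of the skip and the
upsampled decoder features, concatenates them, applies ReLU, then a
batch-normalized pointwise convolution with sigmoid to produce the
attention field α ∈ (0, 1). Default attention is per-location
(one channel, broadcast); per-channel gating is a flag. Batch
normalization is used throughout the gate, including the final gating
convolution.

Decoder upsampling is bilinear 2× followed by a conv block halving the
channels; a transposed-convolution (2 × 2, stride 2) mode is behind a
flag. The head is a 1 × 1 convolution; the mask head applies a sigmoid
(training uses the numerically stable logit form of BCE), the expression
head is linear.

Initialization is Kaiming fan-in scaling from a seeded generator, so a
model is a pure function of its spec and seed. The expression head's bias
is initialized to the per-gene mean of the training targets: log-normalized
expression has a large positive offset that gradient descent at lr 1e-3
would otherwise spend most of the epoch budget learning. The loss is
computed over the full 80 × 64 grid, blank cells included (blank targets
are written into the target maps); a masked-loss mode restricted to
spot-bearing cells is available.

Training follows the fixed protocol — Adam with weight decay 1e-4, cosine
annealing from lr 1e-3 to 0, up to 200 epochs, batch size 5, seeded
shuffling — and aborts with diagnostics on a non-finite loss. Batch norm
uses batch statistics at train time and running averages (momentum 0.1) at
evaluation. LOOCV trains one model per held-out slide in deterministic
fold order and records per-fold manifests.

The level count is configurable (≥ 2, strictly increasing channels) so
reduced lattices can use matching reduced networks; the printed five-level
64…1024 configuration is the default and is asserted structurally in the
tests.

## Application network

ConvNeXt-V2-style backbone: 4 × 4/stride-4 stem convolution with channel
layer normalization, then stages of residual blocks (depthwise 7 × 7 pad 3,
layer norm, pointwise expansion ×4, GELU, global response normalization,
pointwise projection, drop-path on the residual — zero-initialized GRN
affine, drop-path 0 by default) separated by layer-norm + 2 × 2/stride-2
downsampling convolutions; global average pooling, layer normalization and
a linear embedding. Stage widths/depths are configurable; the default is a
small (2, 2, 6, 2) × (40, 80, 160, 320) configuration. Strided
convolutions floor odd spatial sizes (80/4 = 20, 20/2 = 10, 10/2 = 5,
5/2 = 2), and the tests assert the resulting shapes rather than assuming
even divisibility.

The Cox loss L2-normalizes the batch risk vector (dividing by its
Euclidean norm), then averages `−(risk_i − log Σ_j e^{risk_j})` over
uncensored samples. Two denominators are implemented: the default
`risk_set` mode restricts j to subjects with `t_j ≥ t_i` — the standard
partial likelihood, with Breslow handling of ties — while the
`as_printed` mode sums over the whole batch unconditionally. The
time-unrestricted form cannot distinguish early from late events, which is
why the risk-set form is the default; both share a hand-derived vectorized
gradient checked against finite differences. A batch with no uncensored
samples is an error (the normalizer is the number of events).

Survival: embedding ⊕ one-hot clinical covariates → two linear layers →
scalar risk; the covariate encoder learns its category dictionaries on the
training folds only and maps unseen categories to an explicit per-field
"unknown" slot persisted with the model. Training is full-batch AdamW
(first-moment coefficient 0.9, the optimizer's "momentum"), lr 5e-3,
300 epochs, weight decay 1e-4. Response: a single linear layer on the
embedding, cross-entropy, AdamW at lr 5e-5, 200 epochs, batch 20.
Cohorts split by stratified 5-fold on the event indicator, preserving the
censored/uncensored proportion; same seed, same folds.

Pseudo-bulk is the per-gene mean over valid cells — the slide-level
profile comparable to bulk RNA-seq.

## Evaluation conventions

Segmentation metrics are computed at a stated threshold (default 0.5) over
valid cells only by default (blank cells carry no ground truth); a
full-grid mode exists. "SE" is sensitivity, following the segmentation
literature where it appears alongside PC/SP/ACC. An empty positive class
reports sensitivity as missing (nan) rather than raising. AUC is the
rank-based statistic (ties half-counted); C-index is Harrell's with risk
ties at 0.5; the log-rank test is the standard two-group 1-df chi-square;
KM curves are exported as step-function coordinates. Median-split ties go
to the low-risk group, deterministically. Slide-level AUC can be computed
pooled across slides or averaged per slide; both are exposed since either
convention is defensible.

## Synthetic data

The generators produce the statistical structure the method assumes, at
the default full-Visium geometry (78 × 64 = 4,992 spots):

* **Layout** — hex indices with matched parity; pixel centers on a
  triangular lattice with constant pitch (default 10 px/spot).
* **Expression** — a fraction of genes (default 10%) are smooth:
  Gaussian-kernel-smoothed white noise (bandwidth 3 lattice units,
  truncated at 3 bandwidths; bandwidth 0 degenerates to i.i.d.),
  amplitude 1.5 on the log scale plus 0.3 white noise, exponentiated to
  Poisson counts around a baseline mean of e^1.5 ≈ 4.5 counts. These
  settings make smooth genes unambiguous spatially-variable calls
  (median I ≈ 0.6–0.7 at 15-NN) while noise genes stay far below the 0.4
  threshold, mirroring the clear separation of curated SVG panels.
* **Image** — each spot paints a square of 0.7× the spot pitch (hex
  neighbours never overlap, so patch means are uncontaminated); each color
  channel is a *fixed* affine map of one driving gene's log1p count
  (slide-independent, so the image → expression link transfers across
  slides), plus Gaussian texture noise (sd 5 intensity units) and an
  optional darkening of tumor spots (default 40 units) that emulates the
  denser morphology of tumor tissue and is what makes segmentation
  learnable. The image is returned as float64 in 0..255 so the affine
  link is exact at zero noise; PNG export rounds to uint8.
* **Survival cohort** — per-subject grids whose designated channels carry
  latent shifts z ~ N(0,1); the linear predictor is β·z, times are
  exponential with rate 0.1·e^η, and censoring is an independent
  exponential whose rate is solved by bisection so the expected censored
  fraction matches the target. An optional ordinal covariate adds a
  clinical-variable effect.
* **Response cohort** — two classes whose designated pathway channels
  differ by a mean shift; the default cohort shape option (29 responders,
  102 non-responders) reproduces a realistic imbalance.

What passing on synthetic data shows: the transforms are exact, the
statistics agree with oracles, the networks optimize and generalize when a
learnable image link exists, and the clinical heads recover planted hazard
and class structure. What it does not show: accuracy on real H&E
morphology, robustness to staining variation, or the reported performance
levels on real cohorts — those require the pathology-pretrained extractor
and the original datasets.

## Problem sizes used in tests and the acceptance script

Structural checks run at the full 78 × 64 / 80 × 64 geometry, including a
forward pass of the default 768-channel five-level network. Training
experiments run reduced configurations chosen as the package's standard
desk-scale settings: capacity checks overfit one 14 × 16-spot slide with a
three-level (16, 32, 64) network at lr 3e-3 for 200 epochs (the default
lr 1e-3 is tuned to the full geometry; the miniature net trains stably at
3e-3); the LOOCV recovery experiment uses six 14 × 16 slides with
bandwidth 1.5 (smoother fields at this size are nearly global gradients
that a five-slide training set can memorize, masking the local link the
experiment measures) and a two-level (16, 32) network for 60 epochs; the
survival cohort is n = 200 with hazard ratio 3 per latent SD and 30%
censoring, trained with the full 300-epoch protocol on a (16, 32)
two-stage backbone; the response cohort is n = 60, balanced, separation 3,
trained at lr 1e-3 (the printed 5e-5 is matched to the production-size
network and barely moves the reduced one in 200 epochs).

## Numerical choices

The autodiff engine keeps whatever float precision its inputs carry:
training runs float32, gradient checks float64. Convolution is
im2col/einsum with an explicit scatter for the input gradient; max-pool
ties resolve to the first maximum (argmax convention). Bilinear resampling
uses half-pixel centers with clamped edges everywhere (patch resize,
decoder upsampling). Batch-norm epsilon 1e-5, layer-norm 1e-6, GRN 1e-6;
log-sum-exp terms are max-shifted. Cox risk normalization adds 1e-12
inside the square root to keep the all-zero-risk gradient finite.

## Known limitations

* The stub extractor is a statistical stand-in; no claim about real H&E
  generalization follows from synthetic results.
* The engine is CPU-only and single-threaded beyond BLAS; the full
  78 × 64 five-level network is practical for inference and structural
  validation, but production-scale training of the 768-channel model is
  out of desk scope.
* Only exponential event/censoring times are simulated; no competing
  risks, no time-dependent covariates.
* Legacy-ST coordinates beyond the Visium ranges are handled only by the
  rectangular pass-through.
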
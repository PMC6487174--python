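# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Multispace reconstruction

The reconstruction maps an RGB micrograph to a 3-channel image of structural
texture maps. The intent is invariance: H&E color varies with staining
protocol and scanner, while gradients, cooccurrence statistics and binary
patterns of the luminance image track tissue structure.

**White balance.** Gray-world correction: each channel is scaled so its mean
equals the mean of the three channel means, then clipped to [0, 255] and
rounded. It is parameter-free and deterministic. A channel with zero mean
(an all-black channel) makes the scale undefined and raises
`DegenerateInputError` rather than silently producing an extreme image.

**Grayscale.** The standard luminance combination 0.299R + 0.587G + 0.114B,
rounded half-to-even.

**Gradient map.** 3×3 Sobel magnitude √(Gx²+Gy²) with replicate border
padding, then max-normalized so the image maximum maps to 255 (an all-zero
map stays zero). Max-normalization uses the full dynamic range per image;
the absolute gradient scale is not comparable across images, which is
acceptable because the map feeds a feature extractor, not a calibrated
measurement.

**GLCM map.** A cooccurrence matrix is natively a per-region summary, not an
image, so the map is built per pixel: quantize to `glcm_levels` bins
(v → ⌊v·levels/256⌋, default 8), and for each pixel form the symmetric
normalized cooccurrence matrix of its `glcm_window` neighborhood (default
7 px) at `glcm_offset` (default (0,1)), then emit one statistic — contrast
Σ P(i,j)(i−j)² (default), energy Σ P(i,j)², or homogeneity
Σ P(i,j)/(1+|i−j|). Replicate padding keeps every window full, so the pair
count is the constant (w−|dr|)(w−|dc|) and the offset d is equivalent to −d
under symmetrization. Contrast and homogeneity are linear in the pair
counts and are computed as a single weighted box sum via integral images;
energy is quadratic and uses per-level-pair count maps. The statistic map is
max-normalized like the gradient. The window, offset, level count and
statistic are free parameters exposed in `SpaceParams`; the defaults favor
a small window (local nuclear texture at ~10 px nucleus scale) and contrast
(strong response inside chromatin-textured nuclei, zero in flat background).

**LBP map.** Classic non-uniform 8-neighbor radius-1 codes: bit b is set
when the neighbor ≥ the center, bits ordered clockwise from the top-left
neighbor, most significant bit first. Codes natively span [0, 255], so no
rescaling is applied (and the map must be stored losslessly — PNG, never
JPEG). The ≥ convention makes a constant region code 255.

**Composition.** `reconstruct` = white balance → grayscale → (gradient,
GLCM, LBP) stacked as channels R, G, B; shape is preserved end to end and
the output carries the `reconstructed` color-space tag so it cannot be
re-fed to RGB-only operators.

## Tiling and voting

Patches are 64×64, anchored at the top-left pixel, row-major; the W mod 64
right margin and H mod 64 bottom margin are discarded. On the 1388×1040
micrograph geometry this gives ⌊1388/64⌋×⌊1040/64⌋ = 21×16 = 336 patches —
the only layout that reproduces that grid. Majority voting takes the modal
patch label; ties break to the smallest class id, a deterministic
convention. Probability atlases copy each patch's predicted probability for
the image's class into the grid layout.

## Feature extraction

The extractor is the VGG-16 convolutional trunk: five blocks of (2,2,3,3,3)
3×3 stride-1 same-padded convolutions with (64,128,256,512,512) filters and
ReLU, each block closed by 2×2 max-pooling. On a 64×64×3 input the fifth
pool leaves 2×2×512, flattened (channel-major) to 2048 features. The stock
fully connected layers are dropped; the flattened pooled maps are the
features. The trunk is never fine-tuned — it is a fixed projection, which
avoids overfitting small stained-image datasets and makes extraction
deterministic.

Weights are seeded He-normal (std √(2/fan_in), zero biases) by default;
a `.npz` of conv kernels/biases can be plugged in for externally pretrained
weights, and requesting pretrained weights without a file raises an explicit
error directing offline use to `seeded_random`. Inputs are scaled to [0, 1].
Features are taken post-activation. The forward pass is im2col + BLAS
matmul in float32, processed in fixed-size chunks (`batch_size`, default 16)
that bound memory without affecting values — a patch's features never depend
on its batch neighbors.

A seeded-random trunk is a random (nonlinear) projection: it preserves
texture/density contrasts well enough for the downstream selector to
separate the synthetic classes, but its absolute accuracy on real tissue is
not meaningful; with curated pretrained weights the same interfaces apply.

## Feature selection and classification

Each stream's 2048-vector is reshaped row-major into T×D = 64×32 timesteps
and consumed by a stream-specific LSTM (hidden size 32, gate order
input/forget/cell/output, forget-gate bias initialized to 1). The final
hidden state is the selected 32-dim feature vector; the two streams
cascade to 64 dims. Three linear+softmax heads give the RGB-stream
probabilities aᵢ, the reconstruction-stream probabilities bᵢ, and the fused
prediction. The training loss is

  L = −Σᵢ yᵢ log aᵢ − Σᵢ yᵢ log bᵢ + CE(fused),

i.e. the two per-stream cross-entropies plus the fused head's cross-entropy
as a third, equally weighted term: the fused head is what predicts at
inference, so it must be trained jointly, while the per-stream terms keep
both LSTMs supervised even if one head saturates. Probabilities are floored
at ε = 1e-12 inside logarithms.

**Standardization.** The selector z-scores every feature coordinate using
the training-split mean and standard deviation (stored in the model,
applied at inference). Convolutional ReLU features are all-positive with a
large shared mean; without centering, the recurrence sees almost no
between-sample variation and training stalls. Standardization is fitted on
training data only, so no test information leaks.

**Optimization.** Plain stochastic gradient descent over full passes
("iterations") of the training set: learning rate 0.2, batch size 32,
global-norm gradient clipping at 5, seeded shuffling and initialization
(uniform ±1/√fan_in). The default iteration count is 250; desk-scale runs
in the examples and acceptance script use 10–40 passes, which suffices at
their sample sizes. Backprop through time is implemented directly in numpy
and is verified against finite differences in the test suite; the forward
recurrence is verified against a hand-rolled per-step gate-equation oracle.

Hard labels are the argmax of the fused probabilities; exact ties go to the
smallest class id.

## Evaluation

ACC is the mean correct-prediction indicator. For class c, SEN(c) is the
fraction of class-c samples predicted c and SPE(c) the fraction of non-c
samples predicted non-c; both are undefined (raised as errors) when the
reference group is empty. Metrics are fractions internally and ×100 only at
presentation. Cross-validation assigns folds at the **image** level with
class stratification: all patches of an image share a fold, so
near-identical neighboring patches never straddle the train/test boundary.
This is deliberately stricter than patch-level splitting, which inflates
scores through local correlation. Reports carry per-fold mean ± std next to
the pooled point estimates.

## Synthetic data

**Images.** Each image is a pink (eosin-like) Gaussian-jittered background
with purple (hematoxylin-like) non-overlapping random ellipses, placed by
rejection sampling with a uniform-grid neighbor check. The three class
profiles mimic the morphological contrast pathologists use for the lymphoma
subtypes: CLL-like fields of many small uniform nuclei (3800/Mpx, radius
4–6.5 px, low texture amplitude), FL-like fields of fewer, larger, grainier
nuclei (1500/Mpx, 7–11 px, high amplitude, coarse speckle) and intermediate
MCL-like fields (2400/Mpx, 5.5–8.5 px). These densities give the packed,
sheet-of-lymphocytes appearance of the tissue — roughly a third of the field
is nuclear — so every 64×64 patch contains several nuclei and carries class
signal. Each image receives a random per-channel multiplicative color cast
(±12%) that the white-balance stage must absorb. A fixed seed makes
generation bit-reproducible.

What the generator does *not* emulate: overlapping/touching cells,
follicular architecture (FL's spatial clustering), stromal structures,
staining gradients within a slide, or scanner noise statistics. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that it recovers planted class structure — not that it reaches any
particular accuracy on real lymphoma slides.

**Features.** The paired-feature fixture emits class-conditional Gaussians
directly at the selector's interface. Viewing each 2048-vector as the 64×32
sequence, class k's mean is shifted by `separation` on a class-specific
block of matrix *columns* (default 5 columns), so the signal is present at
every timestep — mirroring how convolutional features spread class
information across the whole vector rather than concentrating it in one
row. The rgb and reconstructed streams use disjoint column ranges, so the
streams are complementary by construction and fusing them genuinely adds
information. Unit-variance noise everywhere; separation 0 yields an exact
null.

## Pipeline and reproducibility

Stages hand off through files (PNG images, CSV tables with a config-hash
header line), so each stage can be rerun standalone and `resume=True` only
recomputes missing outputs. One seed drives everything: the pipeline
derives distinct per-stage seeds (generator, backbone, selector, fold
assignment), all below 2³¹. Two runs with the same config and seed produce
byte-identical reports; this is asserted in the acceptance tests.

Desk-scale problem sizes used by the examples, tests and acceptance script —
12 images of 192×128 (6 patches each) for the end-to-end runs, 300 paired
feature vectors for the selector benchmark, 9×9 rasters for the operator
oracles — were chosen so the whole suite runs in a few minutes on one CPU
core while still exercising every code path at meaningful sample sizes.

## Known limitations

- The seeded-random backbone is a fixed random projection; accuracies on
  real data are only meaningful with externally supplied pretrained weights.
- The GLCM map uses a single offset per run (no orientation averaging).
- The LBP variant is the classic non-uniform code; rotation-invariant or
  uniform-pattern variants are not implemented.
- Majority voting ignores patch confidence; probability atlases expose it
  for inspection but do not enter the vote.
- The synthetic benchmark plants linear mean-shift structure; it does not
  probe the selector's behavior under nonlinear class boundaries.
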
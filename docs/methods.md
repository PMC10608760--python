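# Methods

## Pipeline model and assumptions

The fuser assumes two co-registered, same-scene 2-D images: a grayscale
structural image with high-frequency anatomical detail and a color-mapped
functional image with low spatial detail but salient intensity hotspots. No
registration is performed; only size harmonization (bilinear upsampling of
the smaller image) is provided. All pixel data live in the unit interval
[0, 1]; the sharpening stage clips to this range, which fixes the working
domain package-wide.

### Sharpening

`sharpened = clip(source + k · L(G(source)), 0, 1)` with the fixed 3×3
binomial Gaussian G and the 3×3 Laplacian L, both applied as correlation
(no kernel flip) per channel. The enhancement factor `k` (default 1.0,
config `sharpen.enhancement_factor`) scales the detail layer; 0 disables
sharpening. Two Laplacian variants exist: `standard` (all off-center
entries −1/16, center +8/16, zero sum) and `as_printed` (bottom-right entry
+1/16, sum 2/16). The non-zero-sum variant cannot leave constant regions
invariant and exists only to reproduce a published matrix literally; the
default is `standard`. The 1/16 scale is kept on both variants — it merely
rescales the effective enhancement factor. Border handling defaults to
reflection (`reflect`), which avoids the dark frame that zero padding
induces; `zero` is available for oracle comparisons.

### Feature extraction

A single convolution layer — 64 filters of size 3×3, stride 1, same (zero)
padding, ReLU — produces the per-modality feature maps. Two filter banks
are supported:

* `seeded_random` (default): zero-mean Gaussian filters with variance
  2/fan-in from a fixed seed. The pipeline is weight-agnostic by design:
  instance normalization standardizes every channel before the modalities
  compete, so fusion decisions depend on relative spatial activation
  patterns rather than on particular trained weights. This mode is fully
  offline and bit-reproducible.
* `pretrained_layer1`: the first convolution layer of the standard
  19-layer VGG backbone, when torch/torchvision and its weights are
  installed. Unavailability raises an explicit error naming the fallback —
  never a silent substitution.

### Transposed convolution and normalization

Upsampling is fractionally-strided scatter-and-sum: each input value
deposits a kernel-weighted copy at stride-spaced anchors and overlaps add.
The raw canvas (side `stride·(n−1)+K`) is symmetrically cropped — or
zero-padded when `K < stride` — to exactly `stride·n`, so branches with
different kernel sizes align element-wise. One branch runs per kernel size
(default {3, 5, 7}, stride 2, i.e. one resolution doubling); branch outputs
merge by element-wise mean (max optional). Mean is the default because it
preserves scale before normalization. Kernels are separable triangles
("bilinear" fill) by default; all-ones fill is available and warns when
`K < stride` leaves coverage gaps.

Instance normalization is per-channel-per-image: spatial mean and
*population* variance (divisor H·W), `y = (x − μ)/√(σ² + ε)`, ε = 1e−5
(config `eps`), no learnable affine. Constant channels map to zero.

### Maximum fusion and reconstruction

The normalized maps merge by element-wise maximum. Turning the fused
*feature* map back into a fused *image* is underdetermined in this family of
methods; the package takes the reconstruction standard in shallow-backbone
fusion work: per-pixel L1 activity (channel-summed absolute activation,
bilinearly resampled to source resolution) per modality → per-pixel MRI
weight — `soft`: two-way softmax at temperature `softness` (default 1.0);
`hard`: winner-take-all with ties at 0.5 — → fused pixel as the convex
combination of the two **sharpened** sources, clipped. MRI is replicated to
three channels when the PET is RGB and fused per channel. Hard mode makes
the fused image equal one of the sharpened sources at every non-tied pixel;
soft mode trades that literalness for smoother transitions. The max-fused
feature map itself is retained in `FusionResult.intermediates`.

### Baselines

* DWT: per channel, `levels`-deep (default 2) `db2` decomposition;
  approximation coefficients averaged, detail coefficients chosen by larger
  magnitude; inverse transform; clip.
* Laplacian–Gaussian pyramid: 5-tap [1,4,6,4,1]/16 separable filter with
  mirror boundaries (chosen so that constants are exact fixed points of
  reduce/expand); band-pass levels merged by max-abs, Gaussian top by mean;
  collapse inverts decomposition exactly, so self-fusion is an identity up
  to float error.
* Averaging: naive per-pixel mean, used as the control the proposed method
  must beat on edge transfer.

## Metrics

All reference-based metrics run on channel-averaged (BT.601 luminance)
images. Constants are frozen in `MetricsReport.params`.

* **PSNR** `10·log10(peak²/MSE)`, peak 1.0; identical images report an
  infinity sentinel.
* **SSIM** 11×11 Gaussian window, σ = 1.5, C1 = (0.01)², C2 = (0.03)²,
  population covariance, dynamic range 1. For 8–10 px images the window
  shrinks to the largest odd size that fits.
* **Entropy** Shannon entropy of a 256-bin equal-width histogram on [0, 1]
  (the 8-bit convention), in bits.
* **FSIM** phase congruency from a 4-scale × 4-orientation log-Gabor bank
  (min wavelength 6, scale multiplier 2, σ/f = 0.55, angular σ = π/4/1.2),
  computed as total local energy over total local amplitude without
  noise-threshold compensation (a deterministic simplification of the usual
  estimator; similarity ratios are insensitive to it); gradient magnitude by
  Scharr /16 on a 0–255 scale; T1 = 0.85, T2 = 160; pooled with
  max-phase-congruency salience weights. Needs ≥ 32 px per side.
* **EBS** (Q^AB/F) Sobel strength and orientation (folded to (−π/2, π/2]);
  relative-strength and orientation-preservation terms through sigmoids with
  Γg = 0.9994, κg = −15, σg = 0.5, Γα = 0.9879, κα = −22, σα = 0.8;
  source-gradient-strength weighting. Note the index's intrinsic ceiling: a
  fused image identical to both sources scores
  Γg/(1+e^(−7.5)) · Γα/(1+e^(−4.4)) ≈ 0.9748, not 1, because the
  orientation sigmoid is not saturated at a perfect match.
* Aggregation: PSNR/SSIM/FSIM vs each source plus the two-source mean as
  headline; per-reference values are always retained so any other
  aggregation can be recomputed.

## Phantom generator

Phantoms encode complementary information by construction so fusion quality
is operationally measurable. The structural image has a bright elliptical
shell, mid-gray interior, three seeded nested shells, and a left-hemisphere
disk of fine diagonal sinusoidal ridges (period 8 px, amplitude 0.25) —
the `edge_mask`. The functional image Gaussian-blurs the structural layout
(σ = 2 px, erasing the ridges), rescales it into a low background band
[0.08, 0.45], sets a right-hemisphere disk (`hotspot_mask`, disjoint from
the edge region by construction) to `hotspot_contrast` (default 2.0) times
the background mean — exact in noise-free mode — and renders the scalar
field through a fixed 256-entry warm lookup table whose luminance is
monotone in the underlying value. Additive Gaussian noise (σ = 0.01 by
default, 0 in noise-free mode) models acquisition noise only; there is no
anatomical realism, partial-volume effect, or attenuation model. Default
size is 128×128 with everything derived from a single integer seed through
a seed sequence.

What passing tests on phantoms show — and what they do not: they establish
that the pipeline's operators are correct, that its decisions route
high-texture regions to the structural source and hotspots to the functional
source, and that the metric orderings are reproducible; they do not
establish clinical image quality on real MRI/PET pairs, where registration
error, modality-specific noise, and richer texture statistics apply.

## Numerical choices and degenerate inputs

* Correlation (not flipped convolution) everywhere a small kernel is
  applied; both sharpening kernels are symmetric or near-symmetric so this
  only matters for the `as_printed` variant.
* Population variance (divisor H·W) in instance normalization; ε guards
  constant channels.
* Hard-mode weight ties get 0.5, preserving modality symmetry.
* Transposed-convolution crop offsets round down (`(excess)//2`), fixing a
  deterministic alignment for odd excesses.
* Zero-gradient pixels contribute zero weight (and zero preservation) to
  EBS; an all-constant triple scores 0 by convention.
* PNG output quantizes by round-half-up; round-trip error is ≤ 1/510 per
  pixel.

## Problem sizes

The test suite and the acceptance script run on 64–128 px phantoms with
6–20 pairs per experiment — the scale at which every property the package
asserts (oracle equivalence, fixed points, complementarity recovery,
determinism) is already fully exercised; all statistics are means over
seeded replicates and scale with no code change.

## Known limitations

* 2-D only; single-slice NIfTI is read but volumes are not fused.
* No registration; misaligned inputs degrade gracefully but undetectably.
* FSIM omits the noise-compensation term of the full phase-congruency
  estimator, so absolute FSIM values can differ slightly from
  implementations that include it (self-similarity and ordering behavior
  are unaffected in practice).
* The pretrained backbone path requires an optional heavyweight dependency
  and network-fetched weights; all shipped defaults avoid it.
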
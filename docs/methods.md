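# Methods

## Template derivation

The interpolation kernel is the a = −1 piecewise cubic: S(ω) = 1 − 2ω² +
ω³ on [0, 1), 4 − 8ω + 5ω² − ω³ on [1, 2), 0 beyond; it is even
(S(−ω) = S(ω)) and interpolating (S(0) = 1, S at nonzero integers = 0),
and its four active weights sum to one for any fractional offset, so
constants are reproduced exactly.  At offsets with denominator 8 each
weight is an integer over 512; a 2-D stencil is the outer product of a
v-dependent row vector (S(1+v), S(v), S(1−v), S(2−v)) and the analogous
u-dependent column vector, giving integer numerators over 2¹⁸.  All
derivation arithmetic uses `fractions.Fraction`; floats never enter, so
the bank is bit-exact on every platform.  `u` is the offset along the
column (second) axis and `v` along the row (first) axis; the 16
templates are ordered v-major and satisfy two exact symmetries, used as
tests: swapping (u, v) transposes the stencil, and the k ↔ 17−k pairing
is a 180° rotation.

A hand transcription of the published template table ships in
`printed_table.py` purely as regression data.  The derivation and the
transcription agree in 255 of 256 cells; the printed first entry of
template 11 (2205) is inconsistent with S(13/8)²·2¹⁸ = 2025 and with
the transposed template 10, so it is recorded as a misprint by the
discrepancy report rather than replicated.

### What the a = −1 kernel does and does not reproduce

Partition of unity makes constants exact.  Linear functions are *not*
reproduced exactly: the kernel's first moment Σ w·k at offset 1/8 is
106/512, not 1/8 (the vanishing-first-moment property belongs to the
a = −1/2 Catmull–Rom kernel).  On an affine image the output is
therefore the same affine function evaluated at fixed *effective*
offsets φ(1/8) = 106/512, φ(3/8) = 222/512, φ(5/8) = 290/512,
φ(7/8) = 406/512 — an exact rational identity the test-suite asserts.
Practically this behaves as a mild, fixed resampling distortion (the
price of the sharper a = −1 response); it is a property of the kernel,
not of the implementation.

## Upscaling grids

Output pixel (4i+a, 4j+b) contracts a 4×4 input neighbourhood with the
template whose midpoints are v = (2a+1)/8, u = (2b+1)/8.  Two anchor
conventions are provided:

* **paper** (default): the neighbourhood is anchored at pixel (i, j)
  (rows i−1…i+2).  The sampled lattice then sits at i + (2a+1)/8 —
  one-eighth of a source pixel past the corner-aligned a/4 convention.
* **centered**: the same 16 midpoints re-anchored so subcell a samples
  the centre-aligned coordinate i + (2a−3)/8 (subcells a < 2 use the
  neighbourhood one pixel up/left).

The two grids differ by an exact translation of 2 output pixels per
axis, which the tests assert.  The distinction matters because the
training and evaluation path builds low-resolution inputs by 4×4 area
averaging, whose natural registration is centre-aligned: feeding the
paper grid into the MSE loss would charge the network a constant 2-px
shift (measured: ~6× higher starting MSE on textures).  The network and
evaluation therefore use the centred grid, while all bit-exactness
oracles and the operation-count instrumentation run on the verbatim
paper grid.  Borders use replicate padding by default (reflect
available); integer outputs divide by 2¹⁸ with round-half-away-from-zero
then clamp to the bit depth, and a no-rounding numerator path exists
for exact comparisons.

## Hybrid network and training

Layers: fixed template upscale → f2×f2 conv, n2 filters, ReLU → 1×1
conv, n3 filters, ReLU → f3×f3 conv to one channel, linear.  Trainable
convolutions use "same" zero padding so all feature maps keep the
upscaled size.  Defaults f2 = 9, n2 = 64, n3 = 32, f3 = 5 follow the
three-layer super-resolution CNN lineage; the tests and the acceptance
script use a compact f2 = 5, n2 = 8, n3 = 8, f3 = 3 configuration with
32×32 ground-truth patches (the published 128 → 32 patch geometry
scaled by 4 per side) to keep CPU runs in seconds.

Training minimises the mean (over samples and pixels) squared error
with plain mini-batch SGD: default learning rate 0.03, batch size 10,
no momentum (momentum is available).  0.03 was chosen for stability —
at 0.1 the loss trajectory is noisy enough that an 80-epoch run can end
above its start.  Intensities are normalised by the bit-depth peak.
Non-finite loss aborts with a diagnostic.  Runs are exactly
reproducible from the seed (initialisation and shuffling both derive
from it), and the template bank is byte-identical before and after
training.

**Initialisation.** Default `init="identity"`: biases zero, weights
N(0, 10⁻⁶) with a centre-one pass-through chain added on one filter of
each layer, so the untrained network computes (approximately) the
bicubic upscale and training starts from the baseline it is meant to
refine.  A pure zero-mean Gaussian initialisation (`init="gaussian"`)
is provided but starts from a near-zero output whose MSE is orders of
magnitude above bicubic; recovering the baseline from there needs far
more than the few hundred CPU epochs exercised here.  Identity-anchored
initialisation makes "does training improve on bicubic?" a meaningful
short-horizon question.

**Gradient correctness.** The backward pass is validated against
central finite differences at relative tolerance 10⁻⁴ on every
parameter tensor of a tiny network, with biases offset so no ReLU
preactivation sits within the probe step of its kink (finite
differences are invalid across the kink; the analytic subgradient uses
the z > 0 convention).

## SIFT and transfer selection

Scale space: 3 octaves, 3 scales per octave, σ₀ = 1.6, per-octave
stacks of s+3 Gaussians (incremental blurs, reflect boundary) and s+2
difference-of-Gaussians layers; octaves that would drop below 8 px are
trimmed with a warning.  Keypoints are strict extrema over the 26
neighbours (8 in-plane, 9 above, 9 below) with |DoG| above a contrast
threshold, no subpixel refinement and no Hessian edge rejection.  The
threshold default is 0.01 *on raw adjacent-scale differences*: the
conventional 0.03 applies to normalised/interpolated responses, and raw
differencing at three scales per octave attenuates peak responses by
roughly (2^{1/3} − 1), so 0.03 on raw DoG leaves realistic smooth
textures nearly featureless.

Descriptors: dominant orientation from a Gaussian-weighted 36-bin
gradient histogram (two passes of circular smoothing, peak bin);
16×16 gradient samples at spacing σ/2 in the rotated frame,
accumulated into 4×4 cells × 8 orientation bins (128 values),
Gaussian-windowed, normalised to unit length, clipped at 0.2 and
renormalised.  Keypoints whose rotated sampling window leaves the image
are dropped and counted.  Unit normalisation puts descriptor distances
in [0, √2].

Selection: D(S, T) is the mean over the candidate's descriptors of the
minimum Euclidean distance to the reference's (asymmetric by
construction); η is the fraction of candidate features whose nearest
reference neighbour passes Lowe's ratio test (0.8).  D is aggregated as
the minimum over references, η evaluated against that best reference,
and the candidate admitted iff η ≥ D.  The rule compares a
dimensionless ratio to a descriptor distance; unit-normalised
descriptors put both on an O(1) scale, and independent η/D threshold
overrides are exposed.  Candidates with no keypoints are rejected and
flagged.  Selection is fully deterministic given inputs and parameters.

## Data preparation and evaluation

Ground-truth patches are cut randomly (seeded integer origins,
round-robin over sources) and reduced ×4 by exact area averaging —
each low-resolution pixel is the mean of its 4×4 block — so every pair
is bit-reproducible from its provenance record (bicubic decimation is
available behind a flag).  Evaluation mirrors the training geometry:
ground truth → ×4 area scale-down → method → PSNR against the ground
truth at the declared bit depth (peak 255 by default; MSE 0 reports an
infinite sentinel).  Region-wise PSNR takes half-open boxes;
`classify_regions` labels tiles corners/edges vs plain by mean gradient
magnitude.

## Synthetic fixtures

Seeded generators (NumPy PCG64) cover constant, ramp, sinusoid,
separated Gaussian blobs, checkerboard, step edge and smooth noise
(white noise convolved with a Gaussian, rescaled to [0.1, 0.9] of the
intensity range).  Smooth noise is the training/held-out workhorse: it
is band-limited, so part of what ×4 decimation removes is recoverable
and super-resolution training is learnable; blobs guarantee separated
DoG extrema for detector tests; constants and ramps supply
feature-free rejection cases.  These fixtures emulate texture
statistics, not medical physics — no modality noise models, no
anatomy — so passing tests demonstrate the algorithms' correctness and
trainability, not clinical image quality.

Held-out evaluation draws unseen images from the same generative family
as the training corpus.  With matched distributions the short-horizon
trained network consistently recovers PSNR over the bicubic baseline;
across a distribution shift (e.g. training on mixed textures, testing
on nearly-flat blob images) the learned sharpening can cost PSNR on the
smooth kinds — a property of distribution shift, not of the optimiser.

## Problem sizes and limitations

Test and acceptance runs use 50 pairs (8×8 → 32×32), 200 epochs for the
loss-trajectory check and 80 epochs × 10 seeds for the held-out median;
SIFT experiments use 64–128 px fixtures.  Known limitations: ×4 only
(quarter-cell midpoints are baked into the bank); single channel
(colour inputs are reduced to BT.601 luminance); no keypoint subpixel
refinement or edge-response rejection; the η ≥ D criterion inherits the
unit mismatch of its two sides and should be read as a calibrated
heuristic; and small CPU-scale training runs demonstrate improvement in
the tenths-of-a-dB range, not the gains attainable with full-scale
corpora.
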
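# Methods

## Model and assumptions

The pipeline fuses exactly two single-channel sources that are assumed
co-registered on one pixel grid; registration is a precondition, not a
feature. Intensities are carried as float64 in [0, 1] (detail layers and
high-pass maps may be signed). Pixel indexing is 0-based and row-major,
with row = image y increasing downward.

The fusion model is the two-scale weighted-average family: each source
is split into a low-frequency base layer and a signed detail residual,
each pair of layers is blended with its own per-pixel weight map, and
the fused image is the sum of the two blends. The premise is that local
detail strength (saliency) identifies which source is in focus at each
pixel, and that an edge-aware smoothing of the resulting binary decision
— a guided filter steered by the source itself — aligns the weights with
intensity boundaries ("spatial consistency") instead of the jagged
decision boundary.

## Decomposition and the LBP descriptor

The structural split is a mean-filter two-scale decomposition: base =
(2·`base_radius`+1)² box mean (default radius 15, i.e. 31×31), detail =
source − base. This keeps the reconstruction identity exact to machine
precision and every downstream operation well defined. The
local-binary-pattern code map — 8 samples on a circle of radius 1,
bilinear interpolation off-grid, bit 0 at the east sample proceeding
counter-clockwise, ties counting as ≥ — is computed per source as the
declared low-level texture descriptor and attached to the layer pair.
Whether LBP codes should additionally gate the smoothing itself (an
edge-aware base layer) is left open deliberately; the decomposition sits
behind a single entry point (`decompose`) so an alternative split can be
swapped in without touching the rest of the pipeline. The ≥ comparison
in the LBP code carries a 1e-9 absolute slack so exact ties are not
broken by interpolation rounding.

## Saliency and weights

Saliency is the Gaussian-smoothed magnitude of the 4-neighbor Laplacian
response: the absolute value between the two convolutions makes the map
a non-negative local average of high-pass energy (a bare composition of
the two linear filters would largely cancel and measure nothing).
Defaults: 11×11 Gaussian window, sigma 5 — config-exposed, chosen to
match the guided-filtering fusion lineage; they are not claimed to be
canonical.

The binary comparison uses a first-wins tie rule (P₁ = [S₁ ≥ S₂],
P₂ = 1 − P₁). A symmetric ≥ on both sides would assign 1 to both maps on
ties and double-count in the weighted sum; with first-wins the binary
pair always partitions the image, and the final normalization makes the
choice immaterial for the fused output.

Refinement runs the fast guided filter on each binary map with **its own
source** as guidance. Two regimes: base weights use r₁ = 45, ε₁ = 0.25,
subsample 4 (smooth, cheap at large radius); detail weights use r₂ = 7,
ε₂ = 10⁻⁶, subsample 1 (sharp, exact). r₂ is floored from the nominal
7.5 because box windows need integer radii. Refined weights are clipped
to [0, 1].

Refined pairs generally do not sum to one (two different guidance
images), so an explicit per-pixel normalization divides each pair by its
sum, falling back to 0.5/0.5 where the sum is below 1e-9. This step is a
design addition: without it the weighted sums drift in intensity and the
fuse(I, I) = I identity fails.

## Filtering numerics

- **Borders:** every window operation uses mirror reflection without
  repeating the border pixel, avoiding dark-frame bias in window means.
- **Guided filter:** window statistics via box means; the window
  variance is clamped at 0 before adding ε; with ε = 0 and a
  zero-variance window the regression's minimum-norm solution (a = 0,
  b = window mean of the input) is used, avoiding 0/0.
- **Fast guided filter:** block-mean (area) downsampling of input and
  guide — partial edge blocks average over the pixels they contain —
  low-resolution radius max(1, round(r/s)), strictly bilinear upsampling
  of the coefficient maps, and application against the full-resolution
  guide. s = 1 short-circuits to the exact filter. Subsample ratios
  above min(H, W)/4 are rejected as degenerate. On smooth 64×64
  fixtures the s = 4 approximation stays within 0.05 of the exact
  filter (measured ≈ 0.02).
- **Gaussian low-pass:** finite size×size kernel renormalized to sum 1,
  applied separably; with mirror borders the separable pass is identical
  to the dense 2-D convolution up to rounding.
- **Output clipping:** fused values are clipped to [0, 1] at the very
  end; weighted sums of in-range layers can overshoot at sharp edges.

## Metrics

- **MSE** is averaged over the two sources on the 0–255 intensity
  scale — a declared convention, chosen so magnitudes land in the range
  practitioners expect for 8-bit imagery.
- **MI** uses 256-bin joint histograms of 8-bit-quantized intensities,
  log base 2, empty bins contributing zero. For f = a = b this equals
  2·H(a) exactly.
- **Q^AB/F** uses 3×3 Sobel gradients (mirror borders); orientation is
  arctan(g_y/g_x) on (−π/2, π/2]; gradient components below 1e-12 are
  snapped to zero so orientations at exactly axis-aligned edges are
  stable. Relative strength is min/max of the gradient magnitudes (1
  when both vanish). Sigmoid constants Γ_g = 0.9994, κ_g = −15,
  σ_g = 0.5, Γ_α = 0.9879, κ_α = −22, σ_α = 0.8 — the canonical
  published values. Per-pixel preservations are averaged weighted by the
  corresponding source gradient strengths; a gradient-free triple scores
  0 by the zero-total-weight guard.
- **Q_Y** slides a 7×7 window over the fully interior pixels; SSIM uses
  the standard stabilizers C₁ = 0.01², C₂ = 0.03² on the [0, 1] scale;
  λ = σ²_A/(σ²_A + σ²_B) with a 0.5 fallback when both vanish; the
  consistency threshold SSIM(A,B) ≥ 0.75 selects the blended branch,
  otherwise the better source SSIM is taken.

## Synthetic corpus

The phantom generator emulates the *geometry* of anatomy-like imagery —
overlapping soft-edged ellipses of varied intensity over a flat
background, plus band-limited texture (default peak amplitude 0.08) so
detail layers and saliency maps are non-trivial. The focus-pair
generator blurs the phantom with the pipeline's own Gaussian primitive
(no hidden second convolution implementation) and composes each input as
ground truth inside a mask and blur outside, masks exactly
complementary; kinds cover the easy case (half-split), the
smooth-boundary case (radial disk) and the hard case (random blobs with
thin structures, median-thresholded smooth noise). Default blur sigmas 2
and 4 give moderately and strongly defocused inputs at 256×256.

What the corpus does **not** emulate: true multimodal contrast physics
(CT vs MRI), sensor noise, misregistration, or intensity
non-uniformity. Passing tests therefore demonstrate the pipeline's
focus-recovery behavior under ideal complementary-information
conditions, not clinical performance.

## Problem sizes and determinism

The test suite and the acceptance script use 256×256 phantoms for
end-to-end properties (10 idempotence images, 20 focus pairs covering
both blur levels and all three mask kinds) and fixtures up to 32×32 for
brute-force oracle comparisons — sizes at which the loop-based oracles
are exact and fast. All generation is seeded; the pipeline itself is
deterministic, and a CLI run with fixed config and inputs is
byte-reproducible.

## Known limitations

- Exactly two sources; no multi-image weight tournaments.
- Grayscale path only; color inputs are reduced to Rec.601 luminance on
  read.
- No rotation-invariant or histogram LBP variants; the descriptor is
  reported, not yet used to steer the smoothing.
- No DICOM/NIfTI readers; PNG/TIFF only.
- The first-wins tie rule makes fuse(A, B) and fuse(B, A) differ at
  exact-saliency-tie pixels; averaging the two orders removes the
  asymmetry.
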
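# fgfusion

Two-scale fusion of co-registered single-channel images — medical
multifocus/multimodal pairs being the motivating case — with
saliency-driven weight maps refined by a fast guided filter, plus the
four quality metrics commonly used to score fusion results.

## The method

Given two pre-registered sources *I₁*, *I₂* (grayscale, intensities in
[0, 1]):

1. **Two-scale decomposition.** Each source is split as *I = B + D*,
   where the base layer *B* is a large box-window mean (default 31×31)
   and the detail layer *D = I − B* is the signed residual, so
   reconstruction is exact. A circular local-binary-pattern (LBP) code
   map is computed per source as its low-level texture descriptor and
   retained on the result.
2. **Decision maps.** Each source's saliency map
   *S = G \* |L \* I|* is the Gaussian-smoothed magnitude of its
   Laplacian response — a measure of local detail strength. The pixelwise
   comparison *S₁ ≥ S₂* yields binary weight maps *P₁*, *P₂ = 1 − P₁*
   that partition the image.
3. **Weight refinement.** Each binary map is refined with a fast guided
   filter, *W = FGF(P, I)*, guided by its own source, under two
   parameter regimes: base-layer weights use a large radius and strong
   regularization (*r₁ = 45*, *ε₁ = 0.25*, subsample 4) for spatial
   smoothness; detail-layer weights use a small radius and tiny
   regularization (*r₂ = 7*, *ε₂ = 10⁻⁶*, exact filter) to stay sharp.
   Each refined pair is normalized to sum to one per pixel.
4. **Reconstruction.** *F_B = W₁ᴮB₁ + W₂ᴮB₂*, *F_D = W₁ᴰD₁ + W₂ᴰD₂*,
   and the fused image is *F = F_B + F_D*, clipped to [0, 1].

The quality of a fusion *F* of sources *A*, *B* is scored with:

- **MSE** — mean squared error of *F* against each source on the 0–255
  scale, averaged over the two sources (lower is better);
- **MI** — mutual information *I(A;F) + I(B;F)* in bits from 256-bin
  joint histograms;
- **Q^AB/F** — Sobel gradient strength/orientation preservation mapped
  through the canonical sigmoids and averaged with gradient-strength
  weights;
- **Q_Y** — SSIM-based structural preservation over sliding 7×7 windows.

Because clinical benchmark databases cannot ship with a library, the
`synthetic` module generates ground-truth phantoms (soft-edged ellipses
plus band-limited texture) and complementary-focus pairs — each input
sharp inside a mask, Gaussian-blurred outside, with the masks exact
complements — so every pipeline stage is testable offline.

## Worked example

```python
import numpy as np
import fgfusion as fg

gt = fg.make_phantom(size=128, seed=1)                 # ground truth
a, b, mask = fg.make_focus_pair(gt, blur_sigma=2.0,
                                mask_kind="half-split", seed=1)
result = fg.fuse(a, b)                                  # full pipeline

err = lambda x: float(np.mean((255 * (x - gt)) ** 2))
print(err(a), err(b), err(0.5 * (a + b)), err(result.fused))
print(fg.evaluate(a, b, result.fused))
```

Output:

```
30.335112478552787 39.65889361039831 17.498501522237774 1.7221073489142538
MetricsReport(mse=31.15991985124887, mi=6.837836075330609, qabf=0.737639349801044, qy=0.972268688795859)
```

The fused image sits far closer to the ground truth (MSE ≈ 1.7 on the
0–255² scale) than either blurred input (≈ 30 and ≈ 40) or their plain
average (≈ 17.5); the metrics report scores the fused image against the
two *inputs* (its MSE there is dominated by the blur the inputs carry,
which is exactly the information fusion removes).

The same pipeline is available from the shell:

```sh
fgfusion demo --size 256 --seed 0 --mask radial -o out/
fgfusion fuse A.png B.png -o F.png --r1 45 --eps1 0.25
fgfusion metrics A.png B.png F.png --json
```

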
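# contourfit

Semiautomatic contour delineation for 2D medical and synthetic images:
Hermite cubic curve fitting through automatically allocated control points,
scriptable control-point revision, and fully automatic subpixel refinement
of the curve toward maximum gradient magnitude.

## Who this is for

Delineating the closed boundary of a region of interest (an organ, a tumor,
a phantom object) is a routine step in image-guided radiation therapy
planning and in quantitative image analysis. Fully manual tracing is slow
and observer-dependent; fully automatic segmentation is brittle. This
package implements the middle road: a rough boundary (in practice
mouse-drawn; here an ordered point list in JSON or CSV) is condensed to a
handful of editable control points, interpolated with a smooth closed
curve, and then every curve point is pulled automatically onto the nearby
image edge with subpixel precision — no iterative energy minimization.

## The method

**Curve fitting.** A boundary of arc length *L* receives a fixed number of
control points (6 for *L* < 30 px, 10 for *L* < 150, 20 for *L* < 200,
otherwise 30), placed at equal arc length. Each pair of consecutive control
points (P₀, P₁) with centered-difference tangents (u₀, u₁) spans one cubic
segment

&nbsp;&nbsp;&nbsp;&nbsp;P(s) = h₁(s)P₀ + h₂(s)P₁ + h₃(s)u₀ + h₄(s)u₁,&nbsp;&nbsp; s ∈ [0, 1],

with the Hermite basis h₁ = 2s³−3s²+1, h₂ = −2s³+3s², h₃ = s³−2s²+s,
h₄ = s³−s². Sampling at spacing Δs = 0.1 yields 10 points per segment. The
curve interpolates every control point, and moving one control point only
changes the four nearby segments (local control), which is what makes
point-by-point revision practical.

**Refinement.** The image gradient is computed with separable Gaussian
derivative filters, G(x) = exp(−x²/2σ²)/(√(2π)σ) and G′(x) = −x/σ²·G(x).
For each curve point Pᵢ, the normal of the local line fit through
(Pᵢ₋₁, Pᵢ, Pᵢ₊₁) defines a search segment; the point moves to the candidate
Pᵢ + t·n̂, t ∈ {−d, …, −Δd, 0, Δd, …, +d}, with the largest bilinearly
interpolated gradient magnitude. Defaults: d = 2 px, Δd = 0.1 px, σ = 1.

A minimal Kass–Witkin active contour (semi-implicit update with the
circulant internal-energy matrix) is included as a baseline, along with a
synthetic phantom generator and boundary/overlap metrics.

## Worked example

```python
import numpy as np
from contourfit import make_noisy_disc, perturb_contour, delineate, evaluate_contour

# Phantom: dark disc of radius 85 px centered in 256x256, noise sigma 10.
scene = make_noisy_disc(noise_sigma=10.0, seed=1)

# Stand-in for an imprecise manual trace: truth perturbed by up to 1 px.
rough = perturb_contour(scene.truth_contour, amplitude=1.0, seed=2)

result = delineate(scene.image, rough)          # allocate -> fit -> refine
before = evaluate_contour(result.fitted, scene.truth_contour, scene.image.shape)
after = evaluate_contour(result.refined, scene.truth_contour, scene.image.shape)
print(f"control points:        {len(result.control_points)}")
print(f"curve points:          {len(result.refined)}")
print(f"mean error (fitted):   {before.mean_abs_distance:.3f} px")
print(f"mean error (refined):  {after.mean_abs_distance:.3f} px")
print(f"Dice (refined):        {after.dice:.4f}")
```

Output:

```
control points:        30
curve points:          300
mean error (fitted):   0.527 px
mean error (refined):  0.161 px
Dice (refined):        0.9982
```

The disc's perimeter (≈534 px) allocates the maximum 30 control points,
sampled to 300 curve points. The fitted curve inherits roughly half a pixel
of error from the imprecise trace; refinement pulls the mean boundary error
down to ~0.16 px — below pixel quantization — at near-perfect region
overlap.

The same pipeline is available from the shell:

```bash
contourfit simulate --noise-sigma 10 --seed 1 --out-prefix scene
contourfit delineate scene.png init.json --out refined.json --report-out report.json
contourfit metrics refined.json scene_truth.json --shape 256 256
```

Subcommands `revise` (move a control point and re-fit), `refine`
(refinement only) and `snake` (baseline active contour) complete the CLI.

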
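# Methods

## The delineation model

The pipeline treats delineation as two decoupled problems: *representation*
(a rough closed boundary is condensed to an editable, smooth parametric
curve) and *localization* (each curve point is snapped to the nearest image
edge). There is no global energy being minimized and no iteration: every
point's refinement is a one-shot local search, so the result is fast,
deterministic, and order-independent.

### Control-point allocation

The number of control points is a step function of the boundary arc length:
fewer than 30 px → 6 points, [30, 150) → 10, [150, 200) → 20, ≥ 200 → 30.
The bands balance revision effort against expressiveness — small regions
need proportionally more points to follow their shape, large regions would
be tedious to edit with more than 30. The band edges are closed on the
left, which makes the function total and monotone. Allocation ignores
curvature by design: equal arc-length spacing keeps the editing model
simple, at the cost of under-resolving isolated high-curvature features
(a documented limitation, not a bug).

### Hermite interpolation

Segments use the cubic Hermite basis; curve continuity across segments
comes from sharing endpoint tangents. The tangent rule is the
centered difference uᵢ = (Pᵢ₊₁ − Pᵢ₋₁)/2 with cyclic indexing
(Catmull-Rom), chosen because it (a) keeps the curve interpolating,
(b) confines the effect of moving one control point to the four segments
i−2 … i+1, and (c) requires no extra user input. Sampling uses
s = 0, Δs, …, 1−Δs per segment so the shared endpoint is emitted exactly
once; with Δs = 0.1 (default) a K-point curve has exactly 10K samples. Δs
must divide 1 exactly (validated), so sample counts are integers by
construction and the s = 0 sample equals the control point bitwise.

### Gradient field

Gradients are separable Gaussian-derivative convolutions (smoothing
orthogonal to differentiation), truncated at 4σ — the standard
negligible-tail cutoff — with reflective boundary handling to avoid
spurious border edges. σ defaults to 1.0 px; raise it for noisier or
lower-resolution images (noise suppression scales with σ at the cost of
edge localization bias near curved boundaries, which grows as ~σ²/2r for
a circle of radius r).

Canny-style non-maximal suppression (bilinear interpolation of the two
competitors one unit step along ± the gradient direction, ties kept) is
provided for visualization and optional use, but the refinement search
deliberately samples the *raw* magnitude: a suppressed field is zero almost
everywhere along an oblique search segment, which turns the argmax into a
degenerate tie among zeros. The smooth field has no such plateaus.

### Refinement search

Candidates lie at offsets {−d, …, −Δd, 0, Δd, …, +d} along the local unit
normal (total-least-squares line through the point and its two neighbours;
the sign is irrelevant because the search is two-sided). Choices that the
method leaves open, and how this implementation resolves them:

- **Update order.** All points are refined from the *input* contour
  (Jacobi-style), never sequentially in place, so the output does not
  depend on where the contour's first point happens to be.
- **Ties.** The candidate nearest the original position wins; the original
  wins exact ties; among symmetric ties the negative offset is taken.
  Values within 1e−12 (relative) of the maximum count as tied, so bilinear
  round-off on a constant field cannot move a point. This prevents drift
  on plateaus and makes refinement a no-op on gradient-free images.
- **Bounds.** Out-of-bounds candidates are dropped rather than erroring;
  only a point whose entire segment leaves the image raises (with the
  point index in the message).
- **Candidate count.** The offsets give 2d/Δd + 1 candidates (41 for
  d = 2, Δd = 0.1); if Δd does not divide d the outermost candidates fall
  at ⌊d/Δd⌋·Δd.
- **No post-smoothing.** The shifted polyline is the final curve. An
  optional `post_fit` flag re-runs allocation + Hermite fitting on the
  refined polyline for callers who want a smooth editable result, but it
  is off by default because it re-introduces representation error.

Parameter guidance: d (default 2 px, valid 1–5) is the error budget of the
initial curve — if the true edge is farther than d from the fitted curve
the search cannot reach it, so rough inputs need manual revision first,
not a larger d (a larger d also admits more distractor edges). Δd (default
0.1 px) is the localization granularity; finer spacing buys nothing once
below the interpolation error of the bilinear magnitude model, which is
why 0.1 is the default rather than something smaller.

What subpixel means here: the bilinearly interpolated magnitude is
piecewise linear along any axis-aligned line, so its argmax snaps to pixel
nodes for edges parallel to the grid — the step-edge experiments show the
residual quantization (~0.02 px mean at Δd = 0.1 for an edge on a pixel
center). On oblique and curved boundaries the interpolation is genuinely
2D and the refined contour tracks the edge at ~0.16 px mean error on the
reference phantom.

## The synthetic scenes

`make_noisy_disc` emulates the canonical ground-truth experiment: a dark
disc (fg = 0) of radius 85 px centered in a 256×256 bright (bg = 255)
image with additive white Gaussian noise. The noise level is configurable;
the default σ = 10 intensity units (≈4% of contrast) was fixed once as a
realistic moderate-noise condition. The disc edge is anti-aliased by pixel
area coverage (a 1-px linear ramp in signed distance), giving the gradient
magnitude a well-defined subpixel maximum on the analytic circle — a hard
binary edge would make "the true boundary" ambiguous at the pixel scale.
`make_step_edge` provides the 1D analogue; `perturb_contour` displaces a
contour along its normals by a random low-order Fourier profile scaled so
the maximum displacement equals the requested amplitude, emulating smooth,
spatially correlated tracing error rather than white jitter.

What these scenes do *not* model: CT/MR/US texture, speckle, intensity
inhomogeneity, nearby distractor edges, or partial-volume effects. Passing
the phantom tests demonstrates the geometry and the localization machinery
are correct under the stated noise model; it does not by itself establish
clinical accuracy, which in the intended workflow is guarded by the human
revision step.

## The snake baseline

The comparison baseline is the textbook active contour: internal stiffness
A = −αD₂ + βD₄ (circulant second/fourth differences; symmetric positive
semidefinite), external energy −‖∇(G_σ∗I)‖² on the [0, 1]-rescaled image,
and the semi-implicit update x ← (A + γI)⁻¹(γx + ∇‖∇(G_σ∗I)‖²), factorized
once per run. Defaults α = β = 0.1, γ = 1, 400 iterations, fixed-iteration
stopping (no convergence test). It is illustrative only — tuned well
enough to lock onto the clean phantom edge (≈0.1 px mean error from an
initialization 2 px out) — and deliberately excludes balloon forces, GVF
and level sets.

## Metrics

Boundary error is the mean (or max, for Hausdorff) distance from each test
point to the nearest *segment* of the other polyline, so the value does
not depend on how densely either contour is sampled. Dice uses even-odd
pixel-center rasterization; contours whose polygon area is below half a
pixel are rejected as degenerate. By construction symmetric Hausdorff ≥
directed Hausdorff ≥ mean distance.

## Problem sizes

The evaluation scripts use 20 noise realizations of the 256×256 phantom,
120 step-edge searches per spacing, and 50 randomized fuzz scenes of
48–96 px — sizes at which every reported quantity is stable to well within
its decision margin while the whole run stays in the seconds range.

## Known limitations

- Uniform arc-length control points under-resolve thin or highly concave
  structures; the cap of 30 points bounds achievable detail for very large
  regions.
- Refinement is purely local: it cannot recover from initial errors larger
  than d, and in cluttered neighbourhoods a distractor edge inside the
  search window wins if its gradient is stronger.
- Axis-aligned edges localize to the pixel grid (see above); the subpixel
  gain is realized on oblique/curved boundaries.
- Only single-slice 2D images are handled; DICOM input reads the pixel
  array of one frame and ignores spatial metadata (spacing is assumed
  isotropic in pixel units).
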
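"""Synthetic test scenes with analytically known boundaries.

The main scene is a dark disc of radius 85 px centered in a 256x256 image,
corrupted with additive Gaussian noise — a phantom whose true boundary is
known exactly, so delineation accuracy can be measured rather than judged
visually.  The disc edge is anti-aliased by pixel area coverage (a 1-px
linear transition in the signed distance to the circle), which gives the
gradient magnitude a well-defined subpixel maximum on the true boundary.

A vertical step-edge scene and a smooth contour perturbation (standing in
for imprecise manual drawing) complete the fixtures.  Every scene is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import Contour, estimate_tangents

__all__ = ["SyntheticScene", "make_noisy_disc", "make_step_edge", "perturb_contour"]


@dataclass
class SyntheticScene:
    """Image plus analytic ground truth: reproducible from (params, seed)."""

    image: np.ndarray
    truth_contour: Contour
    truth_params: dict
    seed: int
    noise_sigma: float
    clean_image: np.ndarray = field(repr=False, default=None)


def make_noisy_disc(
    size: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    radius: float = 85.0,
    fg: float = 0.0,
    bg: float = 255.0,
    noise_sigma: float = 10.0,
    seed: int = 0,
    n_truth_points: int = 720,
) -> SyntheticScene:
    """Dark disc (intensity ``fg``) on a bright background with Gaussian noise.

    Defaults reproduce the reference phantom: a black radius-85 disc
    centered in a 256x256 image.  ``noise_sigma`` is the additive noise
    standard deviation in intensity units (default 10 on the 0-255 scale).
    The truth contour is a dense exact sampling of the circle.
    """
    rows, cols = int(size[0]), int(size[1])
    if center is None:
        center = (cols / 2.0, rows / 2.0)
    cx, cy = float(center[0]), float(center[1])
    radius = float(radius)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if cx - radius < 0 or cx + radius > cols - 1 or cy - radius < 0 or cy + radius > rows - 1:
        raise ValueError("disc must lie inside the image")
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(radius - dist + 0.5, 0.0, 1.0)  # 1 inside, 0 outside, 1-px ramp
    clean = bg + (fg - bg) * coverage
    image = clean.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    theta = np.linspace(0.0, 2.0 * np.pi, int(n_truth_points), endpoint=False)
    truth = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    return SyntheticScene(
        image=image,
        truth_contour=Contour(truth, closed=True),
        truth_params={"center": (cx, cy), "radius": radius, "fg": fg, "bg": bg},
        seed=int(seed),
        noise_sigma=float(noise_sigma),
        clean_image=clean,
    )


def make_step_edge(
    size: tuple[int, int] = (64, 64),
    edge_x: float = 31.0,
    fg: float = 255.0,
    bg: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Vertical intensity step at subpixel column ``edge_x``.

    Column i (covering [i-0.5, i+0.5]) takes the area-coverage blend of bg
    (left of the edge) and fg (right of the edge).  The analytic truth is
    the vertical line x = edge_x, stored as an open polyline.
    """
    rows, cols = int(size[0]), int(size[1])
    edge_x = float(edge_x)
    if not 0.0 < edge_x < cols - 1:
        raise ValueError("edge_x must be strictly inside the image")
    x = np.arange(cols, dtype=float)
    frac_fg = np.clip(x + 0.5 - edge_x, 0.0, 1.0)
    clean = np.tile(bg + (fg - bg) * frac_fg, (rows, 1))
    image = clean.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    truth = np.column_stack([np.full(rows, edge_x), np.arange(rows, dtype=float)])
    return SyntheticScene(
        image=image,
        truth_contour=Contour(truth, closed=False),
        truth_params={"edge_x": edge_x, "fg": fg, "bg": bg},
        seed=int(seed),
        noise_sigma=float(noise_sigma),
        clean_image=clean,
    )


def perturb_contour(contour: Contour, amplitude: float, seed: int = 0, n_harmonics: int = 4) -> Contour:
    """Displace each point along its local normal by smooth correlated noise.

    The displacement profile is a random low-order Fourier series over the
    contour parameter, rescaled so its maximum absolute value equals
    ``amplitude`` (so no point moves farther than ``amplitude``).  Emulates
    the smooth, spatially correlated error of imprecise manual tracing.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return Contour(contour.points.copy(), contour.closed)
    n = len(contour)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / n
    disp = np.zeros(n)
    for k in range(1, int(n_harmonics) + 1):
        a = rng.normal()
        phi = rng.uniform(0.0, 2.0 * np.pi)
        disp += a * np.cos(2.0 * np.pi * k * t + phi)
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amplitude / peak
    tangents = estimate_tangents(contour.points, contour.closed)
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]]) / norms[:, None]
    return Contour(contour.points + disp[:, None] * normals, contour.closed)
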
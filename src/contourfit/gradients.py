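"""Gaussian-derivative gradient fields and subpixel magnitude sampling.

Edge strength is computed by separable filtering with a 1D Gaussian
G(x) = 1/(sqrt(2*pi)*sigma) * exp(-x^2 / (2*sigma^2)) and its derivative
dG/dx = -x/sigma^2 * G(x): the horizontal component gx smooths along rows'
orthogonal direction and differentiates along x, and symmetrically for gy.
The Gaussian scale sigma controls noise suppression; sigma should grow for
low-resolution, noisy images.

Non-maximal suppression (Canny-style, with linear interpolation of the two
neighbours along the gradient direction) thins the magnitude to ridge
pixels; it is provided for visualization and optional use.  The refinement
search samples the raw (un-suppressed) magnitude, which stays smooth along
the search segment, via bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientField",
    "gaussian_derivative_kernels",
    "compute_gradient",
    "nonmax_suppression",
    "sample_magnitude",
    "load_image",
]


@dataclass
class GradientField:
    """Per-pixel gradient components and magnitude at a single Gaussian scale."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    sigma: float
    nms_applied: bool = False

    def __post_init__(self) -> None:
        if not (self.gx.shape == self.gy.shape == self.magnitude.shape):
            raise ValueError("gx, gy and magnitude must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def gaussian_derivative_kernels(sigma: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """1D Gaussian smoothing kernel and its derivative, sampled at integer offsets.

    Offsets run over [-ceil(truncate*sigma), +ceil(truncate*sigma)].  The
    smoothing kernel is normalized to sum 1; the derivative kernel is the
    sampled -x/sigma^2 * G(x), antisymmetric and zero-sum.
    """
    sigma = float(sigma)
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(truncate * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)
    smooth = g / g.sum()
    deriv = -x / sigma**2 * g
    deriv = (deriv - deriv[::-1]) / 2.0  # exact antisymmetry and zero sum
    return smooth, deriv


def compute_gradient(image: np.ndarray, sigma: float = 1.0, truncate: float = 4.0) -> GradientField:
    """Separable Gaussian-derivative gradient of a 2D intensity image.

    gx differentiates along x (columns) and smooths along y (rows); gy is
    symmetric.  Boundaries are handled by reflection.  Equivalent to 2D
    convolution with the outer-product kernels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2D with at least 3 pixels per axis")
    if not np.isfinite(img).all():
        raise ValueError("image must contain only finite values")
    smooth, deriv = gaussian_derivative_kernels(sigma, truncate)
    gx = ndimage.convolve1d(img, deriv, axis=1, mode="reflect")
    gx = ndimage.convolve1d(gx, smooth, axis=0, mode="reflect")
    gy = ndimage.convolve1d(img, deriv, axis=0, mode="reflect")
    gy = ndimage.convolve1d(gy, smooth, axis=1, mode="reflect")
    return GradientField(gx=gx, gy=gy, magnitude=np.hypot(gx, gy), sigma=float(sigma))


def nonmax_suppression(field: GradientField) -> GradientField:
    """Zero magnitude at pixels not locally maximal along the gradient direction.

    The two competitors are sampled one unit step along +/- the unit
    gradient direction with bilinear interpolation (Canny-style).  gx and gy
    are kept; only the magnitude is thinned.  Applying NMS twice is an
    error (the thinned field no longer equals hypot(gx, gy)).
    """
    if field.nms_applied:
        raise ValueError("non-maximal suppression has already been applied")
    mag = field.magnitude
    rows, cols = mag.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(mag > 0, field.gx / np.where(mag > 0, mag, 1.0), 0.0)
        uy = np.where(mag > 0, field.gy / np.where(mag > 0, mag, 1.0), 0.0)
    fwd = ndimage.map_coordinates(mag, [yy + uy, xx + ux], order=1, mode="nearest")
    bwd = ndimage.map_coordinates(mag, [yy - uy, xx - ux], order=1, mode="nearest")
    keep = (mag >= fwd) & (mag >= bwd) & (mag > 0)
    return GradientField(
        gx=field.gx,
        gy=field.gy,
        magnitude=np.where(keep, mag, 0.0),
        sigma=field.sigma,
        nms_applied=True,
    )


def _sample_many(field: GradientField, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear magnitude samples at arrays of (x, y); no bounds checking."""
    return ndimage.map_coordinates(
        field.magnitude, np.vstack([np.atleast_1d(ys), np.atleast_1d(xs)]), order=1, mode="nearest"
    )


def sample_magnitude(field: GradientField, x: float, y: float) -> float:
    """Bilinear interpolation of the magnitude at a subpixel position.

    Exact array value at integer coordinates.  Positions outside
    [0, cols-1] x [0, rows-1] raise (callers clip search segments).
    """
    rows, cols = field.shape
    if not (0.0 <= x <= cols - 1 and 0.0 <= y <= rows - 1):
        raise ValueError(f"({x}, {y}) is outside the image bounds")
    return float(_sample_many(field, np.array([x]), np.array([y]))[0])


def load_image(path) -> np.ndarray:
    """Load a grayscale image as float64: PNG/TIFF via imageio, DICOM via pydicom.

    Images with color channels are reduced by the channel average.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        import pydicom

        img = pydicom.dcmread(str(path)).pixel_array.astype(float)
    else:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"expected a single-frame 2D image in {path}")
    return img
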
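"""Contour accuracy metrics: boundary distances and region overlap.

Boundary error is measured point-to-polyline (distance from each test point
to the nearest *segment* of the truth polyline, not the nearest vertex), so
densely and sparsely sampled truths are treated consistently.  Region
overlap uses the Dice coefficient of the rasterized interiors (pixel-center
point-in-polygon, even-odd rule).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.draw import polygon2mask

from .curves import Contour

__all__ = [
    "ContourErrorReport",
    "mean_boundary_distance",
    "hausdorff_distance",
    "dice_from_contours",
    "evaluate_contour",
]


@dataclass(frozen=True)
class ContourErrorReport:
    mean_abs_distance: float
    hausdorff: float
    dice: float
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


def _point_to_polyline_distances(points: np.ndarray, poly: Contour) -> np.ndarray:
    """Min distance from each query point to any segment of the polyline."""
    verts = poly.points
    if poly.closed:
        a = verts
        b = np.roll(verts, -1, axis=0)
    else:
        a = verts[:-1]
        b = verts[1:]
    ab = b - a  # (M, 2)
    ab2 = np.einsum("md,md->m", ab, ab)
    ap = points[:, None, :] - a[None, :, :]  # (N, M, 2)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.hypot(points[:, None, 0] - closest[:, :, 0], points[:, None, 1] - closest[:, :, 1])
    return d.min(axis=1)


def mean_boundary_distance(test: Contour, truth: Contour) -> float:
    """Mean over test points of the distance to the nearest truth segment."""
    return float(_point_to_polyline_distances(test.points, truth).mean())


def hausdorff_distance(test: Contour, truth: Contour) -> float:
    """Symmetric Hausdorff distance between the two polylines (point-to-segment)."""
    forward = _point_to_polyline_distances(test.points, truth).max()
    backward = _point_to_polyline_distances(truth.points, test).max()
    return float(max(forward, backward))


def _mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    # polygon2mask expects (row, col) vertices and tests pixel centers
    poly = np.column_stack([contour.points[:, 1], contour.points[:, 0]])
    return polygon2mask(tuple(int(s) for s in shape), poly)


def _polygon_area(contour: Contour) -> float:
    x, y = contour.points[:, 0], contour.points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def dice_from_contours(test: Contour, truth: Contour, shape: tuple[int, int]) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of the rasterized contour interiors."""
    if _polygon_area(test) < 0.5 or _polygon_area(truth) < 0.5:
        raise ValueError("degenerate (zero-area) contour")
    a = _mask(test, shape)
    b = _mask(truth, shape)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("degenerate (zero-area) contour")
    return 2.0 * float(np.logical_and(a, b).sum()) / (na + nb)


def evaluate_contour(test: Contour, truth: Contour, shape: tuple[int, int]) -> ContourErrorReport:
    """Full error report for a delineated contour against the ground truth."""
    return ContourErrorReport(
        mean_abs_distance=mean_boundary_distance(test, truth),
        hausdorff=hausdorff_distance(test, truth),
        dice=dice_from_contours(test, truth, shape),
        n_points=len(test),
    )
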
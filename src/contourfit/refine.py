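"""Automatic subpixel curve refinement along local normals.

Each point P_i of the sampled curve is moved, independently of the others,
to the position of maximum gradient magnitude among the candidates
P_i + t * n_i for t in {-d, -d+Δd, ..., +d}, where n_i is the unit normal of
the local total-least-squares line through (P_{i-1}, P_i, P_{i+1}) and the
magnitude is sampled with bilinear interpolation.  The search half-width d
bounds how far any point can move (the initial curve is assumed within d of
the true boundary); Δd sets the subpixel candidate spacing (0.1 px by
default — finer steps gain nothing against interpolation error and noise).

All points are updated from the *input* contour (Jacobi-style), so the
result is independent of point ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import (
    Contour,
    CurveSamplingParams,
    allocate_control_points,
    evaluate_curve,
    subsample_control_points,
)
from .gradients import GradientField, _sample_many

__all__ = [
    "RefinementParams",
    "RefinementError",
    "estimate_normal",
    "refine_point",
    "refine_curve",
]

TIE_POLICIES = ("nearest_to_original", "keep_original")


class RefinementError(RuntimeError):
    """Refinement failed for a specific curve point."""


@dataclass(frozen=True)
class RefinementParams:
    """Normal-search parameters.

    d: search half-width in pixels (1..5; 2-3 is adequate when the initial
       curve is close to the boundary).
    delta_d: candidate spacing along the normal, in pixels.
    tie_policy: how equal-magnitude maxima are resolved.
    """

    d: float = 2.0
    delta_d: float = 0.1
    tie_policy: str = "nearest_to_original"

    def __post_init__(self) -> None:
        if not 1.0 <= self.d <= 5.0:
            raise ValueError("d must be in [1, 5] pixels")
        if not 0.0 < self.delta_d <= self.d:
            raise ValueError("delta_d must satisfy 0 < delta_d <= d")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")

    @property
    def offsets(self) -> np.ndarray:
        """Signed candidate offsets {-d, ..., -Δd, 0, Δd, ..., +d}."""
        n = int(np.floor(self.d / self.delta_d + 1e-9))
        return np.arange(-n, n + 1) * self.delta_d


def estimate_normal(p_prev, p, p_next) -> np.ndarray:
    """Unit normal of the total-least-squares line through three nearby points.

    The tangent is the dominant principal direction of the centered point
    triple; the normal is its 90-degree rotation.  The sign is arbitrary
    (the search covers both sides).  Falls back to the chord direction
    p_next - p_prev when the triple is directionally degenerate.
    """
    pts = np.array([p_prev, p, p_next], dtype=float)
    chord = pts[2] - pts[0]
    if np.hypot(*chord) == 0.0:
        raise ValueError("p_prev and p_next coincide; normal is undefined")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[1] - w[0] > 1e-12 * max(w[1], 1.0):
        tangent = v[:, 1]
    else:
        tangent = chord / np.hypot(*chord)
    normal = np.array([-tangent[1], tangent[0]])
    return normal / np.hypot(*normal)


def _candidate_values(field: GradientField, cand: np.ndarray) -> np.ndarray:
    return _sample_many(field, cand[:, 0], cand[:, 1])


def _select(offsets: np.ndarray, values: np.ndarray, tie_policy: str) -> int:
    """Index of the winning candidate under the tie policy.

    Values within machine tolerance of the maximum count as tied, so
    bilinear rounding on a constant field cannot break an exact tie.
    """
    vmax = values.max()
    tol = 1e-12 * max(1.0, abs(vmax))
    ties = np.flatnonzero(values >= vmax - tol)
    if tie_policy == "keep_original":
        zero = np.flatnonzero(offsets[ties] == 0.0)
        if zero.size:
            return int(ties[zero[0]])
    order = np.lexsort((offsets[ties], np.abs(offsets[ties])))
    return int(ties[order[0]])


def refine_point(
    field: GradientField, p_prev, p, p_next, params: RefinementParams | None = None
) -> tuple[float, float]:
    """Move one point to the maximum-magnitude candidate along its normal.

    Candidates falling outside the image are dropped; if every candidate is
    out of bounds the search fails.  Ties are broken toward the original
    position (the original wins exact ties), preventing drift on flat
    plateaus.
    """
    if params is None:
        params = RefinementParams()
    normal = estimate_normal(p_prev, p, p_next)
    p = np.asarray(p, dtype=float)
    offsets = params.offsets
    cand = p[None, :] + offsets[:, None] * normal[None, :]
    rows, cols = field.shape
    inb = (
        (cand[:, 0] >= 0.0)
        & (cand[:, 0] <= cols - 1)
        & (cand[:, 1] >= 0.0)
        & (cand[:, 1] <= rows - 1)
    )
    if not inb.any():
        raise ValueError(f"search segment around ({p[0]}, {p[1]}) is entirely out of bounds")
    cand, offsets = cand[inb], offsets[inb]
    values = _candidate_values(field, cand)
    best = _select(offsets, values, params.tie_policy)
    return (float(cand[best, 0]), float(cand[best, 1]))


def refine_curve(
    contour: Contour,
    field: GradientField,
    params: RefinementParams | None = None,
    post_fit: bool = False,
    delta_s: float = 0.1,
) -> Contour:
    """Refine every contour point independently using its cyclic input neighbours.

    The output keeps the point count and ordering; every output point lies
    within d of its input point.  With ``post_fit=True`` the refined
    polyline is additionally smoothed by re-running the control-point
    allocation and Hermite fit on it (off by default: the refined polyline
    itself is the final curve).
    """
    if params is None:
        params = RefinementParams()
    if len(contour) < 3:
        raise ValueError("contour needs at least 3 points")
    pts = contour.points
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    out = np.empty_like(pts)
    for i in range(len(pts)):
        try:
            out[i] = refine_point(field, prev[i], pts[i], nxt[i], params)
        except ValueError as exc:
            raise RefinementError(f"refinement failed at point {i}: {exc}") from exc
    refined = Contour(out, closed=contour.closed)
    if post_fit:
        count = allocate_control_points(refined.length)
        cps = subsample_control_points(refined, count)
        refined = evaluate_curve(cps, CurveSamplingParams(delta_s=delta_s))
    return refined
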
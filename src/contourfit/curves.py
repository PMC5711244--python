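"""Closed-boundary representation and Hermite cubic curve fitting.

The delineation workflow starts from a roughly traced region boundary (an
ordered polyline standing in for a mouse-drawn outline).  A small number of
control points is allocated from the boundary length, placed at equal arc
length along the polyline, and interpolated with a piecewise Hermite cubic
curve.  Each cubic segment between control points ``P0`` and ``P1`` with
endpoint tangents ``u0`` and ``u1`` is

    P(s) = h1(s) P0 + h2(s) P1 + h3(s) u0 + h4(s) u1,   s in [0, 1]

with the four Hermite basis polynomials ``h1..h4``.  Tangents are estimated
by centered differences of the neighbouring control points (Catmull-Rom
style), which keeps the curve interpolating and locally controlled: moving
one control point only changes the four segments whose endpoint or tangent
data involve it.

Coordinates are ``(x, y) = (column, row)``, 0-based, with pixel centers at
integer coordinates.  Contours are closed (the last point connects back to
the first); index arithmetic is cyclic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Contour",
    "ControlPointSet",
    "CurveSamplingParams",
    "hermite_basis",
    "allocate_control_points",
    "estimate_tangents",
    "subsample_control_points",
    "evaluate_curve",
    "move_control_point",
    "save_contour",
    "load_contour",
    "save_control_points",
    "load_control_points",
]

MIN_CONTROL_POINTS = 3
MAX_CONTROL_POINTS = 30


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y) pairs")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    return pts


@dataclass
class Contour:
    """Ordered polyline of subpixel (x, y) points.

    The pipeline always produces closed contours (``closed=True``, the
    closing segment joins the last point to the first).  Open polylines are
    accepted only as analytic truth fixtures.
    """

    points: np.ndarray
    closed: bool = True
    _length: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 points")
        if np.any(self._segment_lengths(pts, self.closed) == 0.0):
            raise ValueError("consecutive duplicate points are not allowed")
        self.points = pts
        self._length = None

    @staticmethod
    def _segment_lengths(pts: np.ndarray, closed: bool) -> np.ndarray:
        if closed:
            seg = np.roll(pts, -1, axis=0) - pts
        else:
            seg = np.diff(pts, axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    @property
    def segment_lengths(self) -> np.ndarray:
        return self._segment_lengths(self.points, self.closed)

    @property
    def length(self) -> float:
        """Arc length in pixels (cached), including the closing segment."""
        if self._length is None:
            self._length = float(self.segment_lengths.sum())
        return self._length

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ControlPointSet:
    """Control points ``P_i`` with endpoint tangents ``u_i`` of the fitted curve."""

    points: np.ndarray
    tangents: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        tan = _as_points(self.tangents)
        if len(pts) != len(tan):
            raise ValueError("points and tangents must have equal length")
        if not MIN_CONTROL_POINTS <= len(pts) <= MAX_CONTROL_POINTS:
            raise ValueError(
                f"control point count must be in "
                f"[{MIN_CONTROL_POINTS}, {MAX_CONTROL_POINTS}], got {len(pts)}"
            )
        self.points = pts
        self.tangents = tan

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CurveSamplingParams:
    """Sampling step Δs in the unit parameter interval of each segment.

    1/Δs must be a positive integer so every segment emits the same number
    of samples and the segment endpoint coincides with the next segment's
    start (no duplicate samples on a closed curve).
    """

    delta_s: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_s <= 0.5:
            raise ValueError("delta_s must satisfy 0 < delta_s <= 0.5")
        m = round(1.0 / self.delta_s)
        if abs(m * self.delta_s - 1.0) > 1e-9:
            raise ValueError("1/delta_s must be a positive integer")

    @property
    def samples_per_segment(self) -> int:
        return round(1.0 / self.delta_s)


def hermite_basis(s: float) -> tuple[float, float, float, float]:
    """Evaluate the four Hermite cubic basis functions at ``s`` in [0, 1].

    Returns ``(h1, h2, h3, h4)`` with h1 = 2s^3 - 3s^2 + 1, h2 = -2s^3 + 3s^2,
    h3 = s^3 - 2s^2 + s, h4 = s^3 - s^2.  h1 + h2 == 1 for all s (partition
    of unity of the positional weights).
    """
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    s2 = s * s
    s3 = s2 * s
    return (
        2.0 * s3 - 3.0 * s2 + 1.0,
        -2.0 * s3 + 3.0 * s2,
        s3 - 2.0 * s2 + s,
        s3 - s2,
    )


def _basis_matrix(s: np.ndarray) -> np.ndarray:
    """Hermite basis evaluated at an array of parameters; shape (len(s), 4)."""
    s = np.asarray(s, dtype=float)
    s2 = s * s
    s3 = s2 * s
    return np.stack(
        [
            2.0 * s3 - 3.0 * s2 + 1.0,
            -2.0 * s3 + 3.0 * s2,
            s3 - 2.0 * s2 + s,
            s3 - s2,
        ],
        axis=1,
    )


def allocate_control_points(boundary_length: float) -> int:
    """Number of control points for a boundary of the given arc length.

    Small regions get relatively many points so they remain editable;
    large regions are capped at 30 points to keep revision manageable.
    Bands (closed on the left): <30 px -> 6, [30, 150) -> 10,
    [150, 200) -> 20, >= 200 -> 30.
    """
    length = float(boundary_length)
    if not np.isfinite(length) or length <= 0:
        raise ValueError("boundary length must be positive")
    if length < 30:
        return 6
    if length < 150:
        return 10
    if length < 200:
        return 20
    return 30


def estimate_tangents(points, closed: bool = True) -> np.ndarray:
    """Centered-difference (Catmull-Rom style) tangents u_i = (P_{i+1} - P_{i-1}) / 2.

    Indexing is cyclic for closed curves; open polylines use one-sided
    differences at the two ends.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to estimate tangents")
    if closed:
        return (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) / 2.0
    tan = np.empty_like(pts)
    tan[1:-1] = (pts[2:] - pts[:-2]) / 2.0
    tan[0] = pts[1] - pts[0]
    tan[-1] = pts[-1] - pts[-2]
    return tan


def subsample_control_points(boundary: Contour, count: int) -> ControlPointSet:
    """Place ``count`` control points on the boundary at equal arc-length spacing.

    The first control point coincides with the boundary's first vertex; the
    rest follow at multiples of length/count along the (closed) polyline.
    """
    count = int(count)
    if count < MIN_CONTROL_POINTS:
        raise ValueError(f"count must be at least {MIN_CONTROL_POINTS}")
    total = boundary.length
    if total / count < 1e-9:
        raise ValueError("count exceeds the number of resolvable positions")
    if boundary.closed:
        verts = np.vstack([boundary.points, boundary.points[:1]])
    else:
        verts = boundary.points
    cum = np.concatenate([[0.0], np.cumsum(Contour._segment_lengths(boundary.points, boundary.closed))])
    targets = np.arange(count) * (total / count)
    x = np.interp(targets, cum, verts[:, 0])
    y = np.interp(targets, cum, verts[:, 1])
    pts = np.column_stack([x, y])
    return ControlPointSet(pts, estimate_tangents(pts, closed=True), closed=True)


def evaluate_curve(cps: ControlPointSet, params: CurveSamplingParams | None = None) -> Contour:
    """Sample the piecewise Hermite curve through the control points.

    Each of the N cyclic segments (P_i -> P_{i+1}) is sampled at
    s = 0, Δs, ..., 1-Δs; the segment endpoint is the next segment's start,
    so the closed curve has exactly N/Δs points and passes through every
    control point exactly (the s=0 sample of segment i is P_i bitwise).
    """
    if params is None:
        params = CurveSamplingParams()
    if not cps.closed:
        raise ValueError("evaluate_curve requires a closed control-point set")
    m = params.samples_per_segment
    s = np.arange(m) / m
    h = _basis_matrix(s)  # (m, 4)
    p0 = cps.points
    p1 = np.roll(p0, -1, axis=0)
    u0 = cps.tangents
    u1 = np.roll(u0, -1, axis=0)
    geom = np.stack([p0, p1, u0, u1], axis=1)  # (n, 4, 2)
    samples = np.einsum("sk,nkd->nsd", h, geom).reshape(len(cps) * m, 2)
    return Contour(samples, closed=True)


def move_control_point(cps: ControlPointSet, index: int, new_pos) -> ControlPointSet:
    """Return a new set with one control point replaced and tangents re-estimated.

    With centered-difference tangents the resampled curve changes only on
    the four cyclic segments index-2 .. index+1; all others are bitwise
    unchanged (local control).
    """
    n = len(cps)
    if not 0 <= int(index) < n:
        raise IndexError(f"control point index {index} out of range [0, {n})")
    pts = cps.points.copy()
    pts[int(index)] = np.asarray(new_pos, dtype=float)
    return ControlPointSet(pts, estimate_tangents(pts, cps.closed), cps.closed)


# ---------------------------------------------------------------------------
# Contour / control-point serialization (JSON and CSV)

def save_contour(contour: Contour, path) -> None:
    """Write a contour as JSON ({"closed": ..., "points": [[x, y], ...]}) or CSV (x,y rows)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        payload = {"closed": bool(contour.closed), "points": contour.points.tolist()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif suffix == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            writer.writerows(contour.points.tolist())
    else:
        raise ValueError(f"unsupported contour format: {path.suffix!r}")


def load_contour(path) -> Contour:
    """Read a contour from a JSON or CSV file (CSV header row optional)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        data = json.loads(path.read_text())
        return Contour(np.asarray(data["points"], dtype=float), bool(data.get("closed", True)))
    if suffix == ".csv":
        rows: list[list[float]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                try:
                    rows.append([float(row[0]), float(row[1])])
                except ValueError:
                    if rows:
                        raise
                    continue  # header row
        return Contour(np.asarray(rows, dtype=float), closed=True)
    raise ValueError(f"unsupported contour format: {path.suffix!r}")


def save_control_points(cps: ControlPointSet, path) -> None:
    payload = {
        "closed": bool(cps.closed),
        "points": cps.points.tolist(),
        "tangents": cps.tangents.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_control_points(path) -> ControlPointSet:
    data = json.loads(Path(path).read_text())
    pts = np.asarray(data["points"], dtype=float)
    if "tangents" in data:
        tan = np.asarray(data["tangents"], dtype=float)
    else:
        tan = estimate_tangents(pts, bool(data.get("closed", True)))
    return ControlPointSet(pts, tan, bool(data.get("closed", True)))
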
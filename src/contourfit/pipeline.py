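"""End-to-end delineation pipeline.

Wires the stages together: boundary length -> control-point allocation ->
equal-arc subsampling -> Hermite curve sampling -> Gaussian-derivative
gradient -> normal-search refinement.  The CLI and the evaluation scripts
are thin layers over :func:`delineate`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curves import (
    Contour,
    ControlPointSet,
    CurveSamplingParams,
    allocate_control_points,
    evaluate_curve,
    subsample_control_points,
)
from .gradients import GradientField, compute_gradient
from .refine import RefinementParams, refine_curve

__all__ = ["DelineationResult", "delineate"]

log = logging.getLogger(__name__)


@dataclass
class DelineationResult:
    """All intermediate stages of one delineation run."""

    control_points: ControlPointSet
    fitted: Contour
    field: GradientField
    refined: Contour
    params: dict

    @property
    def report(self) -> dict:
        return {
            "boundary_length_px": None if "boundary_length" not in self.params else self.params["boundary_length"],
            "n_control_points": len(self.control_points),
            "n_curve_points": len(self.fitted),
            "n_refined_points": len(self.refined),
            **{k: v for k, v in self.params.items() if k != "boundary_length"},
        }


def delineate(
    image: np.ndarray,
    boundary: Contour,
    sigma: float = 1.0,
    delta_s: float = 0.1,
    refinement: RefinementParams | None = None,
    n_control_points: int | None = None,
    post_fit: bool = False,
) -> DelineationResult:
    """Run the full semiautomatic pipeline on an image and a rough boundary.

    ``n_control_points`` overrides the automatic length-based allocation.
    Returns every stage so callers can inspect the control points, the
    fitted curve and the refined curve.
    """
    if refinement is None:
        refinement = RefinementParams()
    length = boundary.length
    count = n_control_points if n_control_points is not None else allocate_control_points(length)
    log.info("boundary length %.1f px -> %d control points", length, count)
    cps = subsample_control_points(boundary, count)
    fitted = evaluate_curve(cps, CurveSamplingParams(delta_s=delta_s))
    log.info("fitted Hermite curve with %d points (delta_s=%g)", len(fitted), delta_s)
    field = compute_gradient(image, sigma=sigma)
    refined = refine_curve(fitted, field, refinement, post_fit=post_fit, delta_s=delta_s)
    log.info(
        "refined %d points (d=%g, delta_d=%g, sigma=%g)",
        len(refined), refinement.d, refinement.delta_d, sigma,
    )
    return DelineationResult(
        control_points=cps,
        fitted=fitted,
        field=field,
        refined=refined,
        params={
            "boundary_length": length,
            "sigma": sigma,
            "delta_s": delta_s,
            "d": refinement.d,
            "delta_d": refinement.delta_d,
            "tie_policy": refinement.tie_policy,
            "post_fit": post_fit,
        },
    )
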
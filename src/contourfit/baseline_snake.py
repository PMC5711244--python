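"""Minimal Kass-Witkin active contour, used as a comparison baseline.

The snake minimizes internal bending/tension energy plus an external edge
energy E_ext = -|grad(G_sigma * I)|^2 by the standard semi-implicit
iteration

    x_{t+1} = (A + gamma I)^{-1} (gamma x_t - dE_ext/dx |_{x_t})

where A is the symmetric circulant internal-energy stiffness built from the
tension weight alpha (second-difference term) and rigidity weight beta
(fourth-difference term).  The image is rescaled to [0, 1] before the edge
energy is computed so the default weights are intensity-scale free.  This
is deliberately the textbook model — no balloon force, GVF, or level sets —
serving only as the reference against which the local normal-search
refinement is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

from .curves import Contour
from .gradients import compute_gradient

__all__ = ["SnakeParams", "internal_matrix", "run_snake"]


@dataclass(frozen=True)
class SnakeParams:
    """alpha: tension, beta: rigidity, gamma: step size, iterations: fixed count."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 1.0
    iterations: int = 400
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta and gamma must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Circulant stiffness A = -alpha*D2 + beta*D4 for a closed n-point snake.

    D2 and D4 are the cyclic second- and fourth-difference operators; A is
    symmetric positive semidefinite.
    """
    if n < 5:
        raise ValueError("snake needs at least 5 points")
    row = np.zeros(n)
    row[[0, 1, -1]] = [-2.0, 1.0, 1.0]
    d2 = linalg.circulant(row)
    row4 = np.zeros(n)
    row4[[0, 1, 2, -2, -1]] = [6.0, -4.0, 1.0, 1.0, -4.0]
    d4 = linalg.circulant(row4)
    return -alpha * d2 + beta * d4


def run_snake(image: np.ndarray, init: Contour, params: SnakeParams | None = None) -> Contour:
    """Iterate the semi-implicit snake update from the initial closed contour.

    The external force is +grad(|grad(G_sigma*I)|^2) sampled bilinearly at
    the snake points (pulling toward edge-magnitude ridges).  The point
    count is preserved; points are clipped to the image bounds.
    """
    if params is None:
        params = SnakeParams()
    if not init.closed:
        raise ValueError("snake initialization must be a closed contour")
    img = np.asarray(image, dtype=float)
    span = img.max() - img.min()
    img = (img - img.min()) / span if span > 0 else np.zeros_like(img)

    field = compute_gradient(img, params.sigma)
    edge = field.magnitude**2
    fy, fx = np.gradient(edge)  # d/drow, d/dcol

    n = len(init)
    a = internal_matrix(n, params.alpha, params.beta)
    system = a + params.gamma * np.eye(n)
    try:
        factor = linalg.cho_factor(system)
    except linalg.LinAlgError as exc:  # pragma: no cover - pathological params
        raise ValueError("singular snake system; adjust alpha/beta/gamma") from exc

    rows, cols = img.shape
    x = init.points.copy()
    for _ in range(params.iterations):
        coords = np.vstack([x[:, 1], x[:, 0]])
        ext_x = ndimage.map_coordinates(fx, coords, order=1, mode="nearest")
        ext_y = ndimage.map_coordinates(fy, coords, order=1, mode="nearest")
        x[:, 0] = linalg.cho_solve(factor, params.gamma * x[:, 0] + ext_x)
        x[:, 1] = linalg.cho_solve(factor, params.gamma * x[:, 1] + ext_y)
        x[:, 0] = np.clip(x[:, 0], 0.0, cols - 1)
        x[:, 1] = np.clip(x[:, 1], 0.0, rows - 1)
    return Contour(x, closed=True)
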
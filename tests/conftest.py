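import numpy as np
import pytest

from contourfit import Contour, compute_gradient, make_noisy_disc


@pytest.fixture(scope="session")
def disc_scene():
    """The reference phantom: radius-85 dark disc in 256x256, noise sigma 10."""
    return make_noisy_disc(noise_sigma=10.0, seed=42)


@pytest.fixture(scope="session")
def clean_disc_scene():
    return make_noisy_disc(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_disc_field(clean_disc_scene):
    return compute_gradient(clean_disc_scene.image, sigma=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def circle_contour(center=(128.0, 128.0), radius=85.0, n=200):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Contour(pts, closed=True)
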
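"""Shared fixtures: analytic band-limited patterns and synthetic pairs.

The ``radial_angular_pattern`` factory renders images whose value is an
analytic function of log-radius and angle around a known center, so a
rotated or rescaled copy can be produced exactly (no image-space
interpolation) and compared against the log-polar sampling pipeline.
Content near the pattern center is kept rotationally symmetric and smooth
at the pixel scale so that the 5x5 Gaussian interpolation operates well
within its accuracy regime.
"""

from __future__ import annotations

import numpy as np
import pytest

from lpm.image_io import Image


@pytest.fixture(scope="session")
def radial_angular_pattern():
    """Factory: band-limited test pattern around center (200, 200).

    ``pattern(theta0, scale)`` returns a 401x401 image equal to the base
    pattern rotated by ``theta0`` radians and magnified by ``scale`` about
    the center.  A feature of radius ``64 * scale`` at the center sees the
    same underlying signal in log-polar coordinates for every theta0 and
    (approximately) every scale.
    """

    def pattern(theta0: float = 0.0, scale: float = 1.0, size: int = 401) -> Image:
        c = (size - 1) // 2
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        dx, dy = (xx - c) / scale, (yy - c) / scale
        r = np.hypot(dx, dy) + 1e-12
        ang = np.arctan2(dy, dx) - theta0
        img = np.cos(2 * np.pi * np.log(r + 25) / np.log(4))
        for ka, amp, ph, r0, w in [
            (2, 0.8, 0.5, 45, 18),
            (1, 0.7, 4.0, 55, 18),
            (3, 0.5, 1.0, 30, 10),
        ]:
            img += amp * np.cos(ka * ang + ph) * np.exp(-((r - r0) ** 2) / (2 * w**2))
        return Image(img)

    return pattern


@pytest.fixture(scope="session")
def blobs_image():
    from lpm.synthetic import make_texture

    return make_texture(256, "blobs", seed=42)


@pytest.fixture(scope="session")
def noise_image():
    from lpm.synthetic import make_texture

    return make_texture(128, "bandlimited-noise", seed=7)
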
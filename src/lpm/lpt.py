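"""Log-polar transform: disc neighborhood -> square ring-by-angle image.

Each feature's disc is resampled on ``N`` logarithmically spaced rings
(radii running geometrically from 1 to the feature radius ``R``) times
``N`` uniformly spaced angles in ``[0, 2*pi)``.  A rotation of the image
about the feature center then becomes a circular shift of the columns,
which the magnitude spectrum downstream is blind to — this is where the
descriptor's rotation invariance comes from.  The log spacing concentrates
samples near the center, which also makes the descriptor tolerant to
moderate errors in the detected feature size.

Row convention: the outermost ring is stored as row 0 (top) and the
innermost ring as row N-1 (bottom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Feature
from .image_io import Image

__all__ = ["LPTImage", "sampling_grid", "sample_patch"]

#: sigma of the Gaussian sub-pixel interpolation weights (5x5 mask ~ +-2 sigma)
INTERP_SIGMA = 1.0


@dataclass(frozen=True)
class LPTImage:
    """The N x N log-polar resampled patch of one feature.

    ``values[r, j]`` holds the intensity on ring ``N-1-r`` (outermost ring
    in row 0, innermost in row N-1) at angle ``2*pi*j/N``.
    """

    values: np.ndarray
    feature: Feature

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"LPT image must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("LPT image contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def N(self) -> int:
        return self.values.shape[0]


def ring_radii(radius: float, N: int) -> np.ndarray:
    """Geometric ring radii ``R**(i/(N-1))`` for ``i = 0 .. N-1``.

    This is the unique log-uniform spacing with both endpoints pinned:
    the innermost ring at radius 1 and the outermost at ``R``.  For
    ``R == 1`` every ring collapses to radius 1.
    """
    if radius < 1:
        raise ValueError(f"feature radius must be >= 1 for log sampling, got {radius}")
    i = np.arange(N, dtype=np.float64)
    return radius ** (i / (N - 1))


def sampling_grid(feature: Feature, N: int) -> np.ndarray:
    """Continuous sample coordinates for one feature, shape ``(N, N, 2)``.

    ``grid[r, j] = (x, y)`` of the sample in LPT row ``r`` (ring
    ``N-1-r``) and column ``j`` (angle ``2*pi*j/N``, measured from the
    positive x axis, counterclockwise in array coordinates with y down).
    """
    rho = ring_radii(feature.radius, N)[::-1]  # row 0 = outermost ring
    theta = 2.0 * np.pi * np.arange(N) / N
    x = rho[:, None] * np.cos(theta)[None, :] + feature.x
    y = rho[:, None] * np.sin(theta)[None, :] + feature.y
    return np.stack([x, y], axis=-1)


def sample_patch(img: Image, feature: Feature, N: int = 32) -> LPTImage:
    """Resample one feature's disc neighborhood into its LPT image.

    Sub-pixel values are Gaussian-interpolated: each continuous sample
    point reads the 5x5 integer-pixel neighborhood centered on its nearest
    pixel, weighted by ``exp(-d**2 / 2)`` of the distance ``d`` from the
    sample point to each pixel, weights normalized to sum 1.  The caller
    must have border-filtered the features first; a neighborhood leaving
    the image is a contract violation.
    """
    grid = sampling_grid(feature, N)
    xs, ys = grid[..., 0].ravel(), grid[..., 1].ravel()
    cx = np.round(xs).astype(np.int64)
    cy = np.round(ys).astype(np.int64)
    h, w = img.height, img.width
    if (cx.min() < 2) or (cy.min() < 2) or (cx.max() > w - 3) or (cy.max() > h - 3):
        raise ValueError(
            "sampling neighborhood outside the image; run remove_border_features first"
        )
    off = np.arange(-2, 3)
    # neighborhood pixel coordinates: (n_samples, 5, 5)
    nx = cx[:, None, None] + off[None, :, None]
    ny = cy[:, None, None] + off[None, None, :]
    d2 = (nx - xs[:, None, None]) ** 2 + (ny - ys[:, None, None]) ** 2
    wgt = np.exp(-d2 / (2.0 * INTERP_SIGMA**2))
    wgt /= wgt.sum(axis=(1, 2), keepdims=True)
    vals = (img.pixels[ny, nx] * wgt).sum(axis=(1, 2))
    return LPTImage(values=vals.reshape(N, N), feature=feature)
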
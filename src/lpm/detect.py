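"""Built-in feature detectors and the external-detector adapter.

The descriptor needs only a center and a radius per feature, so any
detector can feed it.  Two classical detectors are built in — Harris
corners and determinant-of-Hessian blobs — both returning a fixed radius
(32 px by default).  External detectors (SIFT- or SURF-style) are consumed
as data: their scale values are converted to pixel radii by a dedicated
feature scaling coefficient (14 for difference-of-Gaussian scales, 9 for
Hessian-type scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .image_io import Image

__all__ = [
    "Feature",
    "SIGMA_SIFT",
    "SIGMA_SURF",
    "HARRIS_FIXED_RADIUS",
    "detect_harris",
    "detect_hessian",
    "adapt_external",
    "remove_border_features",
]

#: default feature scaling coefficients for external detector scales
SIGMA_SIFT = 14.0
SIGMA_SURF = 9.0
#: fixed radius used when the detector provides no scale
HARRIS_FIXED_RADIUS = 32.0

#: interpolation margin: half the 5x5 sub-pixel interpolation mask
INTERP_MARGIN = 2.0


@dataclass(frozen=True)
class Feature:
    """A circular image feature: center ``(x, y)`` and ``radius``, in pixels."""

    x: float
    y: float
    radius: float
    source: str = "external"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("feature center must be finite")
        if not (self.radius > 0 and np.isfinite(self.radius)):
            raise ValueError(f"feature radius must be > 0, got {self.radius}")


def _local_maxima(
    response: np.ndarray,
    max_features: int,
    rel_threshold: float,
    nms_size: int = 5,
) -> list[tuple[float, int, int]]:
    """Strongest local maxima of a response map.

    Non-maximum suppression in an ``nms_size`` square window; maxima below
    ``rel_threshold`` times the global maximum are discarded.  Returns
    ``(value, row, col)`` sorted by descending value (ties: row, then col).
    """
    peak = response.max()
    if peak <= 0:
        return []
    is_max = response == maximum_filter(response, size=nms_size, mode="nearest")
    is_max &= response > rel_threshold * peak
    rows, cols = np.nonzero(is_max)
    scored = sorted(zip(response[rows, cols], rows, cols), key=lambda t: (-t[0], t[1], t[2]))
    return scored[:max_features]


def detect_harris(
    img: Image,
    max_features: int = 500,
    fixed_radius: float = HARRIS_FIXED_RADIUS,
    k: float = 0.04,
    integration_sigma: float = 2.0,
    rel_threshold: float = 0.01,
) -> list[Feature]:
    """Harris corner detection with a fixed feature radius.

    The corner response is ``det(M) - k * trace(M)**2`` with the structure
    tensor ``M`` integrated by a Gaussian of ``integration_sigma``.  Local
    maxima are non-maximum suppressed in a 5x5 window and thresholded at
    ``rel_threshold`` times the strongest response.  A flat image yields an
    empty list.  The corner detector carries no scale, so every feature is
    given ``fixed_radius``.
    """
    px = img.pixels
    gy, gx = np.gradient(px)
    Axx = gaussian_filter(gx * gx, integration_sigma, mode="reflect")
    Axy = gaussian_filter(gx * gy, integration_sigma, mode="reflect")
    Ayy = gaussian_filter(gy * gy, integration_sigma, mode="reflect")
    response = (Axx * Ayy - Axy * Axy) - k * (Axx + Ayy) ** 2
    return [
        Feature(x=float(c), y=float(r), radius=fixed_radius, source="harris")
        for _, r, c in _local_maxima(response, max_features, rel_threshold)
    ]


def detect_hessian(
    img: Image,
    max_features: int = 500,
    fixed_radius: float = HARRIS_FIXED_RADIUS,
    scale_sigma: float = 2.0,
    rel_threshold: float = 0.01,
) -> list[Feature]:
    """Determinant-of-Hessian blob detection with a fixed feature radius.

    The response is ``Ixx * Iyy - Ixy**2`` of the image smoothed at
    ``scale_sigma``; maxima handling matches :func:`detect_harris`.
    """
    px = img.pixels
    Iyy = gaussian_filter(px, scale_sigma, order=(2, 0), mode="reflect")
    Ixx = gaussian_filter(px, scale_sigma, order=(0, 2), mode="reflect")
    Ixy = gaussian_filter(px, scale_sigma, order=(1, 1), mode="reflect")
    response = Ixx * Iyy - Ixy * Ixy
    return [
        Feature(x=float(c), y=float(r), radius=fixed_radius, source="hessian")
        for _, r, c in _local_maxima(response, max_features, rel_threshold)
    ]


def adapt_external(
    centers_scales: Iterable[tuple[float, float, float]],
    sigma: float,
) -> list[Feature]:
    """Convert external detector output ``(x, y, scale)`` to features.

    Different detectors use different scale spaces, so their scale values
    are multiplied by a detector-specific feature scaling coefficient
    ``sigma`` to become radii in pixels (defaults: 14 for SIFT-type, 9 for
    SURF-type scales).
    """
    if not sigma > 0:
        raise ValueError(f"scaling coefficient must be > 0, got {sigma}")
    out = []
    for x, y, scale in centers_scales:
        if not scale > 0:
            raise ValueError(f"non-positive scale {scale} at ({x}, {y})")
        out.append(Feature(x=float(x), y=float(y), radius=float(scale) * sigma, source="external"))
    return out


def remove_border_features(features: Sequence[Feature], img: Image) -> list[Feature]:
    """Drop features whose sampling disc plus interpolation margin leaves
    the image.

    Log-polar sampling reads a 5x5 pixel neighborhood around points up to
    ``radius`` from the center, so a feature is kept only when
    ``center +- (radius + 2)`` stays inside ``[0, size - 1]`` on both axes
    (boundary inclusive).
    """
    h, w = img.height, img.width
    kept = []
    for f in features:
        m = f.radius + INTERP_MARGIN
        if f.x - m >= 0 and f.y - m >= 0 and f.x + m <= w - 1 and f.y + m <= h - 1:
            kept.append(f)
    return kept
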
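"""Seeded synthetic images and transformed pairs with known homographies.

Every stage of the pipeline is testable without external data: textures
emulate the image families the descriptor targets — fields of Gaussian
spots like fluorescence signals, band-limited noise like transmission
electron micrograph texture, and a spot field over an intensity ramp —
and :func:`make_pair` renders a transformed copy under an exactly known
similarity (rotation, scale, translation) with optional affine intensity
change, blur and additive noise.  Similarities rather than full projective
maps are used: they exercise every invariance the descriptor claims
without confounding it with the viewpoint distortion that circular
features cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .detect import Feature, detect_hessian, remove_border_features
from .homography import Homography
from .image_io import Image, presmooth

__all__ = ["SyntheticPair", "make_texture", "make_pair", "similarity_matrix"]


@dataclass(frozen=True)
class SyntheticPair:
    """A ground-truth test pair: two images, the homography mapping
    A-coordinates to B-coordinates, planted features in A, and the seed
    that regenerates the pair bit-identically."""

    img_a: Image
    img_b: Image
    H: Homography
    planted_features: tuple[Feature, ...]
    seed: int


def make_texture(size: int = 256, kind: str = "blobs", seed: int = 0) -> Image:
    """A deterministic synthetic texture.

    ``blobs``: 30-80 Gaussian spots of random width (sigma 2-6) and
    amplitude on a dark background, emulating fluorescence bright dots.
    ``ramp+blobs``: the same plus a linear intensity ramp.
    ``bandlimited-noise``: white noise low-pass filtered at sigma 2,
    emulating electron-micrograph texture.
    """
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    rng = np.random.default_rng(seed)
    if kind in ("blobs", "ramp+blobs"):
        px = np.full((size, size), 10.0)
        n_blobs = int(rng.integers(30, 81))
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            cx, cy = rng.uniform(5, size - 5, size=2)
            sig = rng.uniform(2.0, 6.0)
            amp = rng.uniform(50.0, 200.0)
            px += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
        if kind == "ramp+blobs":
            gx, gy = rng.uniform(-0.3, 0.3, size=2)
            px += gx * xx + gy * yy
        return Image(px)
    if kind == "bandlimited-noise":
        noise = gaussian_filter(rng.standard_normal((size, size)), sigma=2.0, mode="reflect")
        noise = (noise - noise.mean()) / noise.std()
        return Image(128.0 + 40.0 * noise)
    raise ValueError(f"unknown texture kind {kind!r}")


def similarity_matrix(
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    center: tuple[float, float] = (0.0, 0.0),
) -> Homography:
    """Similarity transform rotating/scaling about ``center`` then
    translating: maps A coordinates to B coordinates."""
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = center
    tx, ty = translation
    R = np.array(
        [
            [scale * c, -scale * s, cx - scale * (c * cx - s * cy) + tx],
            [scale * s, scale * c, cy - scale * (s * cx + c * cy) + ty],
            [0.0, 0.0, 1.0],
        ]
    )
    return Homography(R)


def make_pair(
    base: Image,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    intensity: tuple[float, float] = (1.0, 0.0),
    blur_sigma: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    feature_radius: float = 32.0,
    max_features: int = 150,
) -> SyntheticPair:
    """Render a transformed copy of ``base`` with exactly known geometry.

    The geometric map is a similarity about the image center composed
    with a translation; ``img_b`` is the bicubic warp of ``base`` under
    it, followed by the affine intensity map ``a*I + b``, Gaussian blur of
    ``blur_sigma`` and additive Gaussian noise of ``noise_sigma`` (seeded).
    The identity transform with no photometric change returns the input
    bit-exactly.  Planted features are determinant-of-Hessian detections
    on the pre-smoothed base image, border-filtered, with a fixed radius.
    The composed similarity must keep at least half of A visible in B.
    """
    h, w = base.height, base.width
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    H = similarity_matrix(rotation_deg, scale, translation, center)

    # visibility precondition: >= 50% of A's pixels must land inside B's frame
    yy, xx = np.mgrid[0:h:8, 0:w:8]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(np.float64)
    mapped = H.apply(pts)
    vis = np.mean(
        (mapped[:, 0] >= 0) & (mapped[:, 0] <= w - 1) & (mapped[:, 1] >= 0) & (mapped[:, 1] <= h - 1)
    )
    if vis < 0.5:
        raise ValueError(f"transform leaves only {vis:.0%} of image A visible in B")

    a, b = intensity
    identity_geometry = np.allclose(H.matrix, np.eye(3), atol=1e-15)
    if identity_geometry:
        warped = base.pixels.copy()
    else:
        tform = ProjectiveTransform(matrix=np.linalg.inv(H.matrix))
        warped = warp(
            base.pixels,
            tform,
            order=3,
            mode="constant",
            cval=float(np.median(base.pixels)),
            preserve_range=True,
        )
    out = a * warped + b
    if blur_sigma > 0:
        out = gaussian_filter(out, sigma=blur_sigma, mode="reflect")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    img_b = Image(out)

    planted = remove_border_features(
        detect_hessian(presmooth(base), max_features=max_features, fixed_radius=feature_radius),
        base,
    )
    return SyntheticPair(
        img_a=base, img_b=img_b, H=H, planted_features=tuple(planted), seed=seed
    )
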